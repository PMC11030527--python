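"""Replication of discovery ASE loci in an independent multi-sample cohort.

Each discovery locus is re-tested per cohort sample on the counts of the two
discovery alleles (matched by base identity, so the sign of the fold change
is comparable to discovery). A sample x locus pair enters the analysis only
if the sample looks heterozygous there; significance then uses the same
|aeFC| >= 2 and BH-adjusted p <= 0.05 rule as discovery, with the BH family
being all retained loci within one sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ase_stats import aefc, bh_adjust, binomial_test
from .model import HetLocus, LocusCounts, ValidationRecord, ValidationSummary


@dataclass(frozen=True)
class HetRule:
    """When does a cohort sample count as heterozygous at a locus?

    Default: both discovery alleles observed (>=1 read each) and pileup
    depth >= 10. RNA-only genotyping is circular under strong ASE (the low
    allele can vanish), so an explicit genotype mask can override the rule.
    """

    min_allele_reads: int = 1
    min_depth: int = 10


def validate_loci(
    discovery_loci: Sequence[HetLocus],
    cohort_counts: Mapping[str, Iterable[LocusCounts]],
    het_rule: HetRule = HetRule(),
    genotype_mask: Mapping[str, set[tuple[str, int]]] | None = None,
    fc_min: float = 2.0,
    alpha: float = 0.05,
) -> list[ValidationRecord]:
    """Per sample x locus significance calls at the discovery loci.

    ``cohort_counts`` maps sample id -> pileup tallies; a locus absent from a
    sample yields no record. ``genotype_mask``, when given, restricts each
    sample to externally genotyped heterozygous sites before the read-based
    ``het_rule`` is applied.
    """
    records: list[ValidationRecord] = []
    for sample_id in sorted(cohort_counts):
        index = {(c.chrom, c.pos): c for c in cohort_counts[sample_id]}
        mask = genotype_mask.get(sample_id) if genotype_mask is not None else None
        sample_records: list[ValidationRecord] = []
        p_values: list[float] = []
        for locus in discovery_loci:
            key = (locus.chrom, locus.pos)
            if mask is not None and key not in mask:
                continue
            lc = index.get(key)
            if lc is None:
                continue
            a1, a2 = lc.get(locus.hap1_base), lc.get(locus.hap2_base)
            if min(a1, a2) < het_rule.min_allele_reads or lc.depth < het_rule.min_depth:
                continue  # not heterozygous in this sample
            if a1 + a2 == 0:
                continue
            sample_records.append(
                ValidationRecord(
                    chrom=locus.chrom, pos=locus.pos, sample_id=sample_id,
                    allele1_count=a1, allele2_count=a2,
                    aefc=aefc(a1, a2), p_value=binomial_test(a1, a2),
                    adj_p=1.0, significant=False,
                )
            )
            p_values.append(sample_records[-1].p_value)
        if not sample_records:
            continue
        for rec, adj in zip(sample_records, bh_adjust(p_values)):
            rec.adj_p = float(adj)
            rec.significant = (
                not math.isnan(rec.aefc)
                and abs(rec.aefc) >= fc_min
                and rec.adj_p <= alpha
            )
        records.extend(sample_records)
    return records


def summarize_validation(
    records: Sequence[ValidationRecord],
    discovery_directions: Mapping[tuple[str, int], int],
    replication_threshold: float = 0.9,
) -> ValidationSummary:
    """Confirmation, direction-concordance and per-locus replication rates.

    ``pct_significant`` is over all retained comparisons; direction
    concordance is computed among significant comparisons against the
    discovery sign; per-locus replication is the fraction of a locus's
    tested samples in which it was significant.
    """
    n = len(records)
    sig = [r for r in records if r.significant]
    n_sig = len(sig)
    n_same = sum(
        1 for r in sig
        if r.direction == discovery_directions.get((r.chrom, r.pos), 0)
        and r.direction != 0
    )
    per_locus_rows = []
    by_locus: dict[tuple[str, int], list[ValidationRecord]] = {}
    for r in records:
        by_locus.setdefault((r.chrom, r.pos), []).append(r)
    for (chrom, pos), recs in sorted(by_locus.items()):
        n_tested = len(recs)
        n_locus_sig = sum(1 for r in recs if r.significant)
        per_locus_rows.append(
            {
                "chrom": chrom, "pos": pos,
                "n_samples_tested": n_tested,
                "n_samples_significant": n_locus_sig,
                "replication_fraction": n_locus_sig / n_tested,
            }
        )
    per_locus = pd.DataFrame(
        per_locus_rows,
        columns=["chrom", "pos", "n_samples_tested", "n_samples_significant",
                 "replication_fraction"],
    )
    n_any = int((per_locus["n_samples_significant"] >= 1).sum()) if len(per_locus) else 0
    n_thr = (
        int((per_locus["replication_fraction"] >= replication_threshold).sum())
        if len(per_locus) else 0
    )
    return ValidationSummary(
        n_comparisons=n,
        n_significant=n_sig,
        pct_significant=round(100.0 * n_sig / n, 1) if n else 0.0,
        n_same_direction=n_same,
        pct_same_direction=round(100.0 * n_same / n_sig, 1) if n_sig else 0.0,
        per_locus=per_locus,
        n_loci_tested=len(per_locus),
        n_loci_replicated_any=n_any,
        n_loci_replicated_threshold=n_thr,
        replication_threshold=replication_threshold,
    )
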