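"""Haplotype-aggregated allele expression.

For each phased event, per-locus nucleotide tallies are summed along the two
haplotype base strings: reads matching a locus's haplotype-1 base accrue to
allele 1, haplotype-2 reads to allele 2, and anything else to ``other_exp``
(never to either allele). Values are raw integer read counts — the binomial
test downstream assumes unnormalized counts.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConsistencyError
from .model import HaplotypeExpression, LocusCounts, PhasedEvent

logger = logging.getLogger(__name__)

#: Chromosome names excluded by the autosomal focus of the analysis.
DEFAULT_SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


def index_counts(counts: Iterable[LocusCounts]) -> dict[tuple[str, int], LocusCounts]:
    """Index pileup tallies by (chrom, pos) for event lookup."""
    return {(c.chrom, c.pos): c for c in counts}


def tally_event(
    event: PhasedEvent,
    counts: Mapping[tuple[str, int], LocusCounts],
    tissue: str = "",
    sample: str = "",
) -> HaplotypeExpression:
    """Sum per-locus tallies along the event's two haplotype strings.

    A phased locus with no pileup coverage contributes zero to both alleles
    (logged, not fatal): short-read coverage is uneven and the downstream
    >=10 prefilter removes events whose totals stay too low.
    """
    if not event.loci:
        raise ConsistencyError(f"{event.gene_id}: event has no loci")
    allele1 = allele2 = other = 0
    for locus in event.loci:
        lc = counts.get((locus.chrom, locus.pos))
        if lc is None:
            logger.warning(
                "%s: no pileup coverage at %s:%d; contributes zero",
                event.gene_id, locus.chrom, locus.pos,
            )
            continue
        allele1 += lc.get(locus.hap1_base)
        allele2 += lc.get(locus.hap2_base)
        other += sum(
            n for base, n in lc.tallies.items()
            if base not in (locus.hap1_base, locus.hap2_base)
        )
    chrom, first, last = event.region
    return HaplotypeExpression(
        gene_id=event.gene_id,
        allele1_exp=allele1,
        allele2_exp=allele2,
        other_exp=other,
        n_loci=len(event.loci),
        chrom=chrom,
        start=first,
        end=last,
        tissue=tissue,
        sample=sample,
    )


def tally_events(
    events: Sequence[PhasedEvent],
    counts: Iterable[LocusCounts] | Mapping[tuple[str, int], LocusCounts],
    tissue: str = "",
    sample: str = "",
) -> list[HaplotypeExpression]:
    if not isinstance(counts, Mapping):
        counts = index_counts(counts)
    return [tally_event(e, counts, tissue=tissue, sample=sample) for e in events]


def drop_sex_chromosomes(
    expressions: Iterable[HaplotypeExpression],
    sex_chroms: frozenset[str] | set[str] = DEFAULT_SEX_CHROMS,
    sidecar_path: str | Path | None = None,
) -> tuple[list[HaplotypeExpression], list[HaplotypeExpression]]:
    """Split expressions into (autosomal, sex-chromosome) records.

    The analysis focuses on autosomes, where balanced expression is the
    null; X/Y records are not deleted but returned (and optionally written
    to ``sidecar_path``) so they stay available for separate analysis.
    """
    kept: list[HaplotypeExpression] = []
    dropped: list[HaplotypeExpression] = []
    for e in expressions:
        (dropped if e.chrom in sex_chroms else kept).append(e)
    if sidecar_path is not None:
        lines = ["gene_id\tchrom\tstart\tend\tallele1_exp\tallele2_exp\tother_exp"]
        lines += [
            f"{e.gene_id}\t{e.chrom}\t{e.start}\t{e.end}\t"
            f"{e.allele1_exp}\t{e.allele2_exp}\t{e.other_exp}"
            for e in dropped
        ]
        Path(sidecar_path).write_text("\n".join(lines) + "\n")
    return kept, dropped
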