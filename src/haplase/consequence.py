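"""Variant-consequence classification against transcript models.

A deliberately small stand-in for a full effect predictor: each heterozygous
SNP is classified against every overlapping transcript and the terms are
unioned. Supported terms:

    intergenic_variant, intron_variant, splice_region_variant,
    5_prime_UTR_variant, 3_prime_UTR_variant, non_coding_transcript_exon_variant,
    synonymous_variant, missense_variant, stop_gained, stop_lost,
    coding_sequence_variant  (CDS locus whose codon context is unavailable)

Splice regions follow Ensembl's windows: the last 1-3 exonic bases next to
an intron, and the first 1-8 intronic bases (the 1-2 bp donor/acceptor core
is folded into the splice-region term). Loci annotated only as intronic
and/or intergenic can be excluded downstream — an RNA-seq pileup read at
such a position is more plausibly an alignment artifact than expression.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Iterable, Protocol, Sequence

import pandas as pd
from Bio.Seq import Seq

from .errors import AnnotationWarning
from .model import ConsequenceRecord, HetLocus, TranscriptModel

TERM_VOCABULARY = frozenset(
    {
        "3_prime_UTR_variant",
        "5_prime_UTR_variant",
        "missense_variant",
        "synonymous_variant",
        "stop_gained",
        "stop_lost",
        "splice_region_variant",
        "non_coding_transcript_exon_variant",
        "intron_variant",
        "intergenic_variant",
        "coding_sequence_variant",
    }
)

NONFUNCTIONAL_TERMS = frozenset({"intron_variant", "intergenic_variant"})

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# splice-region windows (bp), Ensembl definitions
_EXONIC_SPLICE_BP = 3
_INTRONIC_SPLICE_BP = 8


class ReferenceSource(Protocol):
    """Anything that can serve 1-based inclusive genomic sequence."""

    def fetch(self, chrom: str, start: int, end: int) -> str: ...


class FastaReference:
    """ReferenceSource backed by an (uncompressed) FASTA via pyfaidx."""

    def __init__(self, path: str) -> None:
        import pyfaidx

        self._fasta = pyfaidx.Fasta(path)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return str(self._fasta.get_seq(chrom, start, end)).upper()


def _splice_region_terms(pos: int, t: TranscriptModel) -> set[str]:
    """Splice-region membership for a position inside transcript ``t``."""
    terms: set[str] = set()
    exons = sorted(t.exons)
    for i, (s, e) in enumerate(exons):
        has_prev_intron = i > 0
        has_next_intron = i < len(exons) - 1
        if s <= pos <= e:
            if has_next_intron and e - pos < _EXONIC_SPLICE_BP:
                terms.add("splice_region_variant")
            if has_prev_intron and pos - s < _EXONIC_SPLICE_BP:
                terms.add("splice_region_variant")
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if e1 < pos < s2:  # inside this intron
            offset = min(pos - e1, s2 - pos)  # 1-based distance into intron
            if 1 <= offset <= _INTRONIC_SPLICE_BP:
                terms.add("splice_region_variant")
    return terms


def _cds_blocks(t: TranscriptModel) -> list[tuple[int, int]]:
    return sorted(t.cds)


def _codon_terms(
    locus: HetLocus,
    t: TranscriptModel,
    reference: ReferenceSource | None,
) -> set[str]:
    """Classify a CDS SNP by translating both alleles' codons."""
    blocks = _cds_blocks(t)
    cds_len = sum(e - s + 1 for s, e in blocks)
    if cds_len % 3 != 0:
        warnings.warn(
            f"{t.transcript_id}: CDS length {cds_len} not divisible by 3; "
            "codon terms suppressed",
            AnnotationWarning,
            stacklevel=2,
        )
        return {"coding_sequence_variant"}
    if reference is None:
        warnings.warn(
            f"{t.transcript_id}: no reference sequence; codon terms suppressed",
            AnnotationWarning,
            stacklevel=2,
        )
        return {"coding_sequence_variant"}
    cds_seq = "".join(reference.fetch(t.chrom, s, e) for s, e in blocks).upper()
    offset = 0
    genomic_index = None
    for s, e in blocks:
        if s <= locus.pos <= e:
            genomic_index = offset + (locus.pos - s)
            break
        offset += e - s + 1
    assert genomic_index is not None  # caller guarantees pos in CDS
    if t.strand == "-":
        cds_seq = "".join(_COMPLEMENT[b] for b in reversed(cds_seq))
        cds_index = cds_len - 1 - genomic_index
    else:
        cds_index = genomic_index
    codon_start = (cds_index // 3) * 3
    within = cds_index - codon_start
    codon = list(cds_seq[codon_start : codon_start + 3])

    alleles = (locus.hap1_base, locus.hap2_base)
    baseline = locus.ref_base if locus.ref_base in alleles else alleles[0]
    variant = alleles[1] if baseline == alleles[0] else alleles[0]
    if t.strand == "-":
        baseline, variant = _COMPLEMENT[baseline], _COMPLEMENT[variant]

    def translate(allele: str) -> str:
        c = codon.copy()
        c[within] = allele
        return str(Seq("".join(c)).translate())

    aa_base, aa_var = translate(baseline), translate(variant)
    if aa_base == aa_var:
        return {"synonymous_variant"}
    if aa_var == "*":
        return {"stop_gained"}
    if aa_base == "*":
        return {"stop_lost"}
    return {"missense_variant"}


def _transcript_terms(
    locus: HetLocus,
    t: TranscriptModel,
    reference: ReferenceSource | None,
) -> set[str]:
    pos = locus.pos
    terms = _splice_region_terms(pos, t)
    in_exon = any(s <= pos <= e for s, e in t.exons)
    if not in_exon:
        terms.add("intron_variant")
        return terms
    span = t.cds_span
    if span is None:
        terms.add("non_coding_transcript_exon_variant")
        return terms
    cds_start, cds_end = span
    if cds_start <= pos <= cds_end:
        terms |= _codon_terms(locus, t, reference)
        return terms
    upstream_of_cds = pos < cds_start
    five_prime = upstream_of_cds if t.strand == "+" else not upstream_of_cds
    terms.add("5_prime_UTR_variant" if five_prime else "3_prime_UTR_variant")
    return terms


def classify_consequence(
    locus: HetLocus,
    transcripts: Sequence[TranscriptModel],
    reference: ReferenceSource | None = None,
) -> ConsequenceRecord:
    """Union of per-transcript consequence terms for one heterozygous SNP."""
    overlapping = [
        t for t in transcripts
        if t.chrom == locus.chrom and t.start <= locus.pos <= t.end
    ]
    if not overlapping:
        return ConsequenceRecord(
            chrom=locus.chrom, pos=locus.pos,
            alleles=(locus.hap1_base, locus.hap2_base),
            terms=frozenset({"intergenic_variant"}), gene_id="",
        )
    terms: set[str] = set()
    for t in overlapping:
        terms |= _transcript_terms(locus, t, reference)
    gene_ids = sorted({t.gene_id for t in overlapping})
    return ConsequenceRecord(
        chrom=locus.chrom, pos=locus.pos,
        alleles=(locus.hap1_base, locus.hap2_base),
        terms=frozenset(terms), gene_id=";".join(gene_ids),
    )


def filter_nonfunctional(
    records: Iterable[ConsequenceRecord],
) -> tuple[list[ConsequenceRecord], list[ConsequenceRecord]]:
    """Drop loci annotated solely as intronic/intergenic; strip those terms
    from mixed annotations. Returns (kept, dropped)."""
    kept: list[ConsequenceRecord] = []
    dropped: list[ConsequenceRecord] = []
    for rec in records:
        if rec.terms <= NONFUNCTIONAL_TERMS:
            dropped.append(rec)
        else:
            kept.append(replace(rec, terms=frozenset(rec.terms - NONFUNCTIONAL_TERMS)))
    return kept, dropped


def summarize_consequences(records: Iterable[ConsequenceRecord]) -> pd.DataFrame:
    """Counts and percentages by exact term combination (ampersand rows)."""
    combos: dict[str, int] = {}
    total = 0
    for rec in records:
        label = " & ".join(sorted(rec.terms))
        combos[label] = combos.get(label, 0) + 1
        total += 1
    if total == 0:
        return pd.DataFrame(columns=["terms", "count", "percent"])
    rows = [
        {"terms": label, "count": n, "percent": round(100.0 * n / total, 2)}
        for label, n in combos.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["count", "terms"], ascending=[False, True], ignore_index=True
    )
    return df
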