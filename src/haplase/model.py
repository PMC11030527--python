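"""Core record types carried between pipeline stages.

Coordinate conventions: genomic positions on loci, events and regions are
1-based inclusive (VCF/GTF/pileup style); peak intervals are 0-based
half-open (BED style). Converters never guess — each reader/writer states
its convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

NUCLEOTIDES = ("A", "C", "G", "T")

#: TSV sentinel for an infinite log2 fold change (one allele count is zero).
AEFC_INF_SENTINEL = 1e9


@dataclass(frozen=True)
class HetLocus:
    """One phased heterozygous SNP.

    ``hap1_base``/``hap2_base`` are the alleles carried by haplotype 1 and 2;
    ``ref_base`` records which of the two the reference genome carries (used
    by the VCF/pileup writers; defaults to ``hap1_base``).
    """

    chrom: str
    pos: int  # 1-based
    hap1_base: str
    hap2_base: str
    gene_id: str
    phase_set: str
    ref_base: str | None = None

    def __post_init__(self) -> None:
        if self.hap1_base == self.hap2_base:
            raise ValueError(f"{self.chrom}:{self.pos}: haplotype bases must differ")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_base is None:
            object.__setattr__(self, "ref_base", self.hap1_base)

    @property
    def alt_base(self) -> str:
        return self.hap2_base if self.ref_base == self.hap1_base else self.hap1_base


@dataclass(frozen=True)
class PhasedEvent:
    """A gene's ordered heterozygous loci with its two haplotype strings."""

    gene_id: str
    chrom: str
    loci: tuple[HetLocus, ...]

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError(f"{self.gene_id}: an event needs at least one locus")
        positions = [l.pos for l in self.loci]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(f"{self.gene_id}: loci must be strictly increasing")
        if any(l.chrom != self.chrom for l in self.loci):
            raise ValueError(f"{self.gene_id}: loci must share the event chromosome")

    @property
    def hap1_string(self) -> str:
        return "".join(l.hap1_base for l in self.loci)

    @property
    def hap2_string(self) -> str:
        return "".join(l.hap2_base for l in self.loci)

    @property
    def region(self) -> tuple[str, int, int]:
        """(chrom, first, last) span of the loci, 1-based inclusive."""
        return (self.chrom, self.loci[0].pos, self.loci[-1].pos)


@dataclass
class LocusCounts:
    """Observed nucleotide tallies at one genomic position.

    ``depth`` is the pileup depth column; tallies may sum to less than depth
    when reads were dropped for base quality or consumed by deletions.
    """

    chrom: str
    pos: int  # 1-based
    ref_base: str
    tallies: dict[str, int]
    depth: int

    def __post_init__(self) -> None:
        if self.depth < 0 or any(v < 0 for v in self.tallies.values()):
            raise ValueError(f"{self.chrom}:{self.pos}: negative count")

    def get(self, base: str) -> int:
        return self.tallies.get(base, 0)


@dataclass
class PeakSet:
    """One histone mark's peak intervals for one tissue/sample.

    Intervals are (chrom, start, end), 0-based half-open, sorted, deduplicated.
    """

    mark: str
    tissue: str
    sample: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start < 0 or end <= start:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")
        self.intervals = sorted(set(self.intervals))


@dataclass
class HaplotypeExpression:
    """Per-event haplotype-aggregated read counts."""

    gene_id: str
    allele1_exp: int
    allele2_exp: int
    other_exp: int
    n_loci: int
    chrom: str
    start: int  # 1-based inclusive
    end: int
    tissue: str = ""
    sample: str = ""

    def __post_init__(self) -> None:
        if min(self.allele1_exp, self.allele2_exp, self.other_exp) < 0:
            raise ValueError(f"{self.gene_id}: negative expression")
        if self.n_loci < 1 or self.start > self.end:
            raise ValueError(f"{self.gene_id}: malformed region")

    @property
    def region(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class ASEEvent:
    """One tested allele-expression comparison.

    ``aefc`` is log2(allele1) - log2(allele2); +/-inf when exactly one count
    is zero, NaN when both are (such an event can never be significant).
    """

    gene_id: str
    tissue: str
    sample: str
    allele1_exp: int
    allele2_exp: int
    aefc: float
    p_value: float
    adj_p: float
    prefilter_pass: bool
    significant: bool
    chrom: str
    start: int
    end: int

    @property
    def region(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    @property
    def direction(self) -> int:
        if math.isnan(self.aefc) or self.aefc == 0:
            return 0
        return 1 if self.aefc > 0 else -1


@dataclass(frozen=True)
class GroundTruthRecord:
    """Simulated truth for one gene."""

    gene_id: str
    is_ase: bool
    true_fold_change: float
    favored_haplotype: int  # 1 or 2

    def __post_init__(self) -> None:
        if not self.is_ase and self.true_fold_change != 1.0:
            raise ValueError(f"{self.gene_id}: null gene must have fold change 1")
        if self.favored_haplotype not in (1, 2):
            raise ValueError(f"{self.gene_id}: favored haplotype must be 1 or 2")


@dataclass
class MarkOverlap:
    """Which histone marks intersect one event's haplotype region."""

    gene_id: str
    tissue: str
    sample: str
    marks_hit: frozenset[str]
    chrom: str
    start: int
    end: int


@dataclass
class ValidationRecord:
    """One discovery locus re-tested in one validation sample."""

    chrom: str
    pos: int
    sample_id: str
    allele1_count: int
    allele2_count: int
    aefc: float
    p_value: float
    adj_p: float
    significant: bool

    @property
    def direction(self) -> int:
        if math.isnan(self.aefc) or self.aefc == 0:
            return 0
        return 1 if self.aefc > 0 else -1


@dataclass
class ValidationSummary:
    """Cohort-level confirmation / direction-concordance / replication stats."""

    n_comparisons: int
    n_significant: int
    pct_significant: float
    n_same_direction: int
    pct_same_direction: float  # among significant comparisons
    per_locus: "pd.DataFrame"  # type: ignore[name-defined]  # noqa: F821
    n_loci_tested: int
    n_loci_replicated_any: int
    n_loci_replicated_threshold: int
    replication_threshold: float


@dataclass(frozen=True)
class TranscriptModel:
    """Minimal transcript structure for consequence annotation.

    ``exons`` and ``cds`` are 1-based inclusive (start, end) pairs sorted by
    start; ``cds`` is empty for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def cds_span(self) -> tuple[int, int] | None:
        if not self.cds:
            return None
        return (min(s for s, _ in self.cds), max(e for _, e in self.cds))


@dataclass(frozen=True)
class ConsequenceRecord:
    """VEP-style term set for one heterozygous locus."""

    chrom: str
    pos: int
    alleles: tuple[str, str]
    terms: frozenset[str]
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"{self.chrom}:{self.pos}: term set may not be empty")
        if "intergenic_variant" in self.terms and len(self.terms) > 1:
            raise ValueError(
                f"{self.chrom}:{self.pos}: intergenic excludes genic terms"
            )


@dataclass
class EnrichmentResult:
    """One pathway's over-representation test."""

    pathway_id: str
    n_universe: int
    n_pathway: int
    n_input: int
    n_overlap: int
    p_value: float
    significant: bool
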