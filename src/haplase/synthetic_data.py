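"""Synthetic phased transcriptomes with known allelic-imbalance ground truth.

The generator emulates the data a haplotype-aware ASE study consumes: per
gene, an ordered run of phased heterozygous SNPs (the two haplotype base
strings), short-read pileup counts at those SNPs, histone-mark peak tracks,
toy transcript models, and a multi-sample validation cohort.

Noise model: per-locus depth is Poisson(mean_depth); conditional on depth,
haplotype-1 reads are Binomial(depth, p1) with p1 = 0.5 for balanced genes
and FC/(1+FC) for imbalanced genes favoring haplotype 1 (1/(1+FC) when
haplotype 2 is favored). This is exactly the null/alternative family under
which a two-sided binomial test of p = 0.5 is the correct per-event test.
Sequencing error is off by default; a configurable error rate re-assigns
reads uniformly to one of the two non-haplotype bases.

All outputs are deterministic functions of (config, seed): each stage draws
from ``numpy.random.default_rng([seed, stage])`` so regenerating any one
artifact never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ConsistencyError
from .model import (
    NUCLEOTIDES,
    GroundTruthRecord,
    HetLocus,
    LocusCounts,
    PeakSet,
    PhasedEvent,
    TranscriptModel,
)

# Horse karyotype: 31 autosomes plus X; sex-chromosome genes are placed on X.
AUTOSOMES = tuple(f"chr{i}" for i in range(1, 32))
SEX_CHROM = "chrX"

_STAGE_TRANSCRIPTOME = 0
_STAGE_COUNTS = 1
_STAGE_COHORT = 2
_STAGE_TRANSCRIPTS = 3
_STAGE_PATHWAYS = 4
_STAGE_REFERENCE = 5


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the generator.

    Defaults mirror a bulk RNA-seq ASE design: ~50x coverage per locus, a
    10% imbalanced-gene fraction at 4-fold imbalance, and a 66-sample
    validation cohort in which a discovery locus is heterozygous in 85% of
    cohort animals.
    """

    n_genes: int = 1000
    loci_per_gene: int | tuple[int, int] = (1, 5)
    mean_depth: float = 50.0
    ase_fraction: float = 0.1
    fold_change: float = 4.0
    n_samples: int = 66
    het_rate: float = 0.85
    seed: int = 0
    sex_chrom_fraction: float = 0.05
    error_rate: float = 0.0
    tissue: str = "liver"
    sample: str = "s1"

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        lo, hi = self.loci_range()
        if lo < 1 or hi < lo:
            raise ConfigurationError("loci_per_gene must be a positive count or range")
        if self.mean_depth < 0:
            raise ConfigurationError("mean_depth must be >= 0")
        for name in ("ase_fraction", "het_rate", "sex_chrom_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.fold_change <= 0:
            raise ConfigurationError("fold_change must be > 0")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be positive")

    def loci_range(self) -> tuple[int, int]:
        if isinstance(self.loci_per_gene, int):
            return (self.loci_per_gene, self.loci_per_gene)
        lo, hi = self.loci_per_gene
        return (int(lo), int(hi))


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def generate_phased_transcriptome(
    config: SimulationConfig,
) -> tuple[list[PhasedEvent], list[GroundTruthRecord]]:
    """Draw gene placements, phased loci and per-gene imbalance truth.

    Each gene receives 1..k loci with strictly increasing positions and two
    distinct alleles per locus; the reference allele is assigned to haplotype
    1 or 2 at random so downstream VCFs contain both 0|1 and 1|0 genotypes.
    """
    config.validate()
    rng = _rng(config, _STAGE_TRANSCRIPTOME)
    lo, hi = config.loci_range()
    events: list[PhasedEvent] = []
    truth: list[GroundTruthRecord] = []
    for i in range(config.n_genes):
        gene_id = f"G{i:05d}"
        if rng.random() < config.sex_chrom_fraction:
            chrom = SEX_CHROM
        else:
            chrom = AUTOSOMES[int(rng.integers(len(AUTOSOMES)))]
        n_loci = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(1_000, 1_800_000))
        gaps = rng.integers(20, 400, size=n_loci)
        positions = start + np.cumsum(gaps)
        phase_set = str(i + 1)
        loci = []
        for pos in positions:
            b1, b2 = rng.choice(len(NUCLEOTIDES), size=2, replace=False)
            hap1, hap2 = NUCLEOTIDES[b1], NUCLEOTIDES[b2]
            ref = hap1 if rng.random() < 0.5 else hap2
            loci.append(
                HetLocus(chrom, int(pos), hap1, hap2, gene_id, phase_set, ref_base=ref)
            )
        events.append(PhasedEvent(gene_id, chrom, tuple(loci)))
        is_ase = bool(rng.random() < config.ase_fraction)
        favored = int(rng.integers(1, 3)) if is_ase else 1
        truth.append(
            GroundTruthRecord(
                gene_id=gene_id,
                is_ase=is_ase,
                true_fold_change=config.fold_change if is_ase else 1.0,
                favored_haplotype=favored,
            )
        )
    return events, truth


def _hap1_probability(record: GroundTruthRecord) -> float:
    if not record.is_ase:
        return 0.5
    fc = record.true_fold_change
    return fc / (1.0 + fc) if record.favored_haplotype == 1 else 1.0 / (1.0 + fc)


def _draw_locus_counts(
    rng: np.random.Generator,
    locus: HetLocus,
    p1: float,
    mean_depth: float,
    error_rate: float,
) -> LocusCounts:
    depth = int(rng.poisson(mean_depth))
    k1 = int(rng.binomial(depth, p1)) if depth > 0 else 0
    k2 = depth - k1
    tallies = {locus.hap1_base: k1, locus.hap2_base: k2}
    if error_rate > 0.0 and depth > 0:
        others = [b for b in NUCLEOTIDES if b not in (locus.hap1_base, locus.hap2_base)]
        for hap_base in (locus.hap1_base, locus.hap2_base):
            n_err = int(rng.binomial(tallies[hap_base], error_rate))
            tallies[hap_base] -= n_err
            for _ in range(n_err):
                b = others[int(rng.integers(len(others)))]
                tallies[b] = tallies.get(b, 0) + 1
    return LocusCounts(
        chrom=locus.chrom,
        pos=locus.pos,
        ref_base=locus.ref_base,
        tallies=tallies,
        depth=depth,
    )


def simulate_counts(
    events: Sequence[PhasedEvent],
    truth: Sequence[GroundTruthRecord],
    config: SimulationConfig,
) -> list[LocusCounts]:
    """Draw pileup-style allele counts at every phased locus."""
    config.validate()
    truth_map = {t.gene_id: t for t in truth}
    rng = _rng(config, _STAGE_COUNTS)
    out: list[LocusCounts] = []
    for event in events:
        record = truth_map.get(event.gene_id)
        if record is None:
            raise ConsistencyError(f"{event.gene_id}: no ground-truth record")
        p1 = _hap1_probability(record)
        for locus in event.loci:
            out.append(
                _draw_locus_counts(rng, locus, p1, config.mean_depth, config.error_rate)
            )
    return out


def generate_peak_track(
    events: Sequence[PhasedEvent],
    mark_name: str,
    tissue: str,
    coverage_fraction: float,
    seed: int,
    sample: str = "s1",
) -> PeakSet:
    """Build a peak track hitting ~``coverage_fraction`` of the event regions.

    Selected events get one peak overlapping their haplotype region (with a
    random flank); intervals are merged per chromosome so the track is
    sorted and non-overlapping. Mark names are free-form labels.
    """
    if not 0.0 <= coverage_fraction <= 1.0:
        raise ConfigurationError("coverage_fraction must lie in [0, 1]")
    rng = np.random.default_rng([seed, zlib.crc32(mark_name.encode())])
    raw: dict[str, list[tuple[int, int]]] = {}
    for event in events:
        if rng.random() >= coverage_fraction:
            continue
        chrom, first, last = event.region
        pad_left = int(rng.integers(0, 300))
        pad_right = int(rng.integers(1, 300))
        start0 = max(0, first - 1 - pad_left)
        end0 = last + pad_right
        raw.setdefault(chrom, []).append((start0, end0))
    intervals: list[tuple[str, int, int]] = []
    for chrom in sorted(raw):
        merged: list[list[int]] = []
        for s, e in sorted(raw[chrom]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        intervals.extend((chrom, s, e) for s, e in merged)
    return PeakSet(mark=mark_name, tissue=tissue, sample=sample, intervals=intervals)


def generate_validation_cohort(
    discovery_loci: Sequence[HetLocus],
    truth: Sequence[GroundTruthRecord],
    config: SimulationConfig,
) -> tuple[dict[str, list[LocusCounts]], dict[str, set[tuple[str, int]]]]:
    """Simulate the replication cohort at the discovery loci.

    Each of ``n_samples`` animals is heterozygous at a discovery locus with
    probability ``het_rate``; at retained loci counts are drawn with the same
    haplotype-1 probability as discovery, so truly imbalanced loci replicate
    with a concordant direction by construction. Returns per-sample counts
    and the per-sample heterozygosity mask (as sets of (chrom, pos)).
    """
    config.validate()
    if not discovery_loci:
        raise ConfigurationError("discovery loci must be nonempty")
    truth_map = {t.gene_id: t for t in truth}
    for locus in discovery_loci:
        if locus.gene_id not in truth_map:
            raise ConsistencyError(f"{locus.gene_id}: no ground-truth record")
    rng = _rng(config, _STAGE_COHORT)
    counts: dict[str, list[LocusCounts]] = {}
    masks: dict[str, set[tuple[str, int]]] = {}
    for s in range(config.n_samples):
        sample_id = f"V{s + 1:03d}"
        sample_counts: list[LocusCounts] = []
        mask: set[tuple[str, int]] = set()
        for locus in discovery_loci:
            if rng.random() >= config.het_rate:
                continue
            mask.add((locus.chrom, locus.pos))
            p1 = _hap1_probability(truth_map[locus.gene_id])
            sample_counts.append(
                _draw_locus_counts(rng, locus, p1, config.mean_depth, config.error_rate)
            )
        counts[sample_id] = sample_counts
        masks[sample_id] = mask
    return counts, masks


def generate_transcript_models(
    events: Sequence[PhasedEvent],
    config: SimulationConfig,
    noncoding_fraction: float = 0.05,
    two_exon_fraction: float = 0.3,
) -> list[TranscriptModel]:
    """One toy transcript per gene, covering its loci.

    The exon span pads the locus region by a few hundred bp; coding
    transcripts carry a CDS (length divisible by 3) inside the exon span so
    loci fall in UTRs or codons, and a fraction of transcripts are split into
    two exons so some loci land in introns or splice regions.
    """
    rng = _rng(config, _STAGE_TRANSCRIPTS)
    models: list[TranscriptModel] = []
    for event in events:
        chrom, first, last = event.region
        tx_start = max(1, first - int(rng.integers(150, 400)))
        tx_end = last + int(rng.integers(150, 400))
        strand = "+" if rng.random() < 0.5 else "-"
        exons: tuple[tuple[int, int], ...]
        if rng.random() < two_exon_fraction and tx_end - tx_start > 400:
            cut = int(rng.integers(tx_start + 100, tx_end - 100))
            intron_len = int(rng.integers(60, 200))
            exons = ((tx_start, cut), (min(cut + 1 + intron_len, tx_end - 1), tx_end))
        else:
            exons = ((tx_start, tx_end),)
        if rng.random() < noncoding_fraction:
            cds: tuple[tuple[int, int], ...] = ()
        else:
            # CDS inside the exon span, in coding coordinates, length % 3 == 0
            exonic = []
            for s, e in exons:
                exonic.extend(range(s, e + 1))
            n_exonic = len(exonic)
            utr5 = int(rng.integers(30, max(31, n_exonic // 4)))
            utr3 = int(rng.integers(30, max(31, n_exonic // 4)))
            cds_len = n_exonic - utr5 - utr3
            cds_len -= cds_len % 3
            if cds_len < 6:
                utr5 = utr3 = 3
                cds_len = n_exonic - 6 - (n_exonic - 6) % 3
            cds_positions = exonic[utr5 : utr5 + cds_len]
            # contiguous runs of genomic positions -> CDS blocks
            blocks: list[list[int]] = []
            for p in cds_positions:
                if blocks and p == blocks[-1][1] + 1:
                    blocks[-1][1] = p
                else:
                    blocks.append([p, p])
            cds = tuple((s, e) for s, e in blocks)
        models.append(
            TranscriptModel(
                transcript_id=f"{event.gene_id}.t1",
                gene_id=event.gene_id,
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds=cds,
            )
        )
    return models


class SyntheticReference:
    """Deterministic random reference sequence pinned to the simulated loci.

    Bases are drawn lazily per chromosome from the config seed; at every
    phased locus the base is overwritten with the locus's reference allele so
    VCF/pileup/codon views of the genome agree.
    """

    def __init__(self, events: Sequence[PhasedEvent], config: SimulationConfig,
                 chrom_length: int = 2_000_000) -> None:
        self._config = config
        self._chrom_length = chrom_length
        self._pinned: dict[str, dict[int, str]] = {}
        for event in events:
            store = self._pinned.setdefault(event.chrom, {})
            for locus in event.loci:
                store[locus.pos] = locus.ref_base
        self._cache: dict[str, np.ndarray] = {}

    def _chromosome(self, chrom: str) -> np.ndarray:
        if chrom not in self._cache:
            rng = np.random.default_rng(
                [self._config.seed, _STAGE_REFERENCE, zlib.crc32(chrom.encode())]
            )
            seq = rng.integers(0, 4, size=self._chrom_length, dtype=np.int8)
            arr = np.array([ord(b) for b in NUCLEOTIDES], dtype=np.uint8)[seq]
            for pos, base in self._pinned.get(chrom, {}).items():
                if pos <= self._chrom_length:
                    arr[pos - 1] = ord(base)
            self._cache[chrom] = arr
        return self._cache[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence for the 1-based inclusive interval [start, end]."""
        if start < 1 or end < start:
            raise ValueError(f"bad interval {chrom}:{start}-{end}")
        return self._chromosome(chrom)[start - 1 : end].tobytes().decode("ascii")


def generate_pathway_map(
    gene_ids: Sequence[str],
    n_pathways: int = 20,
    mean_size: float = 25.0,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random pathway->gene-set membership over the simulated genes."""
    rng = np.random.default_rng([seed, _STAGE_PATHWAYS])
    pathways: dict[str, set[str]] = {}
    ids = list(gene_ids)
    for i in range(n_pathways):
        size = min(len(ids), max(2, int(rng.poisson(mean_size))))
        members = rng.choice(len(ids), size=size, replace=False)
        pathways[f"path{i:03d}"] = {ids[j] for j in members}
    return pathways


# --------------------------------------------------------------------------
# Text writers for the generated artifacts. Readers for these formats live in
# formats_io; the writers sit here because only the generator produces them.
# --------------------------------------------------------------------------

def write_phased_vcf(events: Sequence[PhasedEvent], path: str | Path) -> None:
    """Phased biallelic SNPs, one per locus; GT is 0|1 or 1|0 depending on
    which haplotype carries the reference allele; PS groups a gene's loci."""
    chroms = sorted({e.chrom for e in events})
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene identifier">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">',
    ]
    lines += [f"##contig=<ID={c},length=2500000>" for c in chroms]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample")
    records = []
    for event in events:
        for locus in event.loci:
            gt = "0|1" if locus.ref_base == locus.hap1_base else "1|0"
            records.append(
                (
                    locus.chrom,
                    locus.pos,
                    f"{locus.chrom}\t{locus.pos}\t.\t{locus.ref_base}\t"
                    f"{locus.alt_base}\t.\tPASS\tGENE={locus.gene_id}\tGT:PS\t"
                    f"{gt}:{locus.phase_set}",
                )
            )
    records.sort(key=lambda r: (chroms.index(r[0]), r[1]))
    lines.extend(r[2] for r in records)
    Path(path).write_text("\n".join(lines) + "\n")


def write_mpileup(counts: Sequence[LocusCounts], path: str | Path,
                  quality_char: str = "I") -> None:
    """Six-column samtools-mpileup text: reference-matching reads as '.',
    mismatches as uppercase base letters, one quality char per read."""
    lines = []
    for lc in sorted(counts, key=lambda c: (c.chrom, c.pos)):
        bases = []
        for base in sorted(lc.tallies):
            n = lc.tallies[base]
            bases.append(("." if base == lc.ref_base else base) * n)
        base_str = "".join(bases)
        n_reads = len(base_str)
        lines.append(
            f"{lc.chrom}\t{lc.pos}\t{lc.ref_base}\t{n_reads}\t"
            f"{base_str if n_reads else '*'}\t"
            f"{quality_char * n_reads if n_reads else '*'}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_bed_peaks(peak_sets: Sequence[PeakSet], path: str | Path) -> None:
    """BED3+3: chrom, start, end, mark, tissue, sample."""
    lines = []
    for ps in peak_sets:
        for chrom, start, end in ps.intervals:
            lines.append(f"{chrom}\t{start}\t{end}\t{ps.mark}\t{ps.tissue}\t{ps.sample}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_gtf(models: Sequence[TranscriptModel], path: str | Path,
              source: str = "haplase_sim") -> None:
    lines = []
    for m in models:
        attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
        lines.append(
            f"{m.chrom}\t{source}\ttranscript\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t{attrs}"
        )
        for s, e in m.exons:
            lines.append(f"{m.chrom}\t{source}\texon\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}")
        for s, e in m.cds:
            lines.append(f"{m.chrom}\t{source}\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t{attrs}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_truth_tsv(truth: Sequence[GroundTruthRecord], path: str | Path) -> None:
    lines = ["gene_id\tis_ase\ttrue_fold_change\tfavored_haplotype"]
    for t in truth:
        lines.append(
            f"{t.gene_id}\t{int(t.is_ase)}\t{t.true_fold_change}\t{t.favored_haplotype}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_pathways_tsv(pathways: Mapping[str, set[str]], path: str | Path) -> None:
    lines = ["pathway_id\tgene_id"]
    for pid in sorted(pathways):
        for gid in sorted(pathways[pid]):
            lines.append(f"{pid}\t{gid}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_dataset(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full fixture set; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events, truth = generate_phased_transcriptome(config)
    counts = simulate_counts(events, truth, config)
    models = generate_transcript_models(events, config)
    marks = {"H3K27ac": 0.55, "H3K4me3": 0.43, "H3K4me1": 0.39, "H3K27me3": 0.25}
    peaks = [
        generate_peak_track(events, mark, config.tissue, frac, config.seed,
                            sample=config.sample)
        for mark, frac in marks.items()
    ]
    pathways = generate_pathway_map([e.gene_id for e in events], seed=config.seed)
    files = {
        "vcf": outdir / "loci.vcf",
        "pileup": outdir / "counts.pileup",
        "bed": outdir / "peaks.bed",
        "gtf": outdir / "transcripts.gtf",
        "truth": outdir / "truth.tsv",
        "pathways": outdir / "pathways.tsv",
    }
    write_phased_vcf(events, files["vcf"])
    write_mpileup(counts, files["pileup"])
    write_bed_peaks(peaks, files["bed"])
    write_gtf(models, files["gtf"])
    write_truth_tsv(truth, files["truth"])
    write_pathways_tsv(pathways, files["pathways"])
    return files
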