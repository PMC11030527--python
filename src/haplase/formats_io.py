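"""Readers and writers for the standard formats the pipeline touches.

Conventions, stated once and enforced here so no other module converts
coordinates: VCF, GTF and pileup positions are 1-based (GTF intervals
inclusive); BED intervals are 0-based half-open. TSV round-trips through
:func:`events_to_frame` / :func:`frame_to_events` are lossless, with
infinite aeFC values stored as +/-1e9 sentinels plus a flag column.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import ParseError
from .model import (
    NUCLEOTIDES,
    ASEEvent,
    GroundTruthRecord,
    HetLocus,
    LocusCounts,
    PeakSet,
    PhasedEvent,
    TranscriptModel,
    ValidationRecord,
)
from .ase_stats import aefc_from_sentinel, aefc_to_sentinel

logger = logging.getLogger(__name__)

#: samtools' own default base-quality floor for mpileup counting.
DEFAULT_MIN_BASE_QUALITY = 13


# ---------------------------------------------------------------- VCF ------

def read_phased_vcf(path: str | Path) -> list[PhasedEvent]:
    """Load phased heterozygous SNPs grouped into per-gene events.

    Keeps biallelic SNP records whose genotype is a phased het (``0|1`` or
    ``1|0``); ``1|0`` swaps the haplotype assignment. Unphased hets are
    skipped with a warning. Records are grouped by the PS (phase set) format
    tag, falling back to the GENE info tag.
    """
    path = Path(path)
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"{path}: not a readable VCF: {exc}") from exc
    groups: dict[tuple[str, str], list[HetLocus]] = {}
    with vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ParseError(f"{path}: VCF carries no genotype sample column")
        sample = samples[0]
        try:
            for rec in vcf:
                if rec.alts is None or len(rec.alts) != 1:
                    continue
                ref, alt = rec.ref, rec.alts[0]
                if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
                    continue  # indel or symbolic allele
                call = rec.samples[sample]
                gt = call.get("GT")
                if gt is None or len(gt) != 2 or None in gt:
                    continue
                if sorted(gt) != [0, 1]:
                    continue  # homozygous or multi-allelic genotype
                if not call.phased:
                    logger.warning(
                        "%s:%d: unphased heterozygote skipped", rec.chrom, rec.pos
                    )
                    continue
                hap1, hap2 = (ref, alt) if gt[0] == 0 else (alt, ref)
                gene = str(rec.info.get("GENE", "") or "")
                ps = call.get("PS")
                key = str(ps) if ps is not None else gene
                if not key:
                    key = f"{rec.chrom}:{rec.pos}"
                groups.setdefault((rec.chrom, key), []).append(
                    HetLocus(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        hap1_base=hap1,
                        hap2_base=hap2,
                        gene_id=gene or key,
                        phase_set=key,
                        ref_base=ref,
                    )
                )
        except (OSError, ValueError) as exc:
            raise ParseError(f"{path}: malformed VCF record: {exc}") from exc
    events = []
    for (chrom, _key), loci in groups.items():
        loci = sorted(loci, key=lambda l: l.pos)
        events.append(PhasedEvent(gene_id=loci[0].gene_id, chrom=chrom, loci=tuple(loci)))
    events.sort(key=lambda e: (e.chrom, e.loci[0].pos))
    return events


# ------------------------------------------------------------- mpileup -----

_PILEUP_MARKUP_START = "^"
_PILEUP_READ_END = "$"


def decode_pileup_bases(
    bases: str,
    qualities: str,
    ref_base: str,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    context: str = "",
) -> dict[str, int]:
    """Decode one pileup base string into per-nucleotide tallies.

    Grammar handled: ``.``/``,`` count toward the reference base; letters
    toward that base, case-folded; ``^X`` consumes the mapping-quality
    character; ``$`` is markup; ``+n<seq>``/``-n<seq>`` indel runs are
    consumed without counting; ``*``/``#`` (deleted base) and ``>``/``<``
    (reference skip) consume a quality character but tally nothing. Bases
    whose Phred quality (ASCII-33) is below ``min_base_quality`` are dropped.
    """
    reads: list[str | None] = []
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == _PILEUP_MARKUP_START:
            if i + 1 >= n:
                raise ParseError(f"{context}: dangling '^' in pileup bases")
            i += 2
        elif c == _PILEUP_READ_END:
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise ParseError(f"{context}: indel marker without length")
            run = int(bases[i + 1 : j])
            if j + run > n:
                raise ParseError(f"{context}: indel run exceeds base string")
            i = j + run
        elif c in ".,":
            reads.append(ref_base.upper())
            i += 1
        elif c in "*#><":
            reads.append(None)  # deletion or reference skip: depth, no base
            i += 1
        elif c.upper() in "ACGTN":
            reads.append(c.upper())
            i += 1
        else:
            raise ParseError(f"{context}: unexpected pileup character {c!r}")
    if len(reads) != len(qualities):
        raise ParseError(
            f"{context}: decoded {len(reads)} read bases but "
            f"{len(qualities)} quality characters"
        )
    tallies: dict[str, int] = {}
    for base, q in zip(reads, qualities):
        if base is None or base == "N":
            continue
        if ord(q) - 33 < min_base_quality:
            continue
        tallies[base] = tallies.get(base, 0) + 1
    return tallies


def read_mpileup(
    path: str | Path,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> list[LocusCounts]:
    """Parse six-column samtools-mpileup text into per-locus tallies."""
    path = Path(path)
    out: list[LocusCounts] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            chrom, pos_s, ref, depth_s, bases, quals = fields[:6]
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer pos/depth") from exc
            if depth == 0:
                tallies: dict[str, int] = {}
            else:
                tallies = decode_pileup_bases(
                    bases, quals, ref, min_base_quality,
                    context=f"{path}:{lineno} ({chrom}:{pos})",
                )
            out.append(LocusCounts(chrom=chrom, pos=pos, ref_base=ref.upper(),
                                   tallies=tallies, depth=depth))
    return out


# ----------------------------------------------------------------- BED -----

def read_bed_peaks(path: str | Path) -> list[PeakSet]:
    """BED3+3 (chrom, start, end, mark, tissue, sample) -> PeakSets."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "mark", "tissue", "sample"],
            dtype={"chrom": str, "mark": str, "tissue": str, "sample": str},
        )
    except pd.errors.EmptyDataError:
        return []
    except ValueError as exc:
        raise ParseError(f"{path}: malformed BED: {exc}") from exc
    if df["start"].lt(0).any() or df["end"].le(df["start"]).any():
        bad = df[(df["start"] < 0) | (df["end"] <= df["start"])].iloc[0]
        raise ParseError(
            f"{path}: bad interval {bad['chrom']}:{bad['start']}-{bad['end']}"
        )
    peak_sets = []
    for (mark, tissue, sample), grp in df.groupby(["mark", "tissue", "sample"], sort=True):
        intervals = [
            (str(r.chrom), int(r.start), int(r.end)) for r in grp.itertuples()
        ]
        peak_sets.append(PeakSet(mark=mark, tissue=tissue, sample=sample,
                                 intervals=intervals))
    return peak_sets


# ----------------------------------------------------------------- GTF -----

def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Load transcript models (exons + CDS, 1-based inclusive) from GTF2.2."""
    import gffutils

    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise ParseError(f"{path}: malformed GTF: {exc}") from exc
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    for ftype, store in (("exon", exons), ("CDS", cds)):
        for feat in db.features_of_type(ftype):
            tid = feat.attributes.get("transcript_id", [""])[0]
            gid = feat.attributes.get("gene_id", [tid])[0]
            if not tid:
                raise ParseError(f"{path}: {ftype} without transcript_id")
            if feat.start < 1 or feat.end < feat.start:
                raise ParseError(f"{path}: bad {ftype} span {feat.start}-{feat.end}")
            store.setdefault(tid, []).append((feat.start, feat.end))
            meta.setdefault(tid, (gid, feat.seqid, feat.strand))
    models = []
    for tid, ex in exons.items():
        gid, chrom, strand = meta[tid]
        models.append(
            TranscriptModel(
                transcript_id=tid, gene_id=gid, chrom=chrom,
                strand=strand if strand in "+-" else "+",
                exons=tuple(sorted(ex)),
                cds=tuple(sorted(cds.get(tid, []))),
            )
        )
    models.sort(key=lambda m: (m.chrom, m.start, m.transcript_id))
    return models


# ----------------------------------------------------------------- TSV -----

EVENT_COLUMNS = [
    "gene_id", "tissue", "sample", "allele1_exp", "allele2_exp",
    "aefc", "aefc_infinite", "p_value", "adj_p",
    "prefilter_pass", "significant", "chrom", "start", "end",
]


def events_to_frame(events: Iterable[ASEEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "gene_id": e.gene_id, "tissue": e.tissue, "sample": e.sample,
                "allele1_exp": e.allele1_exp, "allele2_exp": e.allele2_exp,
                "aefc": aefc_to_sentinel(e.aefc),
                "aefc_infinite": int(math.isinf(e.aefc)),
                "p_value": e.p_value, "adj_p": e.adj_p,
                "prefilter_pass": int(e.prefilter_pass),
                "significant": int(e.significant),
                "chrom": e.chrom, "start": e.start, "end": e.end,
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def frame_to_events(df: pd.DataFrame) -> list[ASEEvent]:
    events = []
    for r in df.itertuples():
        events.append(
            ASEEvent(
                gene_id=str(r.gene_id), tissue=str(r.tissue), sample=str(r.sample),
                allele1_exp=int(r.allele1_exp), allele2_exp=int(r.allele2_exp),
                aefc=aefc_from_sentinel(float(r.aefc)),
                p_value=float(r.p_value), adj_p=float(r.adj_p),
                prefilter_pass=bool(r.prefilter_pass),
                significant=bool(r.significant),
                chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            )
        )
    return events


VALIDATION_COLUMNS = [
    "chrom", "pos", "sample_id", "allele1_count", "allele2_count",
    "aefc", "aefc_infinite", "p_value", "adj_p", "significant", "direction",
]


def validation_to_frame(records: Iterable[ValidationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "chrom": r.chrom, "pos": r.pos, "sample_id": r.sample_id,
                "allele1_count": r.allele1_count, "allele2_count": r.allele2_count,
                "aefc": aefc_to_sentinel(r.aefc),
                "aefc_infinite": int(math.isinf(r.aefc)),
                "p_value": r.p_value, "adj_p": r.adj_p,
                "significant": int(r.significant), "direction": r.direction,
            }
        )
    return pd.DataFrame(rows, columns=VALIDATION_COLUMNS)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_truth_tsv(path: str | Path) -> list[GroundTruthRecord]:
    df = read_tsv(path)
    return [
        GroundTruthRecord(
            gene_id=str(r.gene_id), is_ase=bool(r.is_ase),
            true_fold_change=float(r.true_fold_change),
            favored_haplotype=int(r.favored_haplotype),
        )
        for r in df.itertuples()
    ]


def read_pathways_tsv(path: str | Path) -> dict[str, set[str]]:
    df = read_tsv(path)
    out: dict[str, set[str]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.pathway_id), set()).add(str(r.gene_id))
    return out


def bed_to_one_based(interval: tuple[str, int, int]) -> tuple[str, int, int]:
    """(chrom, start0, end0) half-open -> (chrom, start1, end1) inclusive."""
    chrom, start, end = interval
    return (chrom, start + 1, end)


def one_based_to_bed(interval: tuple[str, int, int]) -> tuple[str, int, int]:
    chrom, start, end = interval
    return (chrom, start - 1, end)
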