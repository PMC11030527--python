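"""Histone-mark peak overlap for ASE event regions.

Each event's haplotype region (first to last heterozygous position, 1-based
inclusive; single-locus events span 1 bp) is intersected with every peak
track of the matching tissue (and sample, by default). A mark is "hit" when
at least one base pair of the region falls inside at least one of its peaks
— no reciprocal-fraction requirement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .model import ASEEvent, MarkOverlap, PeakSet

logger = logging.getLogger(__name__)

HISTONE_MARKS = ("H3K27ac", "H3K4me1", "H3K4me3", "H3K27me3")


def _track_key(ps: PeakSet, same_sample: bool) -> tuple:
    return (ps.tissue, ps.sample) if same_sample else (ps.tissue,)


def _event_key(e: ASEEvent, same_sample: bool) -> tuple:
    return (e.tissue, e.sample) if same_sample else (e.tissue,)


def overlap_events(
    events: Sequence[ASEEvent],
    peaks: Sequence[PeakSet],
    same_sample: bool = True,
) -> list[MarkOverlap]:
    """Intersect event regions with peak tracks, matched on tissue(/sample)."""
    trees: dict[tuple, dict[tuple[str, str], IntervalTree]] = {}
    for ps in peaks:
        marks = trees.setdefault(_track_key(ps, same_sample), {})
        for chrom, start, end in ps.intervals:
            marks.setdefault((ps.mark, chrom), IntervalTree()).addi(start, end)
    missing_tracks: set[tuple] = set()
    overlaps: list[MarkOverlap] = []
    for e in events:
        key = _event_key(e, same_sample)
        marks = trees.get(key)
        hit: set[str] = set()
        if marks is None:
            if key not in missing_tracks:
                logger.info("no peak track for %s; marks_hit empty", key)
                missing_tracks.add(key)
        else:
            start0, end0 = e.start - 1, e.end  # 1-based inclusive -> half-open
            for (mark, chrom), tree in marks.items():
                if chrom == e.chrom and tree.overlaps(start0, end0):
                    hit.add(mark)
        overlaps.append(
            MarkOverlap(
                gene_id=e.gene_id, tissue=e.tissue, sample=e.sample,
                marks_hit=frozenset(hit),
                chrom=e.chrom, start=e.start, end=e.end,
            )
        )
    return overlaps


@dataclass
class CombinationSummary:
    """Upset-style tabulation of mark co-occurrence at event regions."""

    n_events: int
    combinations: pd.DataFrame  # columns: marks, count (exact combinations)
    marginals: dict[str, int]  # per-mark totals over all events
    n_any_mark: int
    pct_any_mark: float  # of all events
    n_multi_mark: int
    pct_multi_mark: float  # of events with >= 1 mark


def combination_table(overlaps: Iterable[MarkOverlap]) -> CombinationSummary:
    """Exact-combination counts, per-mark marginals, any-/multi-mark rates."""
    overlaps = list(overlaps)
    combos: dict[frozenset[str], int] = {}
    marginals: dict[str, int] = {}
    for o in overlaps:
        combos[o.marks_hit] = combos.get(o.marks_hit, 0) + 1
        for m in o.marks_hit:
            marginals[m] = marginals.get(m, 0) + 1
    n = len(overlaps)
    n_any = sum(c for k, c in combos.items() if k)
    n_multi = sum(c for k, c in combos.items() if len(k) >= 2)
    rows = [
        {"marks": " & ".join(sorted(k)) if k else "(none)", "count": c}
        for k, c in combos.items()
    ]
    df = pd.DataFrame(rows, columns=["marks", "count"]).sort_values(
        ["count", "marks"], ascending=[False, True], ignore_index=True
    )
    return CombinationSummary(
        n_events=n,
        combinations=df,
        marginals=marginals,
        n_any_mark=n_any,
        pct_any_mark=round(100.0 * n_any / n, 1) if n else 0.0,
        n_multi_mark=n_multi,
        pct_multi_mark=round(100.0 * n_multi / n_any, 1) if n_any else 0.0,
    )
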