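"""Allelic-imbalance statistics.

The imbalance statistic is the allele expression fold change

    aeFC = log2(allele1) - log2(allele2)

computed on haplotype-aggregated read counts, supported by an exact two-sided
binomial test of the equal-expression null (success probability 0.5 on
n = allele1 + allele2 trials) with Benjamini-Hochberg FDR control across the
tested family. An event is called significant when all three hold:

    |aeFC| >= fc_min  (default 2),
    BH-adjusted p <= alpha  (default 0.05),
    max(allele1, allele2) >= exp_min  (default 5).

Events where neither allele reaches ``min_count`` reads (default 10) are
excluded before testing.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .model import AEFC_INF_SENTINEL, ASEEvent, HaplotypeExpression

__all__ = [
    "prefilter",
    "aefc",
    "binomial_test",
    "bh_adjust",
    "classify",
    "test_events",
]


def prefilter(allele1_exp: int, allele2_exp: int, min_count: int = 10) -> bool:
    """True iff at least one allele's aggregated count reaches ``min_count``."""
    return max(allele1_exp, allele2_exp) >= min_count


def aefc(allele1_exp: float, allele2_exp: float) -> float:
    """log2 allele-expression fold change.

    Returns a signed infinity when exactly one count is zero and NaN when
    both are; neither raises, so callers can filter on the sentinel.
    """
    if allele1_exp < 0 or allele2_exp < 0:
        raise ValidationError("allele counts must be non-negative")
    if allele1_exp == 0 and allele2_exp == 0:
        return math.nan
    if allele2_exp == 0:
        return math.inf
    if allele1_exp == 0:
        return -math.inf
    return math.log2(allele1_exp) - math.log2(allele2_exp)


def binomial_test(allele1_exp: int, allele2_exp: int, p: float = 0.5) -> float:
    """Two-sided exact binomial p-value for the equal-expression null.

    ``p`` is the null success probability of an allele-1 read (0.5 unless a
    reference-bias correction is supplied). The two-sided mass sums all
    outcomes whose probability does not exceed that of the observed one.
    """
    n = allele1_exp + allele2_exp
    if n < 1:
        raise ValidationError("binomial test needs at least one read")
    return stats.binomtest(allele1_exp, n, p=p, alternative="two-sided").pvalue


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify(
    aefc_value: float,
    adj_p: float,
    allele1_exp: int,
    allele2_exp: int,
    fc_min: float = 2.0,
    alpha: float = 0.05,
    exp_min: int = 5,
) -> bool:
    """Apply the three-part significance rule; infinite aeFC passes fc_min."""
    if math.isnan(aefc_value):
        return False
    return (
        abs(aefc_value) >= fc_min
        and adj_p <= alpha
        and max(allele1_exp, allele2_exp) >= exp_min
    )


def test_events(
    expressions: Iterable[HaplotypeExpression],
    min_count: int = 10,
    fc_min: float = 2.0,
    alpha: float = 0.05,
    exp_min: int = 5,
    null_p: float = 0.5,
    bh_scope: str = "dataset",
) -> list[ASEEvent]:
    """Run the full cascade: prefilter -> aeFC -> binomial -> BH -> classify.

    ``bh_scope`` chooses the BH family: ``"dataset"`` adjusts within each
    (sample, tissue) group, ``"global"`` across all prefiltered events.
    Events failing the prefilter are returned with ``prefilter_pass=False``,
    ``adj_p=1`` and no significance call, so attrition is auditable.
    """
    if bh_scope not in ("dataset", "global"):
        raise ValidationError(f"unknown bh_scope {bh_scope!r}")
    expressions = list(expressions)
    events: list[ASEEvent] = []
    tested_idx: list[int] = []
    raw_p: list[float] = []
    for i, e in enumerate(expressions):
        passed = prefilter(e.allele1_exp, e.allele2_exp, min_count)
        fc = aefc(e.allele1_exp, e.allele2_exp)
        if passed:
            tested_idx.append(i)
            raw_p.append(binomial_test(e.allele1_exp, e.allele2_exp, p=null_p))
        events.append(
            ASEEvent(
                gene_id=e.gene_id,
                tissue=e.tissue,
                sample=e.sample,
                allele1_exp=e.allele1_exp,
                allele2_exp=e.allele2_exp,
                aefc=fc,
                p_value=math.nan,
                adj_p=1.0,
                prefilter_pass=passed,
                significant=False,
                chrom=e.chrom,
                start=e.start,
                end=e.end,
            )
        )

    if not tested_idx:
        return events

    # BH within each family, then classify.
    if bh_scope == "global":
        families: dict[tuple, list[int]] = {(): list(range(len(tested_idx)))}
    else:
        families = {}
        for j, i in enumerate(tested_idx):
            key = (expressions[i].sample, expressions[i].tissue)
            families.setdefault(key, []).append(j)
    raw = np.asarray(raw_p)
    adj = np.empty_like(raw)
    for members in families.values():
        adj[members] = bh_adjust(raw[members])
    for j, i in enumerate(tested_idx):
        ev = events[i]
        ev.p_value = float(raw[j])
        ev.adj_p = float(adj[j])
        ev.significant = classify(
            ev.aefc, ev.adj_p, ev.allele1_exp, ev.allele2_exp,
            fc_min=fc_min, alpha=alpha, exp_min=exp_min,
        )
    return events


def aefc_to_sentinel(value: float) -> float:
    """Map +/-inf to the +/-1e9 TSV sentinel (NaN passes through)."""
    if math.isinf(value):
        return math.copysign(AEFC_INF_SENTINEL, value)
    return value


def aefc_from_sentinel(value: float) -> float:
    """Inverse of :func:`aefc_to_sentinel`."""
    if abs(value) >= AEFC_INF_SENTINEL:
        return math.copysign(math.inf, value)
    return value
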