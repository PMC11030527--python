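"""Summary tables and pathway over-representation.

``tissue_summary`` reproduces the per-tissue comparison/ASE-count table;
``asdeg_matrix`` pivots significant events into a gene x (tissue, sample)
view and flags multi-context ASDEGs (genes with allele-specific expression
in more than one tissue or sample); ``enrich`` is a transparent one-sided
hypergeometric over-representation test used in place of an external
pathway service.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .ase_stats import bh_adjust
from .errors import ValidationError
from .model import ASEEvent, EnrichmentResult


def tissue_summary(events: Iterable[ASEEvent]) -> pd.DataFrame:
    """Per-tissue allele comparisons, ASE counts and percentages.

    A "comparison" is an event that passed the read-count prefilter. Rows
    are sorted by percentage descending, with a final "All" total row.
    """
    rows: dict[str, dict[str, int]] = {}
    for e in events:
        if not e.prefilter_pass:
            continue
        r = rows.setdefault(e.tissue, {"allele_comparisons": 0, "ase_count": 0})
        r["allele_comparisons"] += 1
        r["ase_count"] += int(e.significant)
    out = [
        {
            "tissue": tissue,
            "allele_comparisons": r["allele_comparisons"],
            "ase_count": r["ase_count"],
            "pct": round(100.0 * r["ase_count"] / r["allele_comparisons"], 2)
            if r["allele_comparisons"] else 0.0,
        }
        for tissue, r in rows.items()
    ]
    out.sort(key=lambda r: (-r["pct"], r["tissue"]))
    total_cmp = sum(r["allele_comparisons"] for r in out)
    total_ase = sum(r["ase_count"] for r in out)
    out.append(
        {
            "tissue": "All",
            "allele_comparisons": total_cmp,
            "ase_count": total_ase,
            "pct": round(100.0 * total_ase / total_cmp, 2) if total_cmp else 0.0,
        }
    )
    return pd.DataFrame(out, columns=["tissue", "allele_comparisons", "ase_count", "pct"])


def asdeg_matrix(events: Iterable[ASEEvent]) -> tuple[pd.DataFrame, list[str]]:
    """|aeFC| of significant events per gene x (tissue, sample).

    Returns the matrix (NaN where a gene has no significant event in a
    context) and the list of multi-context ASDEGs — genes significant in
    two or more (tissue, sample) contexts.
    """
    sig = [e for e in events if e.significant]
    if not sig:
        return pd.DataFrame(), []
    df = pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in sig],
            "tissue": [e.tissue for e in sig],
            "sample": [e.sample for e in sig],
            "abs_aefc": [abs(e.aefc) for e in sig],
        }
    )
    matrix = df.pivot_table(
        index="gene_id", columns=["tissue", "sample"], values="abs_aefc", aggfunc="max"
    )
    df["context"] = list(zip(df["tissue"], df["sample"]))
    n_contexts = df.groupby("gene_id")["context"].nunique()
    multi = sorted(n_contexts[n_contexts >= 2].index.tolist())
    return matrix, multi


def enrich(
    asdeg_genes: Iterable[str],
    pathway_map: Mapping[str, set[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
    bh: bool = False,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation per pathway.

    With a universe of M genes of which K belong to the pathway and an input
    list of n ASDEGs with k in the pathway, p = P(X >= k) for
    X ~ Hypergeom(M, K, n). Pathways with no universe genes are skipped.
    Raw p <= alpha flags significance; ``bh=True`` adjusts first.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValidationError("enrichment universe may not be empty")
    input_set = set(asdeg_genes) & universe_set
    results: list[EnrichmentResult] = []
    for pid in sorted(pathway_map):
        members = pathway_map[pid] & universe_set
        if not members:
            continue
        overlap = len(members & input_set)
        p = float(
            stats.hypergeom.sf(
                overlap - 1, len(universe_set), len(members), len(input_set)
            )
        )
        results.append(
            EnrichmentResult(
                pathway_id=pid,
                n_universe=len(universe_set),
                n_pathway=len(members),
                n_input=len(input_set),
                n_overlap=overlap,
                p_value=p,
                significant=False,
            )
        )
    p_final = [r.p_value for r in results]
    if bh and results:
        p_final = list(bh_adjust(p_final))
    for r, p in zip(results, p_final):
        r.significant = p <= alpha
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "n_universe": r.n_universe,
                "n_pathway": r.n_pathway,
                "n_input": r.n_input,
                "n_overlap": r.n_overlap,
                "p_value": r.p_value,
                "significant": int(r.significant),
            }
            for r in results
        ],
        columns=["pathway_id", "n_universe", "n_pathway", "n_input",
                 "n_overlap", "p_value", "significant"],
    )
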