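"""Hypergeometric pathway over-representation of a DEG set.

The background is the annotated universe (genes with at least one pathway
annotation), not all expressed genes: published tag-DGE enrichment tables
compute their percentages on annotated universes. With N annotated
background genes, K of them in a pathway, n annotated DEGs and k annotated
DEGs in the pathway, the enrichment p-value is the inclusive upper tail
P(X >= k) of Hypergeometric(N, K, n). Genes annotated to several pathways
count in each of them. Q-values are Benjamini–Hochberg over the tested
pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentInput:
    """Contingency for one pathway: universe N, pathway K, DEGs n, overlap k."""

    n_background: int
    k_pathway: int
    n_degs: int
    k_overlap: int

    def __post_init__(self) -> None:
        N, K, n, k = self.n_background, self.k_pathway, self.n_degs, self.k_overlap
        if not (0 <= k <= min(K, n) and K <= N and n <= N):
            raise ValueError(f"inconsistent contingency: N={N} K={K} n={n} k={k}")


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), inclusive."""
    EnrichmentInput(N, K, n, k)  # validate
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    deg_genes,
    annotation: pd.DataFrame,
    background_genes,
) -> pd.DataFrame:
    """Per-pathway over-representation table for a DEG set.

    ``annotation`` needs columns gene_id and pathway_id (pathway_name
    optional). Genes outside the annotated background are ignored on both
    sides; an empty annotated DEG set yields an empty table with a warning.
    Rows are sorted by ascending p-value.
    """
    required = {"gene_id", "pathway_id"}
    if not required.issubset(annotation.columns):
        raise ValueError(f"annotation needs columns {sorted(required)}")
    background = set(background_genes)
    ann = annotation[annotation["gene_id"].isin(background)]
    annotated = set(ann["gene_id"])
    degs = set(deg_genes) & annotated
    N = len(annotated)
    n = len(degs)
    columns = [
        "pathway_id",
        "pathway_name",
        "k",
        "n",
        "K",
        "N",
        "pct_degs",
        "pct_background",
        "pvalue",
        "qvalue",
    ]
    if n == 0:
        logger.warning("no annotated DEGs; enrichment table is empty")
        return pd.DataFrame(columns=columns)
    names = (
        ann.groupby("pathway_id")["pathway_name"].first()
        if "pathway_name" in ann.columns
        else None
    )
    rows = []
    for pathway_id, members in ann.groupby("pathway_id")["gene_id"]:
        member_set = set(members)
        K = len(member_set)
        k = len(member_set & degs)
        rows.append(
            {
                "pathway_id": pathway_id,
                "pathway_name": names[pathway_id] if names is not None else pathway_id,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "pct_degs": 100.0 * k / n,
                "pct_background": 100.0 * K / N,
                "pvalue": hypergeom_upper_tail(N, K, n, k),
            }
        )
    table = pd.DataFrame(rows)
    table["qvalue"] = bh_adjust(table["pvalue"].to_numpy())
    return (
        table.sort_values("pvalue", kind="mergesort")
        .reset_index(drop=True)[columns]
    )
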