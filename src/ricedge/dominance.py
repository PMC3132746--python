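"""Hybrid expression-pattern classification against parental levels.

Each gene's hybrid (F1) TPM is compared to the mid-parent value
MP = (P1 + P2)/2, the high parent HP = max(P1, P2) and the low parent
LP = min(P1, P2):

    category 1 (below_mid):  log2(F1/MP) <= -t
    category 2 (additive):   |log2(F1/MP)| < t
    category 3 (above_mid):  log2(F1/MP) >= t
    category 4 (underdominant flag): log2(F1/LP) <= -t
    category 5 (overdominant flag):  log2(F1/HP) >= t

with threshold t = 1 by default and ties inclusive. Because LP <= MP <= HP,
overdominance implies above-mid and underdominance implies below-mid.

The optional significance gate reproduces the "comparable genes" notion:
a gene is comparable when the Audic–Claverie test of the hybrid library
against a constructed mid-parent pseudo-library (rounded average counts,
averaged library size) is significant at the FDR threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import DEFAULT_FDR, ac_pvalues, bh_adjust, floored_tpm
from .mapping import MappedCounts

CATEGORY_LABELS = {1: "below_mid", 2: "additive", 3: "above_mid"}


@dataclass(frozen=True)
class TrioExpression:
    gene_id: str
    tpm_p1: float
    tpm_p2: float
    tpm_f1: float


@dataclass(frozen=True)
class DominanceCall:
    gene_id: str
    category: str  # additive / above_mid / below_mid
    overdominant: bool
    underdominant: bool
    log2_vs_mid: float
    log2_vs_high: float
    log2_vs_low: float
    tested: bool = True


def classify_trio(trio: TrioExpression, threshold: float = 1.0) -> DominanceCall:
    """Classify one gene from (already floored) parent and hybrid TPMs."""
    df = classify_trios(
        pd.DataFrame(
            {
                "gene_id": [trio.gene_id],
                "tpm_p1": [trio.tpm_p1],
                "tpm_p2": [trio.tpm_p2],
                "tpm_f1": [trio.tpm_f1],
            }
        ),
        threshold=threshold,
    )
    row = df.iloc[0]
    return DominanceCall(
        gene_id=row["gene_id"],
        category=row["category"],
        overdominant=bool(row["overdominant"]),
        underdominant=bool(row["underdominant"]),
        log2_vs_mid=row["log2_vs_mid"],
        log2_vs_high=row["log2_vs_high"],
        log2_vs_low=row["log2_vs_low"],
        tested=bool(row["tested"]),
    )


def classify_trios(trios: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Vectorized classification of a trio TPM table.

    Expects columns gene_id, tpm_p1, tpm_p2, tpm_f1 (zero-floored TPM, same
    rule as the DE stage). Genes where all three TPMs are zero are flagged
    untestable (tested=False) and classified additive by convention.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    p1 = trios["tpm_p1"].to_numpy(dtype=float)
    p2 = trios["tpm_p2"].to_numpy(dtype=float)
    f1 = trios["tpm_f1"].to_numpy(dtype=float)
    if (p1 < 0).any() or (p2 < 0).any() or (f1 < 0).any():
        raise ValueError("TPM values must be non-negative")
    untestable = (p1 == 0) & (p2 == 0) & (f1 == 0)
    mp = (p1 + p2) / 2.0
    hp = np.maximum(p1, p2)
    lp = np.minimum(p1, p2)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_mid = np.log2(f1 / mp)
        log2_high = np.log2(f1 / hp)
        log2_low = np.log2(f1 / lp)
    category = np.where(
        log2_mid >= threshold,
        "above_mid",
        np.where(log2_mid <= -threshold, "below_mid", "additive"),
    )
    category = np.where(untestable, "additive", category)
    over = np.where(untestable, False, log2_high >= threshold)
    under = np.where(untestable, False, log2_low <= -threshold)
    out = pd.DataFrame(
        {
            "gene_id": trios["gene_id"].to_numpy(),
            "category": category,
            "overdominant": over,
            "underdominant": under,
            "log2_vs_mid": np.where(untestable, 0.0, log2_mid),
            "log2_vs_high": np.where(untestable, 0.0, log2_high),
            "log2_vs_low": np.where(untestable, 0.0, log2_low),
            "tested": ~untestable,
        }
    )
    return out


def midparent_pseudolibrary(p1: MappedCounts, p2: MappedCounts) -> MappedCounts:
    """Synthetic mid-parent library: rounded average counts and size."""
    genes = set(p1.counts) | set(p2.counts)
    counts = {
        g: int(round((p1.counts.get(g, 0) + p2.counts.get(g, 0)) / 2.0))
        for g in genes
    }
    size = int(round((p1.library_size + p2.library_size) / 2.0))
    return MappedCounts("midparent", counts, size)


def apply_significance_gate(
    p1: MappedCounts,
    p2: MappedCounts,
    f1: MappedCounts,
    fdr_threshold: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Audic–Claverie gate of the hybrid against the mid-parent library.

    Returns a per-gene table (gene_id, x_mid, y_f1, pvalue, qvalue,
    comparable). A gate threshold of 1.0 degenerates to "any counts".
    """
    mp = midparent_pseudolibrary(p1, p2)
    genes = sorted(set(mp.counts) | set(f1.counts))
    x = np.array([mp.counts.get(g, 0) for g in genes], dtype=np.int64)
    y = np.array([f1.counts.get(g, 0) for g in genes], dtype=np.int64)
    tested = (x + y) > 0
    pvals = np.ones(len(genes))
    pvals[tested] = ac_pvalues(x[tested], mp.library_size, y[tested], f1.library_size)
    qvals = np.ones(len(genes))
    qvals[tested] = bh_adjust(pvals[tested])
    return pd.DataFrame(
        {
            "gene_id": genes,
            "x_mid": x,
            "y_f1": y,
            "pvalue": np.where(tested, pvals, np.nan),
            "qvalue": np.where(tested, qvals, np.nan),
            "comparable": tested & (qvals <= fdr_threshold),
        }
    )


def classify_counts(
    p1: MappedCounts,
    p2: MappedCounts,
    f1: MappedCounts,
    threshold: float = 1.0,
    fdr_threshold: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Full trio classification from mapped counts.

    Combines floored-TPM ratio classification with the mid-parent
    significance gate; ``comparable`` marks genes passing the gate and
    ``nonadditive_call`` applies the DEG rule (gate AND ratio) used for
    calling a gene non-additively expressed.
    """
    genes = sorted(set(p1.counts) | set(p2.counts) | set(f1.counts))
    c1 = np.array([p1.counts.get(g, 0) for g in genes], dtype=np.int64)
    c2 = np.array([p2.counts.get(g, 0) for g in genes], dtype=np.int64)
    cf = np.array([f1.counts.get(g, 0) for g in genes], dtype=np.int64)
    trios = pd.DataFrame(
        {
            "gene_id": genes,
            "tpm_p1": floored_tpm(c1, p1.library_size),
            "tpm_p2": floored_tpm(c2, p2.library_size),
            "tpm_f1": floored_tpm(cf, f1.library_size),
        }
    )
    calls = classify_trios(trios, threshold=threshold)
    gate = apply_significance_gate(p1, p2, f1, fdr_threshold=fdr_threshold)
    calls = calls.merge(gate[["gene_id", "pvalue", "qvalue", "comparable"]], on="gene_id")
    calls["nonadditive_call"] = calls["comparable"] & (calls["category"] != "additive")
    return calls


def summarize_categories(calls: pd.DataFrame) -> dict:
    """Counts for the five figure categories (4 and 5 are flag subsets)."""
    if len(calls) == 0:
        return {1: 0, 2: 0, 3: 0, 4: 0, 5: 0}
    return {
        1: int((calls["category"] == "below_mid").sum()),
        2: int((calls["category"] == "additive").sum()),
        3: int((calls["category"] == "above_mid").sum()),
        4: int(calls["underdominant"].sum()),
        5: int(calls["overdominant"].sum()),
    }
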