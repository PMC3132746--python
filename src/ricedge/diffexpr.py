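"""Differential expression between two tag libraries (Audic–Claverie test).

Single-library tag counts have no replicate-based dispersion estimate; the
Audic–Claverie model treats the count of a gene in each library as Poisson
and conditions on the count x observed in library 1. With r = N2/N1 the
probability of seeing y tags in library 2 given x in library 1 is

    p(y | x) = r^y * (x + y)! / ( x! * y! * (1 + r)^(x + y + 1) )

which is a negative-binomial mass in y and sums to 1 over y >= 0. All
arithmetic is done in log space (log-gamma) and exponentiated at the end.

The two-sided p-value doubles the smaller tail (inclusive of y), capped at
one. Significance uses the tag-DGE convention: Benjamini–Hochberg FDR <=
0.001 and |log2 ratio| >= 1 on the TPM scale, with zero TPM floored at half
of one tag per million so that ratios stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .mapping import MappedCounts

DEFAULT_FDR = 0.001
DEFAULT_RATIO = 1.0


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    x: int
    y: int
    n1: int
    n2: int
    tpm1: float
    tpm2: float
    log2_ratio: float
    pvalue: float
    qvalue: float
    significant: bool


def _log_point(x: int, ys: np.ndarray, log_r: float, log_1pr: float) -> np.ndarray:
    return (
        ys * log_r
        + gammaln(x + ys + 1)
        - gammaln(x + 1)
        - gammaln(ys + 1)
        - (x + ys + 1) * log_1pr
    )


def ac_point_probability(x: int, n1: int, y: int, n2: int) -> float:
    """p(y | x): probability of y tags in library 2 given x in library 1."""
    if x < 0 or y < 0:
        raise ValueError("tag counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    r = n2 / n1
    return float(np.exp(_log_point(x, np.asarray([y]), np.log(r), np.log1p(r))[0]))


def ac_pvalue(x: int, n1: int, y: int, n2: int) -> float:
    """Two-sided Audic–Claverie p-value, 2*min(lower, upper) capped at 1.

    Lower tail sums p(k|x) for k <= y; the upper tail is computed as
    1 - (exclusive lower tail) to avoid an infinite summation. The test
    conditions on x, so swapping the libraries is only approximately
    symmetric (tight for large counts).
    """
    if x < 0 or y < 0:
        raise ValueError("tag counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    r = n2 / n1
    pk = np.exp(_log_point(x, np.arange(y + 1), np.log(r), np.log1p(r)))
    lower, upper = _tails(pk, y)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _tails(pk: np.ndarray, y: int) -> tuple[float, float]:
    # inclusive tails; the upper tail is at least the point mass at y,
    # which also guards against cancellation when the lower sum nears 1
    lower = min(pk.sum(), 1.0)
    upper = 1.0 - pk[:-1].sum() if y > 0 else 1.0
    return lower, max(upper, pk[-1])


def ac_pvalues(xs, n1: int, ys, n2: int) -> np.ndarray:
    """Vectorized two-sided p-values over paired count arrays."""
    xs = np.asarray(xs, dtype=np.int64)
    ys = np.asarray(ys, dtype=np.int64)
    if xs.min(initial=0) < 0 or ys.min(initial=0) < 0:
        raise ValueError("tag counts must be non-negative")
    r = n2 / n1
    log_r, log_1pr = np.log(r), np.log1p(r)
    out = np.empty(len(xs))
    for i, (x, y) in enumerate(zip(xs, ys)):
        pk = np.exp(_log_point(int(x), np.arange(y + 1), log_r, log_1pr))
        lower, upper = _tails(pk, int(y))
        out[i] = min(1.0, 2.0 * min(lower, upper))
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def floored_tpm(count: np.ndarray, library_size: int) -> np.ndarray:
    """TPM with zeros floored at half of one tag (0.5e6/N) for ratio use."""
    tpm = np.asarray(count, dtype=float) * 1e6 / library_size
    return np.maximum(tpm, 0.5e6 / library_size)


def call_degs(
    lib1: MappedCounts,
    lib2: MappedCounts,
    fdr_threshold: float = DEFAULT_FDR,
    ratio_threshold: float = DEFAULT_RATIO,
) -> pd.DataFrame:
    """Per-gene differential-expression table between two libraries.

    Genes with x + y = 0 carry no evidence and are excluded; the BH family
    is exactly the tested set. ``log2_ratio`` is log2(TPM2/TPM1) with the
    zero floor, so its sign follows library 2 relative to library 1.
    """
    genes = sorted(set(lib1.counts) | set(lib2.counts))
    if not genes:
        raise ValueError("empty gene universe")
    x = np.array([lib1.counts.get(g, 0) for g in genes], dtype=np.int64)
    y = np.array([lib2.counts.get(g, 0) for g in genes], dtype=np.int64)
    tested = (x + y) > 0
    genes = [g for g, t in zip(genes, tested) if t]
    x, y = x[tested], y[tested]
    n1, n2 = lib1.library_size, lib2.library_size
    tpm1 = floored_tpm(x, n1)
    tpm2 = floored_tpm(y, n2)
    log2_ratio = np.log2(tpm2 / tpm1)
    pvalues = ac_pvalues(x, n1, y, n2)
    qvalues = bh_adjust(pvalues)
    significant = (qvalues <= fdr_threshold) & (np.abs(log2_ratio) >= ratio_threshold)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "x": x,
            "y": y,
            "n1": n1,
            "n2": n2,
            "tpm1": x * 1e6 / n1,
            "tpm2": y * 1e6 / n2,
            "log2_ratio": log2_ratio,
            "pvalue": pvalues,
            "qvalue": qvalues,
            "significant": significant,
        }
    )
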