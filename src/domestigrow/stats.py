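"""Shared statistics: G-test, median-based Levene test, Pearson correlation, QC.

Thin, explicitly-typed wrappers around scipy's implementations, plus the small
count-based quality-control arithmetic used when filtering genotyped fish.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GTestResult:
    g: float
    df: int
    p: float


@dataclass(frozen=True)
class LeveneResult:
    f: float
    df1: int
    df2: int
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def g_test(observed: Sequence[float], expected: Sequence[float] | None = None) -> GTestResult:
    """Log-likelihood-ratio goodness-of-fit test, G = 2 * sum O * ln(O/E).

    ``expected`` defaults to an equal split of the observed total.  Categories
    with zero observed count contribute nothing to G.  No Williams correction
    is applied.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or obs.size < 2:
        raise ValueError("g_test needs at least two categories")
    if np.any(obs < 0):
        raise ValueError("observed counts must be >= 0")
    if obs.sum() == 0:
        raise ValueError("all observed counts are zero")
    if expected is None:
        exp = np.full(obs.size, obs.sum() / obs.size)
    else:
        exp = np.asarray(expected, dtype=float)
        if exp.shape != obs.shape:
            raise ValueError("expected counts must match observed in length")
        if np.any((exp <= 0) & (obs > 0)):
            raise ValueError("expected counts must be > 0 where observed > 0")
    g, p = sps.power_divergence(obs, exp, lambda_="log-likelihood")
    return GTestResult(float(g), obs.size - 1, float(p))


def levene_median(*groups: Sequence[float]) -> LeveneResult:
    """Median-based Levene (Brown-Forsythe) test for homogeneity of variance."""
    if len(groups) < 2:
        raise ValueError("levene_median needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    f, p = sps.levene(*arrays, center="median")
    n = sum(a.size for a in arrays)
    return LeveneResult(float(f), len(arrays) - 1, n - len(arrays), float(p))


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with a two-sided p-value from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson needs matched samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), int(x.size))


def qc_filter_summary(n_genotyped: int, n_ambiguous: int, n_outliers: int) -> int:
    """Fish retained after removing ambiguous assignments and outliers."""
    for name, v in (("n_genotyped", n_genotyped), ("n_ambiguous", n_ambiguous),
                    ("n_outliers", n_outliers)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    retained = n_genotyped - n_ambiguous - n_outliers
    if retained < 0:
        raise ValueError(
            f"exclusions ({n_ambiguous} + {n_outliers}) exceed genotyped total {n_genotyped}"
        )
    return retained


def bonferroni_alpha(alpha: float = 0.05, m: int = 3) -> float:
    """Bonferroni-adjusted per-comparison significance threshold."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
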