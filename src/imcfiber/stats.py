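"""Statistical battery for cohort summaries.

Covers the study's four tools: Shapiro–Wilk normality checks before t-tests,
two-sided unpaired t-tests with significance at p ≤ 0.05, two-sample
Kolmogorov–Smirnov comparison of fiber CSA distributions, and Spearman rank
correlations across sample-level quantities with Bonferroni correction over
the declared family of pairs.

Spearman p-values are permutation-based at cohort scale, where the
t-approximation is unreliable in the far tail: full enumeration (exact) for
n ≤ 8 paired observations, a seeded Monte-Carlo permutation p with the
add-one estimator — valid at any resample count — for n ≤ 12, and the
t-approximation above that.  The method used is recorded in every result
row.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "CompareResult",
    "CorrelationResult",
    "normality_check",
    "compare_groups",
    "ks_compare",
    "spearman_family",
    "bonferroni",
]

#: Significance level used throughout (p ≤ 0.05).
ALPHA = 0.05

#: Largest n for which the exact spearman permutation p is enumerated.
EXACT_SPEARMAN_MAX_N = 8

#: Largest n for which a Monte-Carlo permutation p replaces the t-approximation.
MC_SPEARMAN_MAX_N = 12

#: Default Monte-Carlo permutation resamples.
MC_RESAMPLES = 4999


def normality_check(values) -> tuple[float, float]:
    """Shapiro–Wilk test; returns (W, p).  Requires n ≥ 3, non-constant."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 3:
        raise ValueError(f"normality check needs n ≥ 3, got n = {values.size}")
    if np.ptp(values) == 0:
        raise ValueError("normality check is degenerate on a constant vector")
    res = sps.shapiro(values)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CompareResult:
    t: float
    p: float
    significant: bool
    method: str


def compare_groups(a, b, equal_var: bool = False, alpha: float = ALPHA) -> CompareResult:
    """Two-sided unpaired t-test; Welch by default, pooled with equal_var.

    significant = (p ≤ alpha).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"each group needs n ≥ 2, got n = {a.size} and {b.size}"
        )
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    return CompareResult(
        t=t, p=p, significant=bool(p <= alpha),
        method="pooled t" if equal_var else "welch t",
    )


def ks_compare(a, b) -> tuple[float, float]:
    """Two-sample KS: D = sup |ECDF_a − ECDF_b| with the asymptotic p."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS comparison needs non-empty samples")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p: min(1, m·p)."""
    if m < 1:
        raise ValueError("family size must be ≥ 1")
    return min(1.0, m * p)


@dataclass(frozen=True)
class CorrelationResult:
    quantity_a: str
    quantity_b: str
    n: int
    r: float
    p: float
    p_adj: float
    m: int
    method: str


def _spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided permutation p for Spearman r by full enumeration.

    Ranks use midranks for ties; the null permutes the pairing of y against
    x over all n! arrangements.
    """
    n = x.size
    rx_c, ry_c, denom = _rank_setup(x, y)
    r_obs = float(rx_c @ ry_c / denom)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    r_all = (ry_c[perms] @ rx_c) / denom
    eps = 1e-12
    p = float(np.mean(np.abs(r_all) >= abs(r_obs) - eps))
    return r_obs, p


def _rank_setup(x: np.ndarray, y: np.ndarray):
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    if denom == 0:
        raise ValueError("spearman undefined: one variable is constant")
    return rx_c, ry_c, denom


def _spearman_mc(
    x: np.ndarray, y: np.ndarray, n_resamples: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Monte-Carlo permutation p with the add-one estimator.

    p = (1 + #{|r*| ≥ |r|}) / (1 + B) satisfies P(p ≤ α) ≤ α for any B, so
    Bonferroni control holds exactly regardless of the resample count.
    """
    rx_c, ry_c, denom = _rank_setup(x, y)
    r_obs = float(rx_c @ ry_c / denom)
    perm = rng.permuted(np.tile(ry_c, (n_resamples, 1)), axis=1)
    r_all = (perm @ rx_c) / denom
    eps = 1e-12
    p = float((1 + np.count_nonzero(np.abs(r_all) >= abs(r_obs) - eps)) / (1 + n_resamples))
    return r_obs, p


def spearman_family(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    exact_max_n: int = EXACT_SPEARMAN_MAX_N,
    mc_max_n: int = MC_SPEARMAN_MAX_N,
    n_resamples: int = MC_RESAMPLES,
    seed: int = 0,
) -> list[CorrelationResult]:
    """Spearman rank correlations over a declared family of quantity pairs.

    The Bonferroni family size m is the number of declared pairs.  Pairs
    with fewer than 4 complete paired observations are skipped with a
    warning.  Ties receive average ranks; p-values are two-sided.  ``seed``
    drives only the Monte-Carlo permutation regime (n in (exact_max_n,
    mc_max_n]); results are deterministic for fixed arguments.
    """
    if not pairs:
        raise ValueError("no correlation pairs declared")
    m = len(pairs)
    rng = np.random.default_rng(seed)
    results: list[CorrelationResult] = []
    for qa, qb in pairs:
        for q in (qa, qb):
            if q not in table.columns:
                raise KeyError(f"quantity {q!r} not in the sample summary table")
        sub = table[[qa, qb]].dropna()
        n = len(sub)
        if n < 4:
            warnings.warn(
                f"pair ({qa}, {qb}) has only {n} complete observations; skipped",
                stacklevel=2,
            )
            continue
        x = sub[qa].to_numpy(dtype=np.float64)
        y = sub[qb].to_numpy(dtype=np.float64)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"pair ({qa}, {qb}) has a constant variable; skipped", stacklevel=2
            )
            continue
        if n <= exact_max_n:
            r, p = _spearman_exact(x, y)
            method = "exact permutation"
        elif n <= mc_max_n:
            r, p = _spearman_mc(x, y, n_resamples, rng)
            method = f"mc permutation (B={n_resamples})"
        else:
            res = sps.spearmanr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
            method = "t approximation"
        results.append(
            CorrelationResult(
                quantity_a=qa,
                quantity_b=qb,
                n=n,
                r=r,
                p=p,
                p_adj=bonferroni(p, m),
                m=m,
                method=method,
            )
        )
    return results


def correlation_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tidy view of a correlation family (one row per pair)."""
    return pd.DataFrame([vars(r) for r in results])
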