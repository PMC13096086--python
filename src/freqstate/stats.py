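"""Normality screening and repeated-measures comparisons.

Lilliefors is a Kolmogorov-Smirnov test against a normal with estimated
mean/SD; its p-value comes from a seeded Monte-Carlo null rather than
lookup tables. Condition comparisons use a one-way repeated-measures ANOVA
(subject as blocking factor) with Bonferroni-corrected paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
from scipy import stats as sps


@dataclass
class AnovaResult:
    F: float
    df: tuple[int, int]
    p: float
    pairwise: dict  # (cond_i, cond_j) -> corrected p


def _lilliefors_stat(x: np.ndarray) -> float:
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return np.inf
    z = sps.norm.cdf((x - mu) / sd)
    up = np.arange(1, n + 1) / n - z
    down = z - np.arange(0, n) / n
    return float(max(up.max(), down.max()))


def lilliefors_null(n: int, n_reps: int = 2000, seed: int = 0) -> np.ndarray:
    """Monte-Carlo null distribution of the Lilliefors statistic for sample
    size n. Precompute once when testing many samples of equal size."""
    rng = np.random.default_rng(seed)
    return np.array([_lilliefors_stat(rng.standard_normal(n))
                     for _ in range(n_reps)])


def lilliefors(values, n_reps: int = 2000, seed: int = 0,
               null: Optional[np.ndarray] = None) -> tuple[float, float]:
    """(statistic, p) for composite normality. ``null`` may supply a
    precomputed null distribution for this sample size."""
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    stat = _lilliefors_stat(x)
    if not np.isfinite(stat):
        # constant input: maximally non-normal, flagged by the degenerate p
        return stat, 0.0
    if null is None:
        null = lilliefors_null(x.size, n_reps=n_reps, seed=seed)
    p = (1 + np.sum(null >= stat)) / (null.size + 1)
    return stat, float(p)


def rm_anova(table: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions matrix.

    F = MS_condition / MS_error with df = (k-1, (k-1)(n-1)); the
    subject x condition interaction is the error term.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("table must be 2-D (subjects x conditions)")
    if np.any(~np.isfinite(x)):
        raise ValueError("complete cases required (no missing cells)")
    n, k = x.shape
    if k < 2 or n < 3:
        raise ValueError("need >= 2 conditions and >= 3 subjects")
    grand = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - grand)**2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand)**2)
    ss_total = np.sum((x - grand)**2)
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        F = np.inf if ms_cond > 0 else 0.0
        p = 0.0 if ms_cond > 0 else 1.0
    else:
        F = ms_cond / ms_err
        p = float(sps.f.sf(F, df1, df2))
    result = AnovaResult(F=float(F), df=(df1, df2), p=p, pairwise={})
    return result


def pairwise_bonferroni(table: np.ndarray,
                        condition_names: Optional[list] = None) -> dict:
    """Paired t-tests for every condition pair, p multiplied by the number
    of pairs and clipped at 1."""
    x = np.asarray(table, dtype=float)
    if np.any(~np.isfinite(x)):
        raise ValueError("complete cases required")
    n, k = x.shape
    names = condition_names if condition_names is not None else list(range(k))
    pairs = list(combinations(range(k), 2))
    out = {}
    for i, j in pairs:
        d = x[:, i] - x[:, j]
        if np.allclose(d, 0):
            raw = 1.0
        else:
            raw = float(sps.ttest_rel(x[:, i], x[:, j]).pvalue)
        out[(names[i], names[j])] = min(1.0, raw * len(pairs))
    return out


def rm_anova_with_pairwise(table: np.ndarray,
                           condition_names: Optional[list] = None) -> AnovaResult:
    res = rm_anova(table)
    res.pairwise = pairwise_bonferroni(table, condition_names)
    return res
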