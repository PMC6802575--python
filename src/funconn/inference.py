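"""Nonparametric group inference for network metrics.

Graph metrics are not normally distributed, so group contrasts use
label-permutation tests and Mann-Whitney U tests, with Cliff's delta as
the effect size.  Nodal (per-ROI) contrasts are corrected for multiple
comparisons with Benjamini-Hochberg FDR; global metrics are left
uncorrected by design (a small fixed family of six).  Spearman rank
correlations relate metrics to clinical covariates, and ordinary least
squares relates per-node structural differences (volume, thickness) to
per-node centrality differences within anatomical region sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermutationResult",
    "GroupComparison",
    "CovariateCorrelation",
    "StructureFunctionFit",
    "compare_metric",
    "permutation_test",
    "mann_whitney_u",
    "cliffs_delta",
    "fdr_correct",
    "spearman_correlation",
    "structure_function_regression",
]


@dataclass
class PermutationResult:
    p: float
    observed: float
    n_perm: int


def _group_stat(x: np.ndarray, n_a: int, statistic: str) -> float:
    if statistic == "mean":
        return float(x[:n_a].mean() - x[n_a:].mean())
    if statistic == "median":
        return float(np.median(x[:n_a]) - np.median(x[n_a:]))
    raise ValueError(f"unknown statistic {statistic!r}")


def permutation_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    statistic: str | Callable[[np.ndarray, np.ndarray], float] = "mean",
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Two-sided label-permutation test on a group-difference statistic.

    The default statistic is the difference of group means.  The p-value
    uses the add-one estimator p = (1 + #{|t*| >= |t|}) / (n_perm + 1),
    which can never report exactly zero.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    pooled = np.concatenate([a, b])
    n_a, n = a.size, a.size + b.size
    rng = np.random.default_rng(seed)

    if callable(statistic):
        observed = float(statistic(a, b))
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(pooled)
            null[i] = statistic(perm[:n_a], perm[n_a:])
    else:
        observed = _group_stat(pooled, n_a, statistic)
        # all permutations at once: each row of `order` is a random shuffle
        order = np.argsort(rng.random((n_perm, n)), axis=1)
        permuted = pooled[order]
        if statistic == "mean":
            null = permuted[:, :n_a].mean(axis=1) - permuted[:, n_a:].mean(axis=1)
        else:
            null = (np.median(permuted[:, :n_a], axis=1)
                    - np.median(permuted[:, n_a:], axis=1))
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(observed))) / (n_perm + 1.0)
    return PermutationResult(float(p), observed, n_perm)


def mann_whitney_u(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U with tie-aware U and a two-sided p-value.

    U counts pairs where a > b, plus half the tied pairs.  The p-value is
    exact when both groups have at most 8 observations and the data are
    tie-free; otherwise the normal approximation with continuity
    correction (and tie-corrected variance) is used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    u = float(gt) + 0.5 * float(eq)
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return u, 1.0  # every value tied: no evidence either way
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (max(a.size, b.size) <= 8 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return u, float(res.pvalue)


def cliffs_delta(values_a: Sequence[float],
                 values_b: Sequence[float]) -> float:
    """Cliff's delta: P(a > b) - P(a < b) over all cross-pairs."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    diff = a[:, None] - b[None, :]
    return float((np.count_nonzero(diff > 0) - np.count_nonzero(diff < 0))
                 / diff.size)


def fdr_correct(p_values: Sequence[float],
                q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejections at q)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def spearman_correlation(metric_values: Sequence[float],
                         covariate_values: Sequence[float]
                         ) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties, two-sided p."""
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(covariate_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples required")
    if x.size < 4:
        raise ValueError("need at least 4 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        warnings.warn("zero rank variance: Spearman rho undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class GroupComparison:
    """Full two-group contrast of one global metric.

    Per-density permutation p-values, the AUC-level permutation p,
    Mann-Whitney U on the AUC values, Cliff's delta, and group summary
    statistics.
    """

    metric: str
    per_density_p: dict[float, float]
    auc_p: float
    u_stat: float
    u_p: float
    delta: float
    group_means_sds: dict[str, tuple[float, float]]
    n_perm: int
    contrast: str = "group"


@dataclass
class CovariateCorrelation:
    """Spearman correlation of a metric AUC with a covariate."""

    metric: str
    covariate: str
    rho: float
    p: float
    group: str
    n: int


def compare_metric(
    auc_a: Sequence[float],
    auc_b: Sequence[float],
    per_density_a: np.ndarray,
    per_density_b: np.ndarray,
    densities: Sequence[float],
    metric: str,
    labels: tuple[str, str] = ("A", "B"),
    statistic: str = "mean",
    n_perm: int = 1000,
    seed: int = 0,
    contrast: str = "group",
) -> GroupComparison:
    """Assemble the standard contrast battery for one global metric.

    ``per_density_a``/``per_density_b`` are (n_subjects, n_densities)
    arrays of the metric at each sweep density; ``auc_a``/``auc_b`` the
    per-subject AUC summaries.  NaN subjects (metric undefined at a
    density) are dropped pairwise per density.
    """
    per_density_p: dict[float, float] = {}
    for di, d in enumerate(densities):
        va = np.asarray(per_density_a)[:, di]
        vb = np.asarray(per_density_b)[:, di]
        va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        if va.size == 0 or vb.size == 0:
            per_density_p[float(d)] = float("nan")
            continue
        per_density_p[float(d)] = permutation_test(
            va, vb, statistic=statistic, n_perm=n_perm,
            seed=seed + di).p
    auc_a = np.asarray(auc_a, dtype=float)
    auc_b = np.asarray(auc_b, dtype=float)
    ok_a, ok_b = auc_a[np.isfinite(auc_a)], auc_b[np.isfinite(auc_b)]
    auc_res = permutation_test(ok_a, ok_b, statistic=statistic,
                               n_perm=n_perm, seed=seed + 1000)
    u, u_p = mann_whitney_u(ok_a, ok_b)
    delta = cliffs_delta(ok_a, ok_b)
    means = {
        labels[0]: (float(ok_a.mean()), float(ok_a.std(ddof=1))
                    if ok_a.size > 1 else 0.0),
        labels[1]: (float(ok_b.mean()), float(ok_b.std(ddof=1))
                    if ok_b.size > 1 else 0.0),
    }
    return GroupComparison(
        metric=metric, per_density_p=per_density_p, auc_p=auc_res.p,
        u_stat=u, u_p=u_p, delta=delta, group_means_sds=means,
        n_perm=n_perm, contrast=contrast)


@dataclass
class StructureFunctionFit:
    """OLS of per-node centrality deltas on per-node structural deltas."""

    region_set: list[str]
    x: np.ndarray
    y: np.ndarray
    slope: float
    intercept: float
    r2: float
    p: float

    @property
    def n_nodes(self) -> int:
        return len(self.region_set)


def structure_function_regression(
    node_deltas_x: pd.Series,
    node_deltas_y: pd.Series,
    region_set: Sequence[str],
) -> StructureFunctionFit:
    """Regress centrality differences on structural differences.

    ``node_deltas_x`` (e.g. group difference in node volume) and
    ``node_deltas_y`` (e.g. group difference in degree AUC) are indexed
    by ROI label; the fit is restricted to ``region_set``.
    """
    region = [r for r in region_set]
    missing = [r for r in region if r not in node_deltas_x.index
               or r not in node_deltas_y.index]
    if missing:
        raise ValueError(f"region nodes missing from deltas: {missing}")
    x = node_deltas_x.loc[region].to_numpy(dtype=float)
    y = node_deltas_y.loc[region].to_numpy(dtype=float)
    if len(region) < 3:
        raise ValueError("need at least 3 nodes in the region set")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in structural deltas")
    res = stats.linregress(x, y)
    return StructureFunctionFit(
        region_set=region, x=x, y=y,
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue ** 2), p=float(res.pvalue))
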