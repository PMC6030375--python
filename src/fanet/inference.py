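"""Group inference: permutation tests, BH-FDR, and severity correlation.

The group comparison is a nonparametric permutation test on the
difference of group means: subjects are randomly reassigned to two groups
of the original sizes, the null distribution of the mean difference is
built from (by default) 10,000 relabelings, and the two-sided p-value is
the +1-corrected fraction of null differences at least as extreme as the
observed one.  Whole-network metrics are judged at uncorrected
alpha = 0.05; per-node metrics are corrected across the 90 regions by
Benjamini-Hochberg FDR at Q < 0.05, separately per metric family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class PermutationResult:
    """Observed ASD-HC mean difference and its empirical two-sided p."""

    metric_name: str
    observed_diff: float
    p_value: float
    n_permutations: int
    seed: int | None = None

    def __post_init__(self):
        assert self.p_value >= 1.0 / (self.n_permutations + 1)


@dataclass(frozen=True)
class FDRResult:
    """Benjamini-Hochberg q-values and the significance mask at Q."""

    q_values: np.ndarray
    significant: np.ndarray
    q_threshold: float


def _perm_group_masks(n_total: int, n_a: int, n_perm: int,
                      rng: np.random.Generator) -> np.ndarray:
    """(n_perm, n_total) 0/1 matrix; each row marks a random size-n_a group."""
    # argpartition of iid uniforms = uniform random subset per row
    u = rng.random((n_perm, n_total))
    order = np.argpartition(u, n_a - 1, axis=1)[:, :n_a]
    masks = np.zeros((n_perm, n_total))
    np.put_along_axis(masks, order, 1.0, axis=1)
    return masks


def permutation_test(values_a, values_b, n_perm: int = 10000,
                     seed: int | None = None,
                     metric_name: str = "") -> PermutationResult:
    """Two-sided permutation test on the difference of group means (A - B)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = a.mean() - b.mean()
    data = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    masks = _perm_group_masks(data.size, a.size, n_perm, rng)
    sum_a = masks @ data
    mean_a = sum_a / a.size
    mean_b = (data.sum() - sum_a) / b.size
    null = mean_a - mean_b
    p = (np.count_nonzero(np.abs(null) >= abs(obs)) + 1) / (n_perm + 1)
    return PermutationResult(metric_name=metric_name, observed_diff=float(obs),
                             p_value=float(p), n_permutations=n_perm, seed=seed)


def permutation_test_table(data: np.ndarray, is_a: np.ndarray,
                           n_perm: int = 10000,
                           seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise permutation tests sharing one set of relabelings.

    ``data`` is (n_subjects, n_columns); ``is_a`` a boolean subject mask.
    Returns (observed_diffs, p_values), one per column.  Sharing the
    relabelings across columns preserves the between-column correlation
    structure of the null and is the standard way to test 90 regions at
    once.
    """
    data = np.asarray(data, dtype=float)
    is_a = np.asarray(is_a, dtype=bool)
    n, _ = data.shape
    n_a = int(is_a.sum())
    n_b = n - n_a
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be nonempty")
    obs = data[is_a].mean(axis=0) - data[~is_a].mean(axis=0)
    rng = np.random.default_rng(seed)
    masks = _perm_group_masks(n, n_a, n_perm, rng)
    sum_a = masks @ data                       # (n_perm, n_columns)
    null = sum_a / n_a - (data.sum(axis=0) - sum_a) / n_b
    exceed = (np.abs(null) >= np.abs(obs)).sum(axis=0)
    p = (exceed + 1) / (n_perm + 1)
    return obs, p


def bh_fdr(p_values, q_threshold: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up FDR correction."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return FDRResult(q_values=np.empty(0), significant=np.empty(0, dtype=bool),
                         q_threshold=q_threshold)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    return FDRResult(q_values=q, significant=reject, q_threshold=q_threshold)


def pearson_with_cars(metric_values, cars) -> tuple[float, float]:
    """Pearson correlation between a metric and CARS severity scores.

    Returns (r, p) with the two-sided p from the exact t transform with
    n - 2 degrees of freedom.
    """
    x = np.asarray(metric_values, dtype=float)
    y = np.asarray(cars, dtype=float)
    if x.size != y.size:
        raise ValueError("metric and CARS vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = _scipy_stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
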