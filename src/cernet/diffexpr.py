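"""SAM-style two-class differential expression.

The statistic is the moderated t-like quantity d = (mean_tumor − mean_normal)
/ (s + s0), where s is the pooled-variance standard error of the mean
difference and s0 a small exchangeability constant that stabilises d for
low-variance features (here the median of the per-feature standard errors).
Significance comes from label permutations; calling combines a fold-change
threshold with the permutation p-value (the default combiner is "or",
configurable to "and").
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix


def _pooled_se(x1: np.ndarray, x2: np.ndarray, axis: int = -1) -> np.ndarray:
    n1, n2 = x1.shape[axis], x2.shape[axis]
    v1 = np.var(x1, axis=axis, ddof=1)
    v2 = np.var(x2, axis=axis, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    return np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))


def sam_statistic(x_tumor, x_normal, s0: float) -> float:
    """d = (mean(x_tumor) − mean(x_normal)) / (s + s0).

    With s0 = 0 this is exactly the pooled two-sample t statistic. Swapping
    the groups negates d.
    """
    x1 = np.asarray(x_tumor, dtype=float)
    x2 = np.asarray(x_normal, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs at least 2 values")
    if s0 < 0:
        raise ValueError("s0 must be ≥ 0")
    s = _pooled_se(x1, x2)
    if s + s0 == 0:
        raise ValueError("zero variance in both groups and s0 = 0: d undefined")
    return float((x1.mean() - x2.mean()) / (s + s0))


def estimate_s0(per_feature_se) -> float:
    """Exchangeability constant: the median per-feature standard error."""
    se = np.asarray(per_feature_se, dtype=float)
    if se.size == 0:
        raise ValueError("cannot estimate s0 from zero features")
    return float(np.median(se))


def _matrix_d(values: np.ndarray, tumor: np.ndarray, s0: float) -> np.ndarray:
    """Vectorised d over all features for one labelling."""
    x1, x2 = values[:, tumor], values[:, ~tumor]
    se = _pooled_se(x1, x2, axis=1)
    return (x1.mean(axis=1) - x2.mean(axis=1)) / (se + s0)


def permutation_pvalues(
    values: np.ndarray,
    tumor: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    s0: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Joint-label permutation p-values for every feature at once.

    Labels are permuted identically across features each iteration;
    p = (1 + #{|d*| ≥ |d_obs|}) / (n_perm + 1), so p can never be 0.
    Returns (p_values, observed d, s0 used).
    """
    values = np.asarray(values, dtype=float)
    tumor = np.asarray(tumor, dtype=bool)
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    if tumor.sum() < 2 or (~tumor).sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    if s0 is None:
        x1, x2 = values[:, tumor], values[:, ~tumor]
        s0 = estimate_s0(_pooled_se(x1, x2, axis=1))
    d_obs = _matrix_d(values, tumor, s0)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(values.shape[0], dtype=int)
    abs_obs = np.abs(d_obs)
    for _ in range(n_perm):
        perm = rng.permutation(tumor)
        d_star = _matrix_d(values, perm, s0)
        exceed += np.abs(d_star) >= abs_obs
    p = (1.0 + exceed) / (n_perm + 1.0)
    return p, d_obs, s0


def permutation_pvalue(
    matrix: ExpressionMatrix, labels, feature: str, n_perm: int = 1000, seed: int = 0,
    s0: float | None = None,
) -> float:
    """Permutation p for one feature (labels permuted jointly with all others)."""
    tumor = np.asarray([lab == "tumor" for lab in labels])
    p, _, _ = permutation_pvalues(matrix.values.to_numpy(), tumor, n_perm, seed, s0)
    idx = matrix.feature_ids.get_loc(feature)
    return float(p[idx])


def call_differential(
    matrix: ExpressionMatrix,
    fc_threshold: float,
    p_threshold: float = 0.01,
    combine: str = "or",
    n_perm: int = 1000,
    seed: int = 0,
    s0: float | None = None,
) -> pd.DataFrame:
    """Call DE features by |log2FC| and permutation p.

    ``called = (|log2_fc| > fc_threshold) <combine> (p < p_threshold)`` with
    combine ∈ {"or", "and"}. Returns one row per feature: feature_id, class,
    log2_fc, d_stat, p_value, direction, called.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if combine not in ("or", "and"):
        raise ValueError(f"combine must be 'or' or 'and', got {combine!r}")
    tumor = matrix.tumor_mask()
    values = matrix.values.to_numpy()
    p, d, _ = permutation_pvalues(values, tumor, n_perm=n_perm, seed=seed, s0=s0)
    log2_fc = values[:, tumor].mean(axis=1) - values[:, ~tumor].mean(axis=1)
    fc_hit = np.abs(log2_fc) > fc_threshold
    p_hit = p < p_threshold
    called = fc_hit | p_hit if combine == "or" else fc_hit & p_hit
    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "class": matrix.feature_class.to_numpy(),
            "log2_fc": log2_fc,
            "d_stat": d,
            "p_value": p,
            "direction": np.where(log2_fc > 0, "up", "down"),
            "called": called,
        }
    ).reset_index(drop=True)
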