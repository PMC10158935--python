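"""Correlation between RNA expression and immune-cell infiltration scores.

Infiltration estimates are defined for tumors, so only tumor samples enter
the correlation. One record per (feature, cell type) over the shared
samples; p-values come from the usual t-distribution of the correlation
(Pearson) or its rank-based analogue (Spearman). Degenerate (constant)
vectors produce a flagged record rather than a silent drop.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, InfiltrationTable


def correlate_infiltration(
    expr: ExpressionMatrix,
    infil: InfiltrationTable,
    method: str = "pearson",
    features=None,
) -> pd.DataFrame:
    """Correlate each feature with each infiltration cell type.

    Returns columns feature_id, cell_type, r, p_value, n_samples, ok.
    ``ok`` is False where a constant vector made the correlation undefined
    (r and p are NaN there).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    tumor = expr.samples_in("tumor")
    shared = tumor.intersection(infil.sample_ids)
    if len(shared) < 3:
        raise ValueError("need at least 3 tumor samples shared with the infiltration table")
    feats = list(features) if features is not None else list(expr.feature_ids)
    ev = expr.values.loc[feats, shared]
    sv = infil.scores.loc[shared]
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    rows = []
    for f in feats:
        x = ev.loc[f].to_numpy(dtype=float)
        x_const = np.ptp(x) == 0
        for ct in infil.cell_types:
            y = sv[ct].to_numpy(dtype=float)
            if x_const or np.ptp(y) == 0:
                rows.append((f, ct, np.nan, np.nan, len(shared), False))
                continue
            res = corr(x, y)
            rows.append((f, ct, float(res.statistic), float(res.pvalue), len(shared), True))
    return pd.DataFrame(
        rows, columns=["feature_id", "cell_type", "r", "p_value", "n_samples", "ok"]
    )


def correlation_matrix(long: pd.DataFrame, value: str = "r") -> pd.DataFrame:
    """Pivot the long-format output to a features × cell-types matrix."""
    return long.pivot(index="feature_id", columns="cell_type", values=value)
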