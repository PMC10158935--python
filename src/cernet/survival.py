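"""Risk-score survival modelling.

The prognosis model weights each gene's expression by its *univariate* Cox
log-hazard coefficient r_i and sums: RiskScore = Σ_i r_i · Exp_i. Patients
above the cohort-mean score form the high-risk group; the groups are
compared with the log-rank test. Single genes are assessed by splitting at
the median (or mean) expression.

The univariate Cox coefficient is the maximiser of the partial likelihood
with Breslow tie handling, found by Newton–Raphson (with step halving) to
|Δr| < 1e-8. Kaplan–Meier estimation and the log-rank test are delegated to
``lifelines``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .datatypes import ClinicalTable, RiskModel, SurvivalComparison


# ---------------------------------------------------------------------------
# univariate Cox regression


def cox_partial_loglik(r: float, x: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Breslow partial log-likelihood of a single coefficient."""
    ll = 0.0
    for t in np.unique(times[events == 1]):
        at_event = (times == t) & (events == 1)
        risk = times >= t
        ll += r * x[at_event].sum()
        ll -= at_event.sum() * np.log(np.exp(r * x[risk]).sum())
    return ll


def fit_univariate_cox(
    expr_gene,
    times,
    events,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> float:
    """Newton–Raphson maximiser of the Breslow partial likelihood.

    Errors on < 2 events, constant expression, or non-convergence.
    """
    x = np.asarray(expr_gene, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if d.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox coefficient")
    if np.ptp(x) == 0:
        raise ValueError("constant expression: Cox coefficient undefined")
    x = x - x.mean()  # centering leaves r unchanged, improves conditioning

    event_times = np.unique(t[d == 1])
    risk_masks = [t >= et for et in event_times]
    d_counts = np.array([((t == et) & (d == 1)).sum() for et in event_times])
    x_event_sums = np.array([x[(t == et) & (d == 1)].sum() for et in event_times])

    def score_info(r: float) -> tuple[float, float]:
        u, info = 0.0, 0.0
        for mask, dk, xs in zip(risk_masks, d_counts, x_event_sums):
            w = np.exp(r * x[mask])
            sw = w.sum()
            xbar = (w * x[mask]).sum() / sw
            x2bar = (w * x[mask] ** 2).sum() / sw
            u += xs - dk * xbar
            info += dk * (x2bar - xbar**2)
        return u, info

    r = 0.0
    ll = cox_partial_loglik(r, x, t, d)
    for _ in range(max_iter):
        u, info = score_info(r)
        if info <= 0:
            raise ValueError("singular information: Cox fit failed")
        step = u / info
        step = float(np.clip(step, -5.0, 5.0))
        # step halving keeps the likelihood non-decreasing
        for _ in range(30):
            ll_new = cox_partial_loglik(r + step, x, t, d)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        r += step
        ll = ll_new
        if abs(step) < tol:
            return float(r)
    raise ValueError("Cox Newton iteration did not converge")


# ---------------------------------------------------------------------------
# risk-score model


def fit_risk_model(expr: pd.DataFrame, clinical: ClinicalTable) -> RiskModel:
    """Univariate Cox coefficient per gene + mean-score cutoff.

    ``expr``: genes × samples; only samples present in the clinical table
    are used, and the cutoff is the mean risk score over that cohort.
    """
    common = expr.columns.intersection(clinical.sample_ids)
    if len(common) < 3:
        raise ValueError("too few samples shared between expression and clinical")
    sub = expr[common]
    cl = clinical.subset(common)
    coefs = pd.Series(
        {g: fit_univariate_cox(sub.loc[g], cl.times, cl.events) for g in sub.index}
    )
    scores = risk_scores(RiskModel(coefs), sub)
    return RiskModel(coefs, cutoff=float(scores.mean()))


def risk_score(model: RiskModel, expr_patient) -> float:
    """Σ_i r_i · Exp_i for one patient; errors on a missing model gene."""
    vals = []
    for g in model.gene_ids:
        try:
            vals.append(float(expr_patient[g]))
        except (KeyError, IndexError) as exc:
            raise KeyError(f"patient expression missing model gene {g!r}") from exc
    return float(np.dot(model.coefficients.to_numpy(), vals))


def risk_scores(model: RiskModel, expr: pd.DataFrame) -> pd.Series:
    """Vectorised risk scores (one per sample column of ``expr``)."""
    missing = [g for g in model.gene_ids if g not in expr.index]
    if missing:
        raise KeyError(f"expression missing model genes {missing}")
    mat = expr.loc[model.gene_ids]
    return pd.Series(
        model.coefficients.to_numpy() @ mat.to_numpy(), index=expr.columns
    )


def stratify(scores: pd.Series) -> tuple[pd.Index, pd.Index, float]:
    """Split at the mean score: strictly above → high risk, else low risk."""
    scores = pd.Series(scores)
    if len(scores) < 2:
        raise ValueError("need at least 2 patients to stratify")
    cutoff = float(scores.mean())
    high = scores.index[scores > cutoff]
    low = scores.index[scores <= cutoff]
    if len(high) == 0 or len(low) == 0:
        raise ValueError("degenerate stratification: all scores identical")
    return high, low, cutoff


# ---------------------------------------------------------------------------
# Kaplan–Meier and log-rank


@dataclass
class KMCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    event_times: np.ndarray  # times at which S drops
    survival: np.ndarray     # S just after each drop

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.event_times, "S": self.survival})


def km_estimator(times, events) -> KMCurve:
    """Kaplan–Meier estimate via lifelines; negative times are rejected."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("need at least 1 subject")
    if (t < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, d)
    sf = kmf.survival_function_
    drop_times = np.unique(t[d == 1])
    surv = np.array([float(sf.loc[tt].iloc[0]) for tt in drop_times])
    return KMCurve(event_times=drop_times, survival=surv)


def logrank_test(group_a, group_b) -> SurvivalComparison:
    """Two-group log-rank test; groups are (times, events) pairs."""
    ta, da = (np.asarray(v, dtype=float) for v in group_a)
    tb, db = (np.asarray(v, dtype=float) for v in group_b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("each group needs at least 1 subject")
    if da.sum() + db.sum() == 0:
        raise ValueError("no events in either group")
    res = _ll_logrank(ta, tb, event_observed_A=da, event_observed_B=db)
    chi2 = float(max(res.test_statistic, 0.0))
    p = float(min(max(res.p_value, np.finfo(float).tiny), 1.0))
    return SurvivalComparison(
        chi_square=chi2,
        degrees_of_freedom=1,
        p_value=p,
        n_high=int(ta.size),
        n_low=int(tb.size),
    )


def single_gene_survival(
    expr_gene: pd.Series, clinical: ClinicalTable, split: str = "median"
) -> SurvivalComparison:
    """Split samples at the median (or mean) expression and run log-rank."""
    if split not in ("median", "mean"):
        raise ValueError("split must be 'median' or 'mean'")
    common = expr_gene.index.intersection(clinical.sample_ids)
    x = expr_gene.loc[common]
    if np.ptp(x.to_numpy()) == 0:
        raise ValueError("constant expression: cannot split")
    cut = float(x.median() if split == "median" else x.mean())
    high = x.index[x > cut]
    low = x.index[x <= cut]
    if len(high) == 0 or len(low) == 0:
        raise ValueError("degenerate expression split")
    ch, cl = clinical.subset(high), clinical.subset(low)
    return logrank_test((ch.times, ch.events), (cl.times, cl.events))


def risk_group_survival(
    model: RiskModel, expr: pd.DataFrame, clinical: ClinicalTable
) -> tuple[SurvivalComparison, pd.Index, pd.Index]:
    """The full chain: score → mean-cutoff stratify → log-rank."""
    common = expr.columns.intersection(clinical.sample_ids)
    scores = risk_scores(model, expr[common])
    high, low, _ = stratify(scores)
    ch, cl = clinical.subset(high), clinical.subset(low)
    comp = logrank_test((ch.times, ch.events), (cl.times, cl.events))
    return comp, high, low
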