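import numpy as np
import pandas as pd
import pytest

from cernet import (
    ClinicalTable,
    RiskModel,
    cox_partial_loglik,
    fit_risk_model,
    fit_univariate_cox,
    km_estimator,
    logrank_test,
    risk_group_survival,
    risk_score,
    risk_scores,
    single_gene_survival,
    stratify,
)


def simulate_cox(n, beta, censoring=0.3, seed=0):
    """Exponential survival with log-hazard beta·x, independent censoring."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    t_event = rng.exponential(1.0 / (0.01 * np.exp(beta * x)))
    t_cens = rng.exponential(1.0 / (0.01 * censoring / (1 - censoring)), size=n)
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    return x, times, events


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        km = km_estimator([5, 10, 15], [0, 0, 0])
        assert km.at(0) == 1.0
        assert km.at(100) == 1.0

    def test_single_event_among_four(self):
        km = km_estimator([5, 8, 9, 10], [1, 0, 0, 0])
        assert km.at(5) == pytest.approx(0.75)

    def test_worked_product_limit_example(self):
        km = km_estimator([1, 2, 3, 4], [1, 1, 0, 1])
        assert km.at(1) == pytest.approx(0.75)
        assert km.at(2) == pytest.approx(0.5)
        assert km.at(4) == pytest.approx(0.0)
        assert km.at(0.5) == 1.0

    def test_curve_non_increasing_starts_at_one(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, size=50)
        e = rng.integers(0, 2, size=50)
        km = km_estimator(t, e)
        assert km.at(0) <= 1.0
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all(km.survival <= 1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            km_estimator([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.array([1.0, 3.0, 5.0, 7.0])
        e = np.array([1, 0, 1, 1])
        comp = logrank_test((t, e), (t.copy(), e.copy()))
        assert comp.chi_square == pytest.approx(0.0, abs=1e-10)
        assert comp.p_value == pytest.approx(1.0)
        assert comp.degrees_of_freedom == 1

    def test_symmetric_in_groups(self):
        a = simulate_cox(50, 1.0, seed=1)[1:]
        b = simulate_cox(50, 0.0, seed=2)[1:]
        c1 = logrank_test(a, b)
        c2 = logrank_test(b, a)
        assert c1.chi_square == pytest.approx(c2.chi_square)
        assert c1.p_value == pytest.approx(c2.p_value)

    def test_strong_hazard_ratio_detected(self):
        rng = np.random.default_rng(5)
        hits = 0
        for i in range(20):
            ta = rng.exponential(1.0, size=200)
            tb = rng.exponential(3.0, size=200)
            comp = logrank_test((ta, np.ones(200)), (tb, np.ones(200)))
            hits += comp.p_value < 0.05
        assert hits >= 19

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test(([1, 2], [0, 0]), ([3, 4], [0, 0]))


class TestCoxFit:
    def test_matches_grid_search_on_small_datasets(self):
        """Oracle: 1-D grid maximization of the Breslow partial likelihood."""
        rng = np.random.default_rng(11)
        grid = np.linspace(-4, 4, 8001)
        for _ in range(10):
            n = 8
            x = rng.normal(size=n)
            t = rng.exponential(5, size=n)
            e = np.zeros(n, dtype=int)
            e[rng.choice(n, size=5, replace=False)] = 1
            r = fit_univariate_cox(x, t, e)
            ll = np.array([cox_partial_loglik(g, x - x.mean(), t, e) for g in grid])
            r_grid = grid[np.argmax(ll)]
            assert r == pytest.approx(r_grid, abs=2e-3)

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines import CoxPHFitter

        x, t, e = simulate_cox(150, 0.5, seed=4)
        df = pd.DataFrame({"x": x, "t": t, "e": e})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit_univariate_cox(x, t, e) == pytest.approx(
            float(cph.params_["x"]), abs=1e-5
        )

    def test_null_covariate_coefficient_near_zero(self):
        x, t, e = simulate_cox(1000, 0.0, seed=7)
        assert abs(fit_univariate_cox(x, t, e)) < 0.1

    def test_recovers_planted_coefficient(self):
        x, t, e = simulate_cox(1000, 0.8, seed=9)
        assert fit_univariate_cox(x, t, e) == pytest.approx(0.8, abs=0.15)

    def test_bias_shrinks_with_sample_size(self):
        errs = {}
        for n in (250, 500, 1000):
            ests = [
                fit_univariate_cox(*simulate_cox(n, 0.8, seed=100 + n + i))
                for i in range(5)
            ]
            errs[n] = abs(np.mean(ests) - 0.8)
        assert errs[1000] <= errs[250] + 0.05

    def test_constant_expression_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_univariate_cox([1, 1, 1, 1], [1, 2, 3, 4], [1, 1, 0, 1])

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="2 events"):
            fit_univariate_cox([1, 2, 3], [1, 2, 3], [1, 0, 0])


class TestRiskScore:
    def test_hand_sum(self):
        model = RiskModel(pd.Series({"a": 1.0, "b": -1.0}))
        assert risk_score(model, {"a": 2.0, "b": 3.0}) == pytest.approx(-1.0)

    def test_zero_coefficients_zero_scores(self):
        model = RiskModel(pd.Series({"a": 0.0, "b": 0.0}))
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 5)),
                            index=["a", "b"])
        assert (risk_scores(model, expr) == 0).all()

    def test_single_gene_linearity(self):
        model = RiskModel(pd.Series({"g": 2.0}))
        rng = np.random.default_rng(1)
        for _ in range(20):
            v = float(rng.normal())
            assert risk_score(model, {"g": v}) == pytest.approx(2 * v)

    def test_missing_gene_rejected(self):
        model = RiskModel(pd.Series({"a": 1.0}))
        with pytest.raises(KeyError, match="missing model gene"):
            risk_score(model, {"b": 1.0})


class TestStratify:
    def test_two_patients(self):
        high, low, cut = stratify(pd.Series({"p1": 1.0, "p2": 3.0}))
        assert cut == pytest.approx(2.0)
        assert list(high) == ["p2"] and list(low) == ["p1"]

    def test_ties_go_to_low_risk(self):
        # mean = 1; only the score strictly above goes high
        high, low, cut = stratify(pd.Series({"a": 0.0, "b": 0.0, "c": 3.0}))
        assert cut == pytest.approx(1.0)
        assert list(high) == ["c"]
        assert set(low) == {"a", "b"}

    def test_translation_invariance(self):
        s = pd.Series({"a": 0.2, "b": 1.4, "c": -0.7, "d": 2.2})
        h1, l1, _ = stratify(s)
        h2, l2, _ = stratify(s + 100.0)
        assert list(h1) == list(h2) and list(l1) == list(l2)

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            stratify(pd.Series({"a": 1.0, "b": 1.0}))


def _clinical_from(times, events, ids):
    return ClinicalTable(
        pd.DataFrame({"OS_time": times, "OS_event": events},
                     index=pd.Index(ids, name="sample_id"))
    )


class TestEndToEndRiskChain:
    def test_planted_signature_detected(self):
        """fit → score → mean-cutoff stratify → log-rank on a 3-gene signature."""
        rng = np.random.default_rng(13)
        n = 563
        ids = [f"T{i}" for i in range(n)]
        expr = pd.DataFrame(rng.normal(size=(3, n)), index=["g1", "g2", "g3"], columns=ids)
        eta = 0.8 * expr.loc["g1"] - 0.8 * expr.loc["g2"] + 0.8 * expr.loc["g3"]
        t_event = rng.exponential(1.0 / (0.01 * np.exp(eta)))
        t_cens = rng.exponential(1.0 / (0.01 * 0.3 / 0.7), size=n)
        clin = _clinical_from(
            np.minimum(t_event, t_cens), (t_event <= t_cens).astype(int), ids
        )
        model = fit_risk_model(expr, clin)
        assert np.sign(model.coefficients["g1"]) == 1
        assert np.sign(model.coefficients["g2"]) == -1
        comp, high, low = risk_group_survival(model, expr, clin)
        assert comp.p_value < 0.05
        assert len(high) + len(low) == n

    def test_single_gene_split_modes(self):
        x, t, e = simulate_cox(200, 1.2, seed=3)
        ids = [f"T{i}" for i in range(200)]
        expr = pd.Series(x, index=ids)
        clin = _clinical_from(t, e, ids)
        for split in ("median", "mean"):
            comp = single_gene_survival(expr, clin, split=split)
            assert comp.p_value < 0.05

    def test_single_gene_constant_rejected(self):
        clin = _clinical_from([1, 2, 3, 4], [1, 1, 0, 1], ["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="constant"):
            single_gene_survival(pd.Series(1.0, index=["a", "b", "c", "d"]), clin)
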