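import numpy as np
import pytest
from scipy import optimize

from regimecox import coxtv
from regimecox.simulate import DGPConfig, draw_cohort

from conftest import make_table


def brute_loglik(tbl, cols, beta, use_weights=False):
    """Independent O(n^2) evaluation of the weighted Breslow log partial
    likelihood by explicit risk-set enumeration."""
    X = tbl.design(cols)
    beta = np.asarray(beta, float)
    w = tbl.weight if use_weights and tbl.weight is not None else np.ones(tbl.n_rows)
    lp = X @ beta if beta.size else np.zeros(tbl.n_rows)
    ll = 0.0
    for e in np.flatnonzero(tbl.event):
        t = tbl.stop[e]
        risk = (tbl.start < t) & (t <= tbl.stop)
        ll += w[e] * (lp[e] - np.log(np.sum(w[risk] * np.exp(lp[risk]))))
    return ll


def brute_maximize(tbl, cols, use_weights=False):
    x0 = np.zeros(len(cols))
    res = optimize.minimize(
        lambda b: -brute_loglik(tbl, cols, b, use_weights), x0,
        method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000},
    )
    return res.x


TWO_SUBJECT = [("a", 0, 1, 1, 1, 0, 1.0), ("b", 0, 2, 1, 0, 0, 0.0)]


class TestHandValues:
    def test_two_subject_loglik_and_score_at_zero(self):
        # risk sets: {a,b} at t=1, {b} at t=2 -> ll(0) = -log 2; score = +1/2
        tbl = make_table(TWO_SUBJECT, q_names=("qx",))
        ll, score = coxtv.partial_loglik(tbl, ["qx"], [0.0], with_score=True)
        assert np.isclose(ll, -np.log(2.0))
        assert np.isclose(score[0], 0.5)

    def test_three_subject_fit_matches_brute_force(self):
        rows = TWO_SUBJECT + [("c", 0, 3, 1, 0, 0, 1.0)]
        tbl = make_table(rows, q_names=("qx",))
        fit = coxtv.fit_cox(tbl, ["qx"])
        assert np.allclose(fit.coef, brute_maximize(tbl, ["qx"]), atol=1e-4)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_small_tables_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(6):
            t = rng.exponential(2.0) + 0.1
            rows.append((i, 0.0, t, int(rng.uniform() < 0.7), int(rng.uniform() < 0.5),
                         0, rng.normal()))
        tbl = make_table(rows, q_names=("qx",),
                         weight=rng.uniform(0.5, 2.0, size=6))
        if tbl.event.sum() == 0:
            pytest.skip("no events drawn")
        for use_w in (False, True):
            fit = coxtv.fit_cox(tbl, ["qx"], use_weights=use_w)
            ref = brute_maximize(tbl, ["qx"], use_weights=use_w)
            assert np.allclose(fit.coef, ref, atol=1e-4)

    def test_gradient_matches_finite_differences(self, small_cohort):
        tbl = small_cohort.tbl_full
        cols = ["treat", "one_minus_zv", "q"]
        beta = np.array([0.3, -0.2, 0.1])
        _, score = coxtv.partial_loglik(tbl, cols, beta, with_score=True)
        eps = 1e-6
        for j in range(3):
            e = np.zeros(3)
            e[j] = eps
            fd = (
                coxtv.partial_loglik(tbl, cols, beta + e)
                - coxtv.partial_loglik(tbl, cols, beta - e)
            ) / (2 * eps)
            assert abs(fd - score[j]) <= 1e-6 * max(1.0, abs(score[j]))


class TestAgainstReferenceImplementations:
    def _weighted_table(self):
        coh = draw_cohort(DGPConfig(n=300, beta=(0.2, 0.3, -0.1), seed=11))
        rng = np.random.default_rng(5)
        wsub = rng.uniform(0.5, 3.0, coh.tbl_full.n_subjects)
        return coh.tbl_full.with_weight(wsub[coh.tbl_full.subj])

    def test_unweighted_fit_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        tbl = self._weighted_table()
        fit = coxtv.fit_cox(tbl, ["treat", "one_minus_zv", "q"])
        df = tbl.to_frame()
        df["omz"] = 1 - df["zv"]
        ctv = lifelines.CoxTimeVaryingFitter().fit(
            df[["id", "start", "stop", "event", "treat", "omz", "q"]],
            id_col="id", start_col="start", stop_col="stop", event_col="event",
        )
        assert np.allclose(fit.coef, ctv.params_.values, atol=1e-6)

    def test_weighted_robust_fit_matches_r_survival(self):
        # frozen oracle: R survival::coxph(Surv(start,stop,event) ~ treat +
        # I(1-zv) + q + cluster(id), weights=weight, ties="breslow") on the
        # identical table (same DGP seed / weight stream)
        tbl = self._weighted_table()
        fit = coxtv.fit_cox(tbl, ["treat", "one_minus_zv", "q"], use_weights=True)
        assert np.allclose(fit.coef, [-0.99281911, 0.42754835, 0.03527074], atol=1e-6)
        assert np.allclose(
            fit.se_robust, [0.15810061, 0.21000456, 0.05862036], atol=1e-6
        )
        assert np.allclose(
            fit.se_model, [0.11464743, 0.15503793, 0.03925178], atol=1e-6
        )


class TestWeightSemantics:
    def test_unit_weights_reproduce_unweighted_fit(self, small_cohort):
        tbl = small_cohort.tbl_full
        fit0 = coxtv.fit_cox(tbl, ["treat", "q"])
        fit1 = coxtv.fit_cox(
            tbl.with_weight(np.ones(tbl.n_rows)), ["treat", "q"], use_weights=True
        )
        assert np.allclose(fit0.coef, fit1.coef, atol=1e-10)
        assert np.allclose(fit0.cov_robust, fit1.cov_robust, atol=1e-10)

    def test_half_weight_duplication_leaves_coef_unchanged(self):
        rows = []
        rng = np.random.default_rng(3)
        for i in range(10):
            rows.append((i, 0.0, rng.exponential(1) + 0.05, 1, 0, 0, rng.normal()))
        tbl = make_table(rows, q_names=("qx",))
        fit = coxtv.fit_cox(tbl, ["qx"])
        dup = make_table(
            [(f"{r[0]}_{k}",) + r[1:] for r in rows for k in (0, 1)],
            q_names=("qx",), weight=np.full(20, 0.5),
        )
        fit2 = coxtv.fit_cox(dup, ["qx"], use_weights=True)
        assert np.allclose(fit.coef, fit2.coef, atol=1e-8)


class TestBaselineAndPrediction:
    def test_single_event_no_covariates_gives_unit_mass(self):
        tbl = make_table([("a", 0, 1, 1, 0, 0)])
        fit = coxtv.fit_cox(tbl, [])
        times, incr = coxtv.breslow_cumhaz(fit)
        assert times.tolist() == [1.0] and np.isclose(incr[0], 1.0)
        assert fit.baseline_cumhaz(0.0) == 0.0

    def test_null_model_baseline_is_nelson_aalen(self, small_cohort):
        tbl = small_cohort.tbl_full
        fit = coxtv.fit_cox(tbl, [])
        # Nelson-Aalen by hand at each event time
        for t in fit.baseline_times[:20]:
            at_risk = np.sum((tbl.start < t) & (t <= tbl.stop))
            d = np.sum((tbl.stop == t) & (tbl.event == 1))
            k = np.searchsorted(fit.baseline_times, t)
            assert np.isclose(fit.baseline_incr[k], d / at_risk)

    def test_predict_survival_reductions(self):
        tbl = make_table([("a", 0, 1, 1, 0, 0, 1.0), ("b", 0, 3, 0, 0, 0, 0.0)],
                         q_names=("qx",))
        fit = coxtv.fit_cox(tbl, [])
        K = coxtv.predict_survival(fit, ([], [[0.0]]))
        # zero coefficients: K(t) = exp(-Lam0(t)); increment = 1/2 at t=1
        assert np.isclose(K(0.0), 1.0)
        assert np.isclose(K(2.0), np.exp(-0.5))

    def test_predict_survival_with_lp(self):
        # single increment 0.5 at t=1 and lp = log 2 gives K(2) = exp(-1)
        fit = coxtv.null_fit(["qx"])
        fit.baseline_times = np.array([1.0])
        fit.baseline_incr = np.array([0.5])
        fit.coef = np.array([np.log(2.0)])
        K = coxtv.predict_survival(fit, ([], [[1.0]]))
        assert np.isclose(K(2.0), np.exp(-1.0))

    def test_hazard_increments_consistency(self, small_cohort):
        tbl = small_cohort.tbl_full
        fit = coxtv.fit_cox(tbl, ["q"])
        path = ([], [[0.7]])
        K = coxtv.predict_survival(fit, path)
        t_end = fit.baseline_times[10]
        incs = coxtv.hazard_increments(fit, path, fit.baseline_times[: 11])
        assert np.isclose(K(t_end), np.exp(-incs.sum()))
        # non-event time yields zero increment
        assert coxtv.hazard_increments(fit, path, [fit.baseline_times[0] / 2])[0] == 0.0


class TestDegenerateDesigns:
    def test_constant_column_raises_naming_culprit(self):
        tbl = make_table([("a", 0, 1, 1, 1, 0), ("b", 0, 2, 1, 1, 0)])
        with pytest.raises(np.linalg.LinAlgError, match="treat"):
            coxtv.fit_cox(tbl, ["treat"])

    def test_monotone_likelihood_flagged_not_raised(self):
        tbl = make_table([("a", 0, 1, 1, 1, 0, 1.0), ("b", 0, 2, 0, 1, 0, 0.0)],
                         q_names=("qx",))
        with pytest.warns(coxtv.ConvergenceWarning):
            fit = coxtv.fit_cox(tbl, ["qx"])
        assert fit.monotone and not fit.converged

    def test_no_events_is_an_error(self):
        tbl = make_table([("a", 0, 1, 0, 1, 0)])
        with pytest.raises(ValueError, match="no events"):
            coxtv.fit_cox(tbl, [])


def test_robust_matches_model_cov_under_correct_spec():
    """Sandwich and inverse-information agree loosely on a well-specified
    null simulation (diagonal ratio within [0.5, 2])."""
    coh = draw_cohort(DGPConfig(n=2000, seed=17, beta=(0.0, 0.0, 0.0)))
    fit = coxtv.fit_cox(coh.tbl_full, ["treat", "q"])
    ratio = np.diag(fit.cov_robust) / np.diag(fit.cov_model)
    assert np.all(ratio > 0.5) and np.all(ratio < 2.0)


def test_binary_group_parameter_recovery():
    """Two-group exponential data: beta-hat approaches the simulating log
    hazard ratio."""
    rng = np.random.default_rng(21)
    n = 4000
    x = (rng.uniform(size=n) < 0.5).astype(float)
    lam = 0.1 * np.exp(0.5 * x)
    t = rng.exponential(1.0 / lam)
    rows = [(i, 0.0, t[i], 1, 0, 0, x[i]) for i in range(n)]
    tbl = make_table(rows, q_names=("qx",))
    fit = coxtv.fit_cox(tbl, ["qx"])
    assert abs(fit.coef[0] - 0.5) < 3 * fit.se_model[0]
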