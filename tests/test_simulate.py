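import numpy as np
import pytest
from scipy import stats

from regimecox import coxtv
from regimecox.simulate import (
    DGPConfig,
    draw_cohort,
    sample_piecewise_exponential,
    simulate_counterfactual,
)
from regimecox.survdata import from_subject_times

from conftest import make_table


class TestPiecewiseExponentialSampler:
    def test_constant_rate_closed_form(self):
        # exp(-0.2 t) = e^{-1} at t = 5
        assert np.isclose(sample_piecewise_exponential([], [0.2], np.exp(-1.0)), 5.0)

    def test_two_piece_closed_form(self):
        # Lambda(2) = 1*1 + 2*1 = 3 -> u = e^{-3} inverts to t = 2
        t = sample_piecewise_exponential([1.0], [1.0, 2.0], np.exp(-3.0))
        assert np.isclose(t, 2.0)

    def test_empirical_mean_exponential(self):
        rng = np.random.default_rng(1)
        draws = sample_piecewise_exponential([], [0.2], rng.uniform(size=100_000))
        se = 5.0 / np.sqrt(100_000)
        assert abs(draws.mean() - 5.0) < 3 * se

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            sample_piecewise_exponential([1.0], [0.5, 0.0], 0.5)

    def test_matches_fine_grid_bernoulli_simulator(self):
        """Brute-force oracle: a discrete-time simulator on a 1e-3 grid with
        per-step survival prob (1 - lambda dt) must agree distributionally
        (two-sample KS distance < 0.02 at n = 1e5)."""
        breaks, rates = [1.0, 4.0], np.array([0.5, 1.2, 0.25])
        n = 100_000
        rng = np.random.default_rng(7)
        exact = sample_piecewise_exponential(breaks, rates, rng.uniform(size=n))

        dt, tmax = 1e-3, 60.0
        grid = np.arange(dt, tmax + dt, dt)
        lam = rates[np.searchsorted(breaks, grid, side="left")]
        surv = np.cumprod(1.0 - lam * dt)
        u = rng.uniform(size=n)
        idx = np.searchsorted(-surv, -u, side="right")
        approx = grid[np.minimum(idx, grid.size - 1)]
        ks = stats.ks_2samp(exact, approx).statistic
        assert ks < 0.02


@pytest.fixture(scope="module")
def big():
    return draw_cohort(DGPConfig(n=100_000, seed=5, beta=(0.0, 0.0, 0.0)))


class TestCohortMoments:
    def test_treatment_is_bernoulli_half(self, big):
        se = 0.5 / np.sqrt(big.A.size)
        assert abs(big.A.mean() - 0.5) < 3 * se

    def test_q0_mean_and_variance(self, big):
        # E[Q(0)] = 0.2 E[G] - 4 = -3 ; Var = 1 + 0.04 Var(G) = 2
        q0 = big.Q_raw[:, 0]
        assert abs(q0.mean() + 3.0) < 3 * np.sqrt(2.0 / q0.size)
        assert abs(q0.var() - 2.0) < 0.05

    def test_q_update_only_after_discontinuation(self, big):
        changed = big.Q_obs != big.Q_raw
        assert not changed[:, 0].any()
        for j, l in ((1, 5.0), (2, 10.0)):
            assert np.array_equal(changed[:, j], big.D < l)
            upd = big.D < l
            assert np.allclose(
                big.Q_obs[upd, j] - big.Q_raw[upd, j], np.log(l - big.D[upd])
            )

    def test_latent_times_positive(self, big):
        for arr in (big.D, big.R, big.T, big.C):
            assert np.all(arr > 0)


class TestObservedTables:
    def test_tables_match_per_subject_constructor(self):
        cohort = draw_cohort(DGPConfig(n=60, seed=12, beta=(0.1, 0.2, -0.1)))
        for censor, tbl in ((False, cohort.tbl_full), (True, cohort.tbl_regime)):
            ptr = tbl.indptr()
            for i in range(cohort.cfg.n):
                qpath = ([5.0, 10.0], cohort.Q_obs[i])
                one, out = from_subject_times(
                    i, A=int(cohort.A[i]), X={"xq0": cohort.Q_raw[i, 0]},
                    Q_path={"q": qpath}, D=cohort.D[i], R=cohort.R[i],
                    T=cohort.T[i], C=cohort.C[i], censor_at_violation=censor,
                )
                sl = slice(ptr[i], ptr[i + 1])
                assert np.allclose(one.stop, tbl.stop[sl])
                assert np.array_equal(one.event, tbl.event[sl])
                assert np.array_equal(one.zv, tbl.zv[sl])
                assert np.allclose(one.q["q"], tbl.q["q"][sl])
                if censor:
                    assert out.S == cohort.S[i] and out.GammaS == cohort.GammaS[i]
                else:
                    assert out.U == cohort.U[i] and out.Delta == cohort.Delta[i]

    def test_regime_table_never_extends_past_violation(self):
        cohort = draw_cohort(DGPConfig(n=500, seed=3))
        end = np.minimum(np.minimum(cohort.T, cohort.C), cohort.R)
        last = cohort.tbl_regime.indptr()[1:] - 1
        assert np.allclose(cohort.tbl_regime.stop[last], end)

    def test_reproducible_bit_for_bit(self):
        a = draw_cohort(DGPConfig(n=200, seed=8), replicate=3)
        b = draw_cohort(DGPConfig(n=200, seed=8), replicate=3)
        assert np.array_equal(a.T, b.T) and np.array_equal(a.Q_obs, b.Q_obs)
        c = draw_cohort(DGPConfig(n=200, seed=8), replicate=4)
        assert not np.array_equal(a.T, c.T)


class TestCounterfactualOracle:
    def test_null_effect_regimes_indistinguishable(self):
        cfg = DGPConfig(n=20_000, seed=31, beta=(0.0, 0.0, 0.0))
        t_never = simulate_counterfactual(cfg, a=1, nu=np.inf, replicate=1)
        t_early = simulate_counterfactual(cfg, a=1, nu=0.1, replicate=2)
        ks = stats.ks_2samp(t_never, t_early).statistic
        assert ks < 0.02

    def test_pooled_cox_recovers_arm_contrast(self):
        # under "never discontinue", 1-z == 1 so the arm contrast is b1 + b3
        cfg = DGPConfig(n=20_000, seed=32, beta=(0.3, 0.1, 0.2))
        t1 = simulate_counterfactual(cfg, a=1, nu=np.inf, replicate=1)
        t0 = simulate_counterfactual(cfg, a=0, nu=np.inf, replicate=2)
        rows = [(k, 0.0, t, 1, 1, 0) for k, t in enumerate(t1)]
        rows += [(len(t1) + k, 0.0, t, 1, 0, 0) for k, t in enumerate(t0)]
        tbl = make_table(rows)
        fit = coxtv.fit_cox(tbl, ["treat"])
        assert abs(fit.coef[0] - 0.5) < 0.05

    def test_discontinuation_effect_monotone_in_beta2(self):
        # larger b2 (on-treatment coding) widens the gap between never- and
        # early-discontinuation regimes
        gaps = []
        for b2 in (0.2, 0.8):
            cfg = DGPConfig(n=20_000, seed=33, beta=(0.0, b2, 0.0))
            t_never = simulate_counterfactual(cfg, a=0, nu=np.inf, replicate=1)
            t_early = simulate_counterfactual(cfg, a=0, nu=0.5, replicate=2)
            gaps.append(np.median(t_early) - np.median(t_never))
        assert gaps[1] > gaps[0] > 0
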