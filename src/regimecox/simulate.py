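"""Cohort simulator for the treatment-discontinuation study conditions.

The data-generating process emulates a two-arm observational cohort in which
patients may discontinue their initial treatment (time ``D``), violate the
treatment regime under study (time ``R``, e.g. switch treatments or restart
after discontinuing), fail (``T``) or be censored (``C``).  All four latent
times follow piecewise-exponential proportional-hazards models driven by the
initial treatment ``A``, a time-dependent covariate ``Q(t)`` measured at
t = 0, 5, 10 (held constant between measurements), and the discontinuation
indicator ``Zv(t)``:

* ``A ~ Bernoulli(0.5)``; a latent frailty ``G ~ Exponential(rate 0.2)``;
* ``(Q(0), Q(5), Q(10)) ~ N(0.2 G - 4, Sigma)`` with ``Sigma_ij = 0.7^|i-j|``;
* ``lambda_D(t) = 0.15 exp(0.15 A + 0.15 Q(t))`` (raw Q);
* after discontinuation, measurements at times ``l > D`` are updated to
  ``Q(l) + log(l - D)`` (regime confounding: past exposure feeds the
  covariate that predicts future exposure and the outcome);
* ``lambda_R(t) = 0.15 exp(0.15 A + 0.15 (1 - Zv(t)))``;
* ``lambda_T(t) = 0.15 exp(b1 A + b2 (1-Zv(t)) + b3 A (1-Zv(t)) + 0.1 Q(0))``,
  and ``T`` is multiplied by 5 whenever ``R < T`` and ``A = 1`` (regime
  violation affects the failure time in one arm);
* ``lambda_C(t) = 0.025 exp(0.15 A + 0.15 (1 - Zv(t)))``.

Under this scheme the marginal structural model for the regime "take
treatment a, discontinue at nu" is
``lambda_{a nu}(t) = lambda_00(t) exp(b1 a + b2 (1-z_nu(t)) + b3 a (1-z_nu(t)))``
(note the on-treatment coding ``1 - z``).

Latent times are sampled by exact cumulative-hazard inversion of the
piecewise-constant hazards.  One counter-based Philox stream per replicate,
keyed by (seed, replicate index), makes every cohort reproducible
independently of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .survdata import CountingProcessTable

__all__ = [
    "DGPConfig",
    "LatentCohort",
    "sample_piecewise_exponential",
    "draw_cohort",
    "simulate_counterfactual",
]


@dataclass
class DGPConfig:
    """Parameters of the data-generating process (defaults are the study
    conditions of the simulation experiment)."""

    n: int = 1000
    seed: int = 0
    beta: tuple = (0.0, 0.0, 0.0)  # (b1, b2, b3) on the 1-z coding
    p_treat: float = 0.5
    g_rate: float = 0.2
    q_mean_slope: float = 0.2
    q_mean_shift: float = -4.0
    q_cov_base: float = 0.7
    q_times: tuple = (0.0, 5.0, 10.0)
    disc_base: float = 0.15
    disc_coefA: float = 0.15
    disc_coefQ: float = 0.15
    viol_base: float = 0.15
    viol_coefA: float = 0.15
    viol_coefOn: float = 0.15  # coefficient on 1 - Zv(t)
    ev_base: float = 0.15
    ev_coefQ0: float = 0.1
    viol_multiplier: float = 5.0
    cens_base: float = 0.025
    cens_coefA: float = 0.15
    cens_coefOn: float = 0.15

    def validate(self):
        for name in ("g_rate", "disc_base", "viol_base", "ev_base", "cens_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not np.all(np.diff(self.q_times) > 0):
            raise ValueError("q_times must be strictly increasing")
        return self


@dataclass
class LatentCohort:
    """Full latent variables and derived observables for one cohort.

    ``tbl_full`` ends follow-up at ``min(T, C)`` (no artificial censoring);
    ``tbl_regime`` ends it at ``min(T, C, R)`` (artificially censored at
    regime violation).  Both carry columns ``q`` (time-dependent covariate)
    and ``xq0`` (baseline value Q(0)).
    """

    cfg: DGPConfig
    A: np.ndarray
    G: np.ndarray
    Q_raw: np.ndarray
    Q_obs: np.ndarray
    D: np.ndarray
    R: np.ndarray
    T: np.ndarray
    C: np.ndarray
    U: np.ndarray = None
    Delta: np.ndarray = None
    V: np.ndarray = None
    GammaV: np.ndarray = None
    S: np.ndarray = None
    GammaS: np.ndarray = None
    tbl_full: CountingProcessTable = None
    tbl_regime: CountingProcessTable = None


def _rng(seed: int, replicate: int = 0) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=[int(seed), int(replicate)]))


def sample_piecewise_exponential(breaks, rates, u):
    """Invert a piecewise-constant cumulative hazard at ``-log(u)``.

    ``breaks`` are the interior change times (sorted, length m) and ``rates``
    the m+1 hazard levels, the last extending to infinity.  Returns the time
    t with ``exp(-integral_0^t rate) = u``.
    """
    breaks = np.asarray(breaks, float)
    rates = np.asarray(rates, float)
    if np.any(rates <= 0):
        raise ValueError("rates must be > 0")
    e = -np.log(u)
    edges = np.concatenate(([0.0], breaks))
    widths = np.diff(np.concatenate((edges, [np.inf])))
    cumhaz = np.concatenate(([0.0], np.cumsum(rates[:-1] * widths[:-1])))
    k = np.searchsorted(cumhaz, e, side="right") - 1
    return edges[k] + (e - cumhaz[k]) / rates[k]


def _pwexp_rows(edges, rates, u):
    """Row-wise piecewise-exponential inversion.

    ``edges``: (n, m) interior breakpoints per subject (nondecreasing along
    axis 1; use +inf to disable a breakpoint).  ``rates``: (n, m+1) hazard
    levels.  ``u``: (n,) uniforms.
    """
    e = -np.log(u)
    n, m = edges.shape
    fin = np.where(np.isfinite(edges), edges, 0.0)
    prev = np.hstack([np.zeros((n, 1)), fin])
    widths = np.where(np.isfinite(edges), edges - prev[:, :-1], np.inf)
    seg = rates[:, :-1] * np.where(np.isfinite(widths), widths, 0.0)
    seg[~np.isfinite(widths)] = np.inf
    cum = np.hstack([np.zeros((n, 1)), np.cumsum(seg, axis=1)])
    k = (e[:, None] >= cum[:, 1:]).sum(axis=1)  # segment index 0..m
    rows = np.arange(n)
    left = np.hstack([np.zeros((n, 1)), fin])[rows, k]
    return left + (e - cum[rows, k]) / rates[rows, k]


def draw_cohort(cfg: DGPConfig, replicate: int = 0) -> LatentCohort:
    """Generate one cohort (latent variables plus observed tables)."""
    cfg.validate()
    rng = _rng(cfg.seed, replicate)
    n = cfg.n
    b1, b2, b3 = cfg.beta

    A = (rng.uniform(size=n) < cfg.p_treat).astype(np.int8)
    G = rng.exponential(scale=1.0 / cfg.g_rate, size=n)
    tq = np.asarray(cfg.q_times)
    m = tq.size
    cov = cfg.q_cov_base ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    L = np.linalg.cholesky(cov)
    Q_raw = (cfg.q_mean_slope * G + cfg.q_mean_shift)[:, None] + rng.standard_normal(
        (n, m)
    ) @ L.T

    # discontinuation: hazard pieces follow the raw Q path (risk ends at D)
    edges_q = np.broadcast_to(tq[1:], (n, m - 1))
    rates_D = cfg.disc_base * np.exp(cfg.disc_coefA * A[:, None] + cfg.disc_coefQ * Q_raw)
    D = _pwexp_rows(np.ascontiguousarray(edges_q, float), rates_D, rng.uniform(size=n))

    # regime confounding: measurements at l > D shift by log(l - D)
    Q_obs = Q_raw.copy()
    for j in range(1, m):
        upd = D < tq[j]
        Q_obs[upd, j] += np.log(tq[j] - D[upd])

    # regime violation: hazard switches when Zv turns on at D
    one = np.ones(n)
    edges_D = D[:, None]
    rates_R = cfg.viol_base * np.exp(
        cfg.viol_coefA * A[:, None] + cfg.viol_coefOn * np.column_stack([one, 0 * one])
    )
    R = _pwexp_rows(edges_D, rates_R, rng.uniform(size=n))

    # failure: depends on A, 1-Zv(t) and the baseline measurement Q(0)
    lp0 = b1 * A + cfg.ev_coefQ0 * Q_raw[:, 0]
    rates_T = cfg.ev_base * np.exp(
        lp0[:, None] + np.column_stack([b2 * one + b3 * A, 0 * one])
    )
    T = _pwexp_rows(edges_D, rates_T, rng.uniform(size=n))
    T = np.where((R < T) & (A == 1), cfg.viol_multiplier * T, T)

    # censoring
    rates_C = cfg.cens_base * np.exp(
        cfg.cens_coefA * A[:, None] + cfg.cens_coefOn * np.column_stack([one, 0 * one])
    )
    C = _pwexp_rows(edges_D, rates_C, rng.uniform(size=n))

    U = np.minimum(T, C)
    Delta = (T <= C).astype(np.int8)
    V = np.minimum(D, U)
    GammaV = (D <= U).astype(np.int8)
    S = np.minimum(R, U)
    GammaS = (R <= U).astype(np.int8)

    tbl_full = _build_table(cfg, A, Q_raw, Q_obs, D, U, Delta)
    end_regime = np.minimum(U, R)
    ev_regime = (T <= np.minimum(C, R)).astype(np.int8)
    tbl_regime = _build_table(cfg, A, Q_raw, Q_obs, D, end_regime, ev_regime)

    return LatentCohort(
        cfg=cfg, A=A, G=G, Q_raw=Q_raw, Q_obs=Q_obs, D=D, R=R, T=T, C=C,
        U=U, Delta=Delta, V=V, GammaV=GammaV, S=S, GammaS=GammaS,
        tbl_full=tbl_full, tbl_regime=tbl_regime,
    )


def _build_table(cfg, A, Q_raw, Q_obs, D, end, event) -> CountingProcessTable:
    """Vectorized counting-process table: breaks at measurement times and D."""
    n = A.shape[0]
    tq = np.asarray(cfg.q_times, float)
    cand = np.column_stack([np.broadcast_to(tq[1:], (n, tq.size - 1)), D])
    cand = np.where(cand < end[:, None], cand, np.inf)
    cand.sort(axis=1)
    n_break = np.isfinite(cand).sum(axis=1)
    reps = n_break + 1
    total = int(reps.sum())
    subj = np.repeat(np.arange(n), reps)
    offsets = np.concatenate(([0], np.cumsum(reps)))
    pos = np.arange(total) - offsets[subj]

    bounds = np.hstack([np.zeros((n, 1)), cand, end[:, None]])
    # move each subject's end into slot n_break+1
    bounds[np.arange(n), n_break + 1] = end
    start = bounds[subj, pos]
    stop = bounds[subj, pos + 1]
    ev = np.where(pos == n_break[subj], event[subj], 0).astype(np.int8)
    zv = (start >= D[subj]).astype(np.int8)
    piece = np.searchsorted(tq, start, side="right") - 1
    q_val = np.where(zv == 1, Q_obs[subj, piece], Q_raw[subj, piece])
    # pre-D intervals always carry the raw measurement; post-D intervals carry
    # the updated measurement when the measurement time exceeds D (Q_obs
    # equals Q_raw otherwise), so indexing Q_obs after D is exact.
    return CountingProcessTable(
        ids=np.arange(n),
        subj=subj,
        start=start,
        stop=stop,
        event=ev,
        treat=A[subj],
        zv=zv,
        q={"q": q_val},
        x={"xq0": Q_raw[subj, 0]},
    )


def simulate_counterfactual(cfg: DGPConfig, a: int, nu: float, n: int | None = None,
                            replicate: int = 0) -> np.ndarray:
    """Potential failure times under the regime "take a, discontinue at nu".

    Forces ``A = a`` and ``D = nu`` (with the covariate update applied),
    forbids regime violation and censoring, and applies no failure-time
    multiplier.  Returns the failure times only (oracle for causal
    contrasts).
    """
    cfg.validate()
    n = cfg.n if n is None else n
    rng = _rng(cfg.seed, replicate)
    b1, b2, b3 = cfg.beta
    G = rng.exponential(scale=1.0 / cfg.g_rate, size=n)
    tq = np.asarray(cfg.q_times)
    m = tq.size
    cov = cfg.q_cov_base ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    Q = (cfg.q_mean_slope * G + cfg.q_mean_shift)[:, None] + rng.standard_normal(
        (n, m)
    ) @ np.linalg.cholesky(cov).T
    one = np.ones(n)
    lp0 = b1 * a + cfg.ev_coefQ0 * Q[:, 0]
    rates_T = cfg.ev_base * np.exp(
        lp0[:, None] + np.column_stack([(b2 + b3 * a) * one, 0 * one])
    )
    edges = np.full((n, 1), np.inf if np.isinf(nu) else float(nu))
    return _pwexp_rows(edges, rates_T, rng.uniform(size=n))
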