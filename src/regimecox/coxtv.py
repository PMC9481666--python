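"""Weighted time-dependent Cox proportional-hazards engine.

Fits the (case-)weighted Cox partial likelihood on counting-process data with
Breslow tie handling, and provides the Breslow baseline cumulative hazard,
per-subject survival prediction along an observed covariate path, and the
clustered sandwich (robust) covariance with score residuals aggregated within
subject.  Weights enter score and information as case weights on interval
contributions (the estimating-equation form of inverse-probability-weighted
partial likelihoods); no re-normalization is applied.

Risk sets are defined by half-open interval membership: a row ``(start,
stop]`` is at risk at time ``t`` iff ``start < t <= stop``.  Risk-set sums at
all event times are computed with two reverse cumulative sums (over rows
sorted by ``stop`` and by ``start``), giving an O((rows + events) log rows)
Newton iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .survdata import CountingProcessTable

__all__ = [
    "CoxFit",
    "fit_cox",
    "null_fit",
    "breslow_cumhaz",
    "predict_survival",
    "hazard_increments",
    "cumhaz_at",
    "hazard_increment_at",
    "ConvergenceWarning",
]


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class CoxFit:
    """A fitted (possibly weighted) time-dependent Cox model.

    ``baseline_times`` / ``baseline_incr`` hold the Breslow baseline hazard
    increments at the observed event times; the cumulative baseline hazard is
    their running sum (right-continuous, 0 at t=0).
    """

    covariates: list
    coef: np.ndarray
    cov_model: np.ndarray
    cov_robust: np.ndarray
    baseline_times: np.ndarray
    baseline_incr: np.ndarray
    n_events: int
    converged: bool
    loglik: float
    monotone: bool = False
    _baseline_cum: np.ndarray = field(default=None, repr=False)

    @property
    def se_model(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_model)) if self.coef.size else np.array([])

    @property
    def se_robust(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_robust)) if self.coef.size else np.array([])

    def baseline_cumhaz(self, t) -> np.ndarray:
        """Breslow cumulative baseline hazard, right-continuous."""
        idx = np.searchsorted(self.baseline_times, np.asarray(t, float), side="right")
        return self._cum()[idx]

    def baseline_cumhaz_left(self, t) -> np.ndarray:
        """Left limit of the cumulative baseline hazard (jumps at t excluded)."""
        idx = np.searchsorted(self.baseline_times, np.asarray(t, float), side="left")
        return self._cum()[idx]

    def _cum(self) -> np.ndarray:
        if self._baseline_cum is None:
            self._baseline_cum = np.concatenate(([0.0], np.cumsum(self.baseline_incr)))
        return self._baseline_cum

    def export_baseline(self, path) -> None:
        """Write (time, cumulative hazard) as a two-column CSV."""
        import pandas as pd

        pd.DataFrame(
            {"time": self.baseline_times, "cumhaz": np.cumsum(self.baseline_incr)}
        ).to_csv(path, index=False)


def null_fit(covariates=()) -> CoxFit:
    """A degenerate fit with no events: survival predictions are all 1."""
    p = len(covariates)
    return CoxFit(
        covariates=list(covariates),
        coef=np.zeros(p),
        cov_model=np.zeros((p, p)),
        cov_robust=np.zeros((p, p)),
        baseline_times=np.array([]),
        baseline_incr=np.array([]),
        n_events=0,
        converged=True,
        loglik=0.0,
    )


def _risk_sums(v_stop, comp_start, idx_stop, idx_start):
    """Risk-set sums at event times for stop-ordered column block ``v_stop``.

    The sum over rows with ``start < t <= stop`` equals (prefix sum over
    rows with start < t) minus (prefix sum over rows with stop < t);
    ``comp_start`` reorders the stop-ordered block into start order.
    """
    ps = np.cumsum(v_stop, axis=0)
    ps = np.vstack([np.zeros((1, v_stop.shape[1])), ps])
    pa = np.cumsum(v_stop[comp_start], axis=0)
    pa = np.vstack([np.zeros((1, v_stop.shape[1])), pa])
    return pa[idx_start] - ps[idx_stop]


def fit_cox(
    tbl: CountingProcessTable,
    covariates,
    use_weights: bool = False,
    *,
    max_iter: int = 100,
    tol: float = 1e-9,
    loglik_tol: float = 1e-12,
    compute_robust: bool = True,
) -> CoxFit:
    """Maximize the weighted Cox log partial likelihood (Breslow ties).

    Parameters
    ----------
    tbl : CountingProcessTable
        Counting-process data; must contain at least one event.
    covariates : sequence of str
        Design column names resolved through ``tbl.column`` (may be empty,
        in which case only the baseline hazard is estimated).
    use_weights : bool
        Use ``tbl.weight`` as case weights on interval contributions.

    Newton-Raphson with step-halving; convergence when the max absolute
    coefficient change is below ``tol`` or the relative log-likelihood change
    is below ``loglik_tol``.  Monotone likelihood (divergent coefficients) is
    reported through ``converged=False`` / ``monotone=True`` with the last
    iterate rather than raised, so simulation loops survive degenerate
    replicates.
    """
    covariates = list(covariates)
    p = len(covariates)
    Xd = tbl.design(covariates)
    if not np.all(np.isfinite(Xd)):
        raise ValueError("non-finite values in design columns")
    w = np.ones(tbl.n_rows)
    if use_weights:
        if tbl.weight is None:
            raise ValueError("use_weights=True but table has no weight column")
        w = np.asarray(tbl.weight, float)
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite and nonnegative")

    ev = tbl.event.astype(bool)
    n_events = int(ev.sum())
    if n_events == 0:
        raise ValueError("table has no events")

    start, stop = tbl.start, tbl.stop
    so_stop = np.argsort(stop, kind="stable")
    so_start = np.argsort(start, kind="stable")
    inv_stop = np.empty_like(so_stop)
    inv_stop[so_stop] = np.arange(so_stop.size)
    comp_start = inv_stop[so_start]  # start order expressed in stop order
    sorted_stop = stop[so_stop]
    sorted_start = start[so_start]

    # stop-ordered working copies (so the hot loop needs one gather, not two)
    Xs = Xd[so_stop]
    ws = w[so_stop]
    evs = ev[so_stop]

    ut = np.unique(stop[ev])  # distinct event times
    idx_stop = np.searchsorted(sorted_stop, ut, side="left")
    idx_start = np.searchsorted(sorted_start, ut, side="left")
    # weighted event mass and weighted covariate sums at each event time
    ev_pos = np.searchsorted(ut, stop[ev])
    wE = np.zeros(ut.size)
    np.add.at(wE, ev_pos, w[ev])
    s_ev = np.zeros(p)
    if p:
        s_ev = (w[ev, None] * Xd[ev]).sum(axis=0)

    iu, ju = (np.triu_indices(p) if p else (np.array([], int), np.array([], int)))

    def eval_ll(beta):
        """Log partial likelihood and the S0 ingredients only (cheap)."""
        lp = Xs @ beta if p else np.zeros(tbl.n_rows)
        np.clip(lp, -500, 500, out=lp)
        we = ws * np.exp(lp)
        S0 = _risk_sums(we[:, None], comp_start, idx_stop, idx_start)[:, 0]
        ll = float((ws[evs] * lp[evs]).sum() - (wE * np.log(S0)).sum())
        return ll, lp, we, S0

    def eval_derivs(lp, we, S0):
        S1 = _risk_sums(we[:, None] * Xs, comp_start, idx_stop, idx_start)
        S2u = _risk_sums(
            we[:, None] * (Xs[:, iu] * Xs[:, ju]), comp_start, idx_stop, idx_start
        )
        xbar = S1 / S0[:, None]
        U = s_ev - (wE[:, None] * xbar).sum(axis=0)
        S2 = np.zeros((ut.size, p, p))
        S2[:, iu, ju] = S2u
        S2[:, ju, iu] = S2u
        info = np.einsum("t,tij->ij", wE, S2 / S0[:, None, None]) - np.einsum(
            "t,ti,tj->ij", wE, xbar, xbar
        )
        return U, info, xbar

    beta = np.zeros(p)
    ll, lp, we, S0 = eval_ll(beta)
    if p:
        U, info, xbar = eval_derivs(lp, we, S0)
    else:
        U = info = xbar = None
    converged = p == 0
    monotone = False
    for _ in range(max_iter if p else 0):
        try:
            delta = np.linalg.solve(info, U)
        except np.linalg.LinAlgError:
            _raise_singular(info, covariates)
        if np.linalg.cond(info) > 1e12:
            _raise_singular(info, covariates)
        step = 1.0
        for _half in range(25):
            cand = beta + step * delta
            ll_new, lp_new, we_new, S0_new = eval_ll(cand)
            if ll_new >= ll - 1e-12 or not np.isfinite(ll_new):
                break
            step /= 2.0
        if not np.isfinite(ll_new):
            monotone = True
            break
        change = np.max(np.abs(cand - beta))
        rel = abs(ll_new - ll) / (abs(ll) + 1e-300)
        beta, ll, lp, we, S0 = cand, ll_new, lp_new, we_new, S0_new
        U, info, xbar = eval_derivs(lp, we, S0)
        if change < tol or rel < loglik_tol:
            converged = True
            break
    if p and (np.max(np.abs(beta)) > 20 or not converged):
        monotone = np.max(np.abs(beta)) > 20
        if monotone:
            converged = False
        warnings.warn(
            "possible monotone likelihood / non-convergence "
            f"(|beta|max={np.max(np.abs(beta)):.3g})",
            ConvergenceWarning,
        )

    dLam0 = wE / S0
    if p:
        cov_model = np.linalg.inv(info)
    else:
        cov_model = np.zeros((0, 0))

    cov_robust = cov_model
    if compute_robust and p:
        cov_robust = _sandwich(
            tbl, Xd, w, beta, ut, dLam0, xbar, cov_model
        )

    return CoxFit(
        covariates=covariates,
        coef=beta,
        cov_model=cov_model,
        cov_robust=cov_robust,
        baseline_times=ut,
        baseline_incr=dLam0,
        n_events=n_events,
        converged=converged,
        loglik=ll,
        monotone=monotone,
    )


def _raise_singular(info, covariates):
    # name the (nearly) collinear columns via the smallest eigenvector
    try:
        _vals, vecs = np.linalg.eigh(info)
        load = np.abs(vecs[:, 0])
        cols = [c for c, l in zip(covariates, load) if l > 0.1 * load.max()]
    except Exception:  # pragma: no cover
        cols = covariates
    raise np.linalg.LinAlgError(
        f"singular information matrix; collinear columns likely among {cols}"
    )


def _sandwich(tbl, Xd, w, beta, ut, dLam0, xbar, cov_model):
    """Clustered sandwich covariance (cluster = subject id).

    Score residuals are computed per row, weighted, summed within subject,
    and outer-producted: cov = A^{-1} B A^{-1}.
    """
    lp = Xd @ beta if beta.size else np.zeros(tbl.n_rows)
    elp = np.exp(np.clip(lp, -500, 500))
    cumL = np.concatenate(([0.0], np.cumsum(dLam0)))
    cumP = np.vstack([np.zeros((1, beta.size)), np.cumsum(dLam0[:, None] * xbar, axis=0)])
    a = np.searchsorted(ut, tbl.start, side="right")
    b = np.searchsorted(ut, tbl.stop, side="right")
    dL = cumL[b] - cumL[a]
    dP = cumP[b] - cumP[a]
    resid = -elp[:, None] * (Xd * dL[:, None] - dP)
    ev = tbl.event.astype(bool)
    pos = np.searchsorted(ut, tbl.stop[ev])
    resid[ev] += Xd[ev] - xbar[pos]
    resid *= w[:, None]
    G = np.column_stack(
        [
            np.bincount(tbl.subj, weights=resid[:, j], minlength=tbl.n_subjects)
            for j in range(beta.size)
        ]
    )
    B = G.T @ G
    return cov_model @ B @ cov_model


def partial_loglik(tbl, covariates, beta, use_weights=False, with_score=False):
    """Weighted log partial likelihood (and score) at a fixed ``beta``.

    Diagnostic helper; shares the risk-set machinery of :func:`fit_cox`.
    """
    covariates = list(covariates)
    p = len(covariates)
    beta = np.asarray(beta, float)
    Xd = tbl.design(covariates)
    w = np.ones(tbl.n_rows)
    if use_weights:
        w = np.asarray(tbl.weight, float)
    ev = tbl.event.astype(bool)
    so_stop = np.argsort(tbl.stop, kind="stable")
    so_start = np.argsort(tbl.start, kind="stable")
    inv_stop = np.empty_like(so_stop)
    inv_stop[so_stop] = np.arange(so_stop.size)
    comp_start = inv_stop[so_start]
    ut = np.unique(tbl.stop[ev])
    idx_stop = np.searchsorted(tbl.stop[so_stop], ut, side="left")
    idx_start = np.searchsorted(tbl.start[so_start], ut, side="left")
    wE = np.zeros(ut.size)
    np.add.at(wE, np.searchsorted(ut, tbl.stop[ev]), w[ev])
    lp = Xd @ beta if p else np.zeros(tbl.n_rows)
    we = (w * np.exp(lp))[so_stop]
    cols = we[:, None] * np.hstack([np.ones((tbl.n_rows, 1)), Xd[so_stop]])
    sums = _risk_sums(cols, comp_start, idx_stop, idx_start)
    S0 = sums[:, 0]
    ll = float((w[ev] * lp[ev]).sum() - (wE * np.log(S0)).sum())
    if not with_score:
        return ll
    s_ev = (w[ev, None] * Xd[ev]).sum(axis=0) if p else np.zeros(0)
    score = s_ev - (wE[:, None] * sums[:, 1:] / S0[:, None]).sum(axis=0)
    return ll, score


# -- baseline / prediction helpers ------------------------------------------


def breslow_cumhaz(fit: CoxFit):
    """The Breslow baseline cumulative hazard as ``(times, increments)``.

    The step function is right-continuous, nondecreasing, and 0 at t=0;
    evaluate it with ``fit.baseline_cumhaz``.
    """
    return fit.baseline_times, fit.baseline_incr


def cumhaz_at(fit: CoxFit, tbl: CountingProcessTable, subj, t, left=True):
    """Subject-specific cumulative hazard along an observed covariate path.

    ``tbl`` supplies each subject's interval-constant covariate path (any
    table with the model's design columns; normally the table the model was
    fitted on).  For query pairs ``(subj[k], t[k])`` returns
    ``Lambda_i(t-) = sum_rows exp(lp_row) * (Lam0(min(stop,t)-) - Lam0(start))``
    using the left-continuous linear predictor.  With ``left=False`` the jump
    at ``t`` itself is included.  Queries must lie within the subject's
    recorded follow-up (``0 < t <= last stop``).
    """
    subj = np.asarray(subj)
    t = np.asarray(t, float)
    lp = tbl.design(fit.covariates) @ fit.coef if fit.coef.size else np.zeros(tbl.n_rows)
    elp = np.exp(np.clip(lp, -500, 500))
    L0_start = fit.baseline_cumhaz(tbl.start)
    L0_stop = fit.baseline_cumhaz(tbl.stop)
    contrib = elp * (L0_stop - L0_start)
    cum = np.concatenate(([0.0], np.cumsum(contrib)))
    indptr = tbl.indptr()
    # locate, for each query, the row with start < t <= stop via a composite
    # sort key subject + start/(Tmax+1) (fraction strictly < 1)
    tmax = float(tbl.stop.max()) + 1.0
    key_rows = tbl.subj + tbl.start / tmax
    key_q = subj + np.minimum(t, tmax - 1.0) / tmax
    row = np.searchsorted(key_rows, key_q, side="left") - 1
    if np.any(row < 0) or np.any(tbl.subj[row] != subj) or np.any(t > tbl.stop[row] + 1e-9):
        bad = np.flatnonzero(
            (row < 0) | (tbl.subj[row] != subj) | (t > tbl.stop[row] + 1e-9)
        )[0]
        raise ValueError(
            f"query time {t[bad]} outside recorded follow-up of subject "
            f"{tbl.ids[subj[bad]]!r}"
        )
    L0_t = fit.baseline_cumhaz_left(t) if left else fit.baseline_cumhaz(t)
    partial = elp[row] * (L0_t - L0_start[row])
    return cum[row] - cum[indptr[subj]] + partial


def survival_at(fit: CoxFit, tbl: CountingProcessTable, subj, t, left=True):
    """``K(t) = exp(-Lambda_i(t))`` along the recorded covariate path."""
    return np.exp(-cumhaz_at(fit, tbl, subj, t, left=left))


def predict_survival(fit: CoxFit, subject_path):
    """Survival function ``t -> K(t)`` for one covariate path.

    ``subject_path`` is ``(breaks, X)``: interior change times (sorted) and an
    ``(len(breaks)+1, p)`` matrix of covariate values, row k holding on
    ``(breaks[k-1], breaks[k]]`` with the last row extending to infinity.
    Returns a vectorized callable; ``K(0) = 1`` and K is nonincreasing,
    computed with the left-continuous linear predictor:
    ``K(t) = exp(-sum_{s<=t} dLam0(s) exp(lp(s-)))``.
    """
    breaks, X = subject_path
    breaks = np.asarray(breaks, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != breaks.size + 1:
        raise ValueError("covariate path must have len(breaks)+1 rows")
    lp = X @ fit.coef if fit.coef.size else np.zeros(X.shape[0])
    elp = np.exp(lp)
    ut, dL = fit.baseline_times, fit.baseline_incr
    piece = np.searchsorted(breaks, ut, side="left")  # lp(s-) left-continuous
    incr = dL * elp[piece] if ut.size else dL
    cum = np.concatenate(([0.0], np.cumsum(incr)))

    def K(t):
        t = np.asarray(t, float)
        idx = np.searchsorted(ut, t, side="right")
        return np.exp(-cum[idx])

    return K


def hazard_increments(fit: CoxFit, subject_path, t):
    """Increment of the subject's cumulative hazard at time(s) ``t``.

    Returns ``dLam0(t) * exp(lp(t-))`` if ``t`` is an observed event time of
    the fitted model, else 0.  Consistent with ``predict_survival`` via
    ``K(t) = exp(-sum of increments up to t)``.
    """
    breaks, X = subject_path
    breaks = np.asarray(breaks, float)
    X = np.atleast_2d(np.asarray(X, float))
    lp = X @ fit.coef if fit.coef.size else np.zeros(X.shape[0])
    elp = np.exp(lp)
    t = np.asarray(t, float)
    pos = np.searchsorted(fit.baseline_times, t)
    pos_c = np.minimum(pos, max(fit.baseline_times.size - 1, 0))
    is_event = (
        (fit.baseline_times[pos_c] == t) if fit.baseline_times.size else np.zeros(t.shape, bool)
    )
    piece = np.searchsorted(breaks, t, side="left")
    out = np.where(
        is_event,
        (fit.baseline_incr[pos_c] if fit.baseline_times.size else 0.0) * elp[piece],
        0.0,
    )
    return out


def hazard_increment_at(fit: CoxFit, tbl: CountingProcessTable, subj, t):
    """``dLam0(t) * exp(lp(t-))`` for table subjects at their own times.

    ``t`` must be observed event times of the fitted model (used for the
    ratio of numerator to denominator hazard increments at the observed
    discontinuation time, where the baseline jump masses cancel).
    """
    subj = np.asarray(subj)
    t = np.asarray(t, float)
    pos = np.searchsorted(fit.baseline_times, t)
    if np.any(pos >= fit.baseline_times.size) or np.any(fit.baseline_times[np.minimum(pos, fit.baseline_times.size - 1)] != t):
        raise ValueError("hazard_increment_at: t is not an observed event time")
    lp = tbl.design(fit.covariates) @ fit.coef if fit.coef.size else np.zeros(tbl.n_rows)
    elp = np.exp(np.clip(lp, -500, 500))
    tmax = float(tbl.stop.max()) + 1.0
    key_rows = tbl.subj + tbl.start / tmax
    key_q = subj + t / tmax
    row = np.searchsorted(key_rows, key_q, side="left") - 1
    return fit.baseline_incr[pos] * elp[row]
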