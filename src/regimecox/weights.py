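"""Assembly of the inverse-probability-of-regime-compliance (IPRC) weights.

For target treatment arm ``a``, the subject- and time-specific weight is the
product of three components, of which exactly one "line" is active at any
``(i, t)``:

* C1, treatment: ``1(A_i = a) / pi_A(X_i)`` -- corrects for non-randomized
  treatment (optionally stabilized by the marginal ``pr(A = a)``);
* C2, artificial censoring: ``1(S_i >= t) * K_R(t | X, A) /
  K_R(t | history, Zv)`` -- corrects for censoring subjects at regime
  violation;
* C3, discontinuation (regime confounding), branching on the subject's
  discontinuation status at ``t``:

  - not yet discontinued (``t <= V_i``):
    ``K_D(t | X, A) / K_D(t | history)``;
  - discontinued at ``V_i < t``: the ratio of numerator to denominator
    hazard-increment-times-survival at ``V_i`` (Breslow jump masses cancel),
    constant thereafter.

Weights are piecewise constant and left-continuous; for subjects on the
other arm (``A_i != a``) or past ``S_i`` the weight is zero.  The change
grid is the set of failure event times intersected with each subject's
at-risk window (plus the subject's own interval boundaries, which include
covariate changes, ``V_i`` and ``S_i``): the weighted estimating equations
only read the weight at failure event times over the at-risk rows, so a
piecewise-constant representation on this grid is exact there.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import coxtv
from .nuisance import NuisanceBundle, PositivityError
from .survdata import CountingProcessTable

__all__ = [
    "WeightSeries",
    "assemble_iprc",
    "combine_by_arm",
    "truncate",
    "attach_weights",
    "weight_diagnostics",
]


@dataclass
class WeightSeries:
    """Per-subject piecewise-constant, left-continuous weight trajectories.

    ``times``/``values`` are flat arrays; subject ``s`` owns the slice
    ``indptr[s]:indptr[s+1]`` and its weight equals ``values[k]`` on
    ``(times[k-1], times[k]]`` (with an implicit left edge at the subject's
    follow-up start).  Beyond the last change point the weight is zero
    (violators after ``S``, and everyone after follow-up).
    """

    ids: np.ndarray
    indptr: np.ndarray
    times: np.ndarray
    values: np.ndarray
    arm: object  # 0, 1 or "combined"
    provenance: tuple = ()
    truncation: float | None = None

    @property
    def n_subjects(self) -> int:
        return self.ids.shape[0]

    def evaluate(self, subj, t) -> np.ndarray:
        """Weight value at times ``t`` for subject codes ``subj``."""
        subj = np.atleast_1d(np.asarray(subj))
        t = np.atleast_1d(np.asarray(t, float))
        tmax = float(self.times.max()) + 1.0 if self.times.size else 1.0
        # composite key: piecewise-constant value on (times[k-1], times[k]]
        key_pts = np.repeat(np.arange(self.n_subjects), np.diff(self.indptr)) + (
            self.times / tmax
        )
        key_q = subj + np.minimum(t, tmax - 1.0) / tmax
        k = np.searchsorted(key_pts, key_q, side="left")
        out = np.zeros(t.shape)
        valid = (k < self.indptr[np.minimum(subj + 1, self.n_subjects)]) & (
            k >= self.indptr[subj]
        )
        out[valid] = self.values[k[valid]]
        return out

    def per_subject(self, subj):
        """(times, values) arrays for one subject code."""
        s = slice(self.indptr[subj], self.indptr[subj + 1])
        return self.times[s], self.values[s]


def _row_weights(bundle: NuisanceBundle, tbl: CountingProcessTable,
                 stabilize_treatment: bool):
    """Own-arm IPRC weight evaluated at the stop of each row of ``tbl``.

    ``tbl`` is the artificially censored analysis table, already split at
    the failure event times.
    """
    subj = tbl.subj
    t = tbl.stop

    # C1 -- treatment component, per subject, constant in time
    pi_own = bundle.propensity.pi_A(tbl)
    if np.any(pi_own <= 0):
        raise PositivityError("propensity of received arm is zero")
    c1 = 1.0 / pi_own
    if stabilize_treatment:
        p1 = bundle.propensity.p_treat_marginal
        A_subj = tbl.treat[tbl.indptr()[:-1]]
        c1 = np.where(A_subj == 1, p1, 1.0 - p1) * c1
    c1_rows = c1[subj]

    # C2 -- artificial-censoring component (1(S>=t) is one inside the table)
    lam_den = coxtv.cumhaz_at(bundle.viol_denom, bundle.viol_tbl, subj, t, left=True)
    lam_num = coxtv.cumhaz_at(bundle.viol_numer, bundle.viol_base_tbl, subj, t, left=True)
    c2 = np.exp(lam_den - lam_num)

    # C3 -- discontinuation component, branch by status at t
    c3 = np.empty(tbl.n_rows)
    notyet = tbl.zv == 0
    if np.any(notyet):
        s_n, t_n = subj[notyet], t[notyet]
        ld = coxtv.cumhaz_at(bundle.disc_denom, bundle.disc_tbl, s_n, t_n, left=True)
        ln = coxtv.cumhaz_at(bundle.disc_numer, bundle.disc_base_tbl, s_n, t_n, left=True)
        c3[notyet] = np.exp(ld - ln)
    disc_rows = ~notyet
    if np.any(disc_rows):
        # V_i = first start with Zv = 1 (the observed discontinuation time)
        n = tbl.n_subjects
        V = np.full(n, np.inf)
        np.minimum.at(V, subj[disc_rows], tbl.start[disc_rows])
        dsub = np.unique(subj[disc_rows])
        Vd = V[dsub]
        num_inc = coxtv.hazard_increment_at(
            bundle.disc_numer, bundle.disc_base_tbl, dsub, Vd
        )
        den_inc = coxtv.hazard_increment_at(
            bundle.disc_denom, bundle.disc_tbl, dsub, Vd
        )
        ln_v = coxtv.cumhaz_at(bundle.disc_numer, bundle.disc_base_tbl, dsub, Vd, left=True)
        ld_v = coxtv.cumhaz_at(bundle.disc_denom, bundle.disc_tbl, dsub, Vd, left=True)
        if np.any(den_inc <= 0):
            bad = dsub[np.flatnonzero(den_inc <= 0)[0]]
            raise PositivityError(
                f"zero discontinuation-hazard increment for subject "
                f"{tbl.ids[bad]!r}"
            )
        ratio = np.zeros(n)
        ratio[dsub] = (num_inc * np.exp(-ln_v)) / (den_inc * np.exp(-ld_v))
        c3[disc_rows] = ratio[subj[disc_rows]]

    w = c1_rows * c2 * c3
    if not np.all(np.isfinite(w)):
        bad = np.flatnonzero(~np.isfinite(w))[0]
        raise PositivityError(
            f"IPRC weight not finite for subject {tbl.ids[subj[bad]]!r} "
            f"at t={t[bad]:.4g}"
        )
    return w


def assemble_iprc(
    bundle: NuisanceBundle,
    tbl: CountingProcessTable,
    a: int,
    stabilize_treatment: bool = False,
) -> WeightSeries:
    """IPRC weight series targeting treatment arm ``a``.

    ``tbl`` must be the artificially censored analysis table the bundle was
    fitted from, split at the failure event times (the weight-change grid).
    Subjects with ``A_i != a`` get an identically-zero series.
    """
    cache = getattr(bundle, "_w_own_cache", None)
    key = (id(tbl), bool(stabilize_treatment))
    if cache is not None and cache[0] == key:
        w_own = cache[1]
    else:
        w_own = _row_weights(bundle, tbl, stabilize_treatment)
        bundle._w_own_cache = (key, w_own)
    own = tbl.treat[tbl.subj] == a
    values = np.where(own, w_own, 0.0)
    return WeightSeries(
        ids=tbl.ids,
        indptr=tbl.indptr(),
        times=tbl.stop.copy(),
        values=values,
        arm=a,
        provenance=(id(bundle),),
    )


def combine_by_arm(
    w0: WeightSeries, w1: WeightSeries, tbl: CountingProcessTable
) -> WeightSeries:
    """Per subject, the series for the arm actually received:
    ``omega_{A_i}(t) = A_i omega_1i(t) + (1 - A_i) omega_0i(t)``."""
    if w0.n_subjects != tbl.n_subjects or w1.n_subjects != tbl.n_subjects:
        raise ValueError("weight series and table cover different subjects")
    if not (np.array_equal(w0.times, w1.times) and np.array_equal(w0.indptr, w1.indptr)):
        raise ValueError("weight series were built on different grids")
    if w0.provenance != w1.provenance:
        raise ValueError("weight series come from different nuisance bundles")
    A_rows = tbl.treat[tbl.subj]
    values = np.where(A_rows == 1, w1.values, w0.values)
    return dataclasses.replace(w1, values=values, arm="combined")


def truncate(w: WeightSeries, cap: float) -> WeightSeries:
    """Cap weights at ``cap`` (weight-instability safeguard).

    Returns a new series with ``min(value, cap)``; the number of affected
    subject-intervals is recorded on the result as ``n_truncated``.
    """
    if cap <= 0:
        raise ValueError("cap must be > 0")
    affected = int((w.values > cap).sum())
    out = dataclasses.replace(w, values=np.minimum(w.values, cap), truncation=cap)
    out.n_truncated = affected
    return out


def attach_weights(tbl: CountingProcessTable, w: WeightSeries) -> CountingProcessTable:
    """Fill the weight column of ``tbl`` from a weight series.

    If the series' change points are interval boundaries of ``tbl`` (the
    normal pipeline case) this is a per-row assignment; otherwise the table
    is first split at the change points so the weight is constant on every
    row.  At-risk time is conserved.
    """
    if w.n_subjects != tbl.n_subjects:
        raise ValueError("series and table cover different numbers of subjects")
    # fast path: the series was built on this exact row grid
    if w.times.shape == tbl.stop.shape and np.array_equal(w.times, tbl.stop):
        return tbl.with_weight(w.values)
    need_split = []
    ptr = tbl.indptr()
    for s in range(tbl.n_subjects):
        ts, _ = w.per_subject(s)
        row_bounds = np.concatenate(
            (tbl.start[ptr[s] : ptr[s + 1]], tbl.stop[ptr[s + 1] - 1 : ptr[s + 1]])
        )
        inner = ts[(ts > row_bounds[0]) & (ts < row_bounds[-1])]
        if np.setdiff1d(inner, row_bounds).size:
            need_split.extend(inner.tolist())
    out = tbl
    if need_split:
        from .survdata import split_at

        out = split_at(tbl, np.unique(need_split))
    vals = w.evaluate(out.subj, out.stop)
    return out.with_weight(vals)


def weight_diagnostics(w: WeightSeries) -> dict:
    """Summary of the weight distribution over subject-time intervals.

    Statistics are over the stored change-grid values (which, in the fitting
    pipeline, sit at the failure event times) restricted to the subjects the
    series covers with nonzero support when the series is arm-specific.
    """
    v = w.values
    if w.arm != "combined":
        v = v[v > 0] if np.any(v > 0) else v
    qs = np.quantile(v, [0.01, 0.25, 0.5, 0.75, 0.99]) if v.size else [np.nan] * 5
    return {
        "n": int(v.size),
        "mean": float(np.mean(v)) if v.size else np.nan,
        "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        "min": float(v.min()) if v.size else np.nan,
        "max": float(v.max()) if v.size else np.nan,
        "q01": float(qs[0]),
        "q25": float(qs[1]),
        "median": float(qs[2]),
        "q75": float(qs[3]),
        "q99": float(qs[4]),
        "truncation": w.truncation,
    }
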