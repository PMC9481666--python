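"""Nuisance models for the IPRC weights, fitted in the required order.

The weights need four hazard/probability models besides the propensity
score:

1. the time-dependent Cox model for the hazard of *regime violation* given
   the full history (the denominator of the artificial-censoring component),
2. its stabilizing numerator, a Cox model for violation given baseline
   covariates and treatment only (``theta_bar_R(t) = pr(R >= t | X, A)``),
3. the time-dependent Cox model for the hazard of *treatment
   discontinuation* given the full history, fitted with the
   regime-compliance weights ``omega_D`` built from models 1-2 (so the
   violation models must be fitted first -- the workflow order is enforced),
4. its stabilizing numerator, an unweighted Cox model for discontinuation
   given baseline covariates and treatment.

The discontinuation numerator hazard is represented through its Breslow
increments; the weights only ever use ratios of numerator to denominator
increments at observed discontinuation times, where the baseline jump
masses cancel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from . import coxtv
from .survdata import CountingProcessTable, split_at

__all__ = [
    "PropensityFit",
    "NuisanceBundle",
    "OmegaD",
    "fit_propensity",
    "fit_violation_models",
    "compute_omega_D",
    "fit_discontinuation_models",
    "violation_table",
    "discontinuation_table",
    "collapse_to_baseline",
    "fit_nuisance",
]


class PositivityError(RuntimeError):
    """A weight denominator hit zero (or the propensity left (0, 1))."""


@dataclass
class PropensityFit:
    """Logistic model for pr(A = 1 | X)."""

    covariates: list
    coef: np.ndarray
    p_treat_marginal: float

    def pi(self, tbl: CountingProcessTable) -> np.ndarray:
        """pr(A=1 | X) per subject, from first-interval covariate values."""
        Xb = _baseline_design(tbl, self.covariates)
        lp = self.coef[0] + Xb @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-lp))

    def pi_A(self, tbl: CountingProcessTable) -> np.ndarray:
        """Probability of the treatment arm actually received, per subject."""
        p1 = self.pi(tbl)
        A = _subject_treat(tbl)
        return np.where(A == 1, p1, 1.0 - p1)


@dataclass
class OmegaD:
    """Regime-compliance weights for the discontinuation-hazard fit.

    ``1(S >= t) * K_R(t | X, A) / K_R(t | history, Zv)`` evaluated
    left-continuously at the stop of every row of ``tbl`` (the
    discontinuation-outcome table split at its own event times).  Carries
    the identity of the violation fits that produced it so the workflow
    order (violation models before the weighted discontinuation model) is
    auditable.
    """

    values: np.ndarray
    tbl: CountingProcessTable
    provenance: tuple


@dataclass
class NuisanceBundle:
    """All fitted nuisance models plus the tables that define each
    subject's covariate path (needed to evaluate survival predictions)."""

    propensity: PropensityFit
    viol_denom: coxtv.CoxFit
    viol_numer: coxtv.CoxFit
    viol_tbl: CountingProcessTable
    viol_base_tbl: CountingProcessTable
    disc_denom: coxtv.CoxFit
    disc_numer: coxtv.CoxFit
    disc_tbl: CountingProcessTable  # split, with omega_D weights attached
    disc_base_tbl: CountingProcessTable
    omega_D: OmegaD

    def coefficient_report(self):
        """Coefficient/SE table for all Cox nuisance fits (diagnostics)."""
        import pandas as pd

        rows = []
        for name, fit in (
            ("violation_denominator", self.viol_denom),
            ("violation_numerator", self.viol_numer),
            ("discontinuation_denominator", self.disc_denom),
            ("discontinuation_numerator", self.disc_numer),
        ):
            for c, b, se in zip(fit.covariates, fit.coef, fit.se_robust):
                rows.append(
                    {"model": name, "term": c, "coef": b, "hr": np.exp(b),
                     "robust_se": se}
                )
        return pd.DataFrame(rows)


def _subject_treat(tbl: CountingProcessTable) -> np.ndarray:
    return tbl.treat[tbl.indptr()[:-1]]


def _baseline_design(tbl: CountingProcessTable, covariates) -> np.ndarray:
    """First-interval values of the named columns, one row per subject."""
    first = tbl.indptr()[:-1]
    if not covariates:
        return np.empty((first.size, 0))
    return np.column_stack(
        [np.asarray(tbl.column(c), float)[first] for c in covariates]
    )


def fit_propensity(tbl: CountingProcessTable, covariate_spec) -> PropensityFit:
    """Maximum-likelihood logistic regression of A on baseline covariates."""
    A = _subject_treat(tbl).astype(float)
    if A.min() == A.max():
        raise ValueError("both treatment arms must be present")
    Xb = _baseline_design(tbl, covariate_spec)
    exog = sm.add_constant(Xb, has_constant="add")
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        warnings.simplefilter("error", category=PerfectSeparationWarning)
        try:
            res = sm.GLM(A, exog, family=sm.families.Binomial()).fit()
        except Exception as exc:
            raise ValueError(
                f"propensity fit failed (possible perfect separation) for "
                f"columns {list(covariate_spec)}: {exc}"
            ) from exc
    fitted = res.fittedvalues
    if np.any(fitted <= 1e-10) or np.any(fitted >= 1 - 1e-10):
        raise ValueError(
            f"perfect separation in propensity model, columns {list(covariate_spec)}"
        )
    return PropensityFit(
        covariates=list(covariate_spec),
        coef=np.asarray(res.params),
        p_treat_marginal=float(A.mean()),
    )


def collapse_to_baseline(tbl: CountingProcessTable, event=None) -> CountingProcessTable:
    """One interval (0, last stop] per subject with baseline covariate values.

    ``event`` overrides the per-subject event indicator (default: whether the
    subject has an event anywhere in ``tbl``).
    """
    ptr = tbl.indptr()
    first, last = ptr[:-1], ptr[1:] - 1
    n = tbl.n_subjects
    if event is None:
        event = np.bincount(tbl.subj, weights=tbl.event, minlength=n) > 0
    return CountingProcessTable(
        ids=tbl.ids,
        subj=np.arange(n),
        start=np.zeros(n),
        stop=tbl.stop[last],
        event=np.asarray(event, np.int8),
        treat=tbl.treat[first],
        zv=np.zeros(n, np.int8),
        q={k: v[first] for k, v in tbl.q.items()},
        x={k: v[first] for k, v in tbl.x.items()},
    )


def violation_table(tbl_regime: CountingProcessTable, gamma_s) -> CountingProcessTable:
    """Regime-violation outcome table.

    Follow-up runs to ``S = min(R, T, C)`` (exactly the artificially censored
    table's follow-up) with the event indicator replaced by the violation
    indicator ``Gamma_S`` on each subject's last interval.
    """
    gamma_s = np.asarray(gamma_s).astype(np.int8)
    last = tbl_regime.indptr()[1:] - 1
    ev = np.zeros(tbl_regime.n_rows, np.int8)
    ev[last] = gamma_s
    return tbl_regime.with_event(ev)


def discontinuation_table(tbl_regime: CountingProcessTable) -> CountingProcessTable:
    """Discontinuation outcome table: follow-up to ``min(D, T, C, R)``.

    Rows after discontinuation (``Zv = 1``) are dropped; the event fires on
    the last pre-discontinuation interval iff the subject discontinued
    before failure/censoring/violation.
    """
    keep = tbl_regime.zv == 0
    sub = tbl_regime.take(keep)
    n = tbl_regime.n_subjects
    disc = np.bincount(tbl_regime.subj, weights=tbl_regime.zv, minlength=n) > 0
    last = sub.indptr()[1:] - 1
    ev = np.zeros(sub.n_rows, np.int8)
    ev[last] = disc.astype(np.int8)
    return sub.with_event(ev)


def fit_violation_models(
    tbl_viol: CountingProcessTable, denom_spec, numer_spec
):
    """Fit the regime-violation hazard models (denominator and numerator).

    Returns ``(viol_denom, viol_numer, viol_base_tbl)``.  With zero
    violation events both survival predictions are identically one (the
    artificial-censoring weight component degenerates to ``1(S >= t)``) and
    a warning is emitted.
    """
    base = collapse_to_baseline(tbl_viol)
    if int(tbl_viol.event.sum()) == 0:
        warnings.warn("no regime violations observed; K_R == 1", UserWarning)
        return coxtv.null_fit(denom_spec), coxtv.null_fit(numer_spec), base
    denom = coxtv.fit_cox(tbl_viol, denom_spec, compute_robust=False)
    numer = coxtv.fit_cox(base, numer_spec, compute_robust=False)
    return denom, numer, base


def compute_omega_D(
    viol_denom: coxtv.CoxFit,
    viol_numer: coxtv.CoxFit,
    viol_tbl: CountingProcessTable,
    viol_base_tbl: CountingProcessTable,
    disc_tbl: CountingProcessTable,
) -> OmegaD:
    """Per-row regime-compliance weights for the discontinuation fit.

    The discontinuation table is split at its own event times so the
    weighted partial likelihood reads the correct left-continuous weight on
    every risk set; values are ``K_R(t- | X, A) / K_R(t- | history, Zv)``
    (the ``1(S >= t)`` factor is identically one inside this table, whose
    follow-up never extends past ``S``).
    """
    ev_times = np.unique(disc_tbl.stop[disc_tbl.event.astype(bool)])
    tbl2 = split_at(disc_tbl, ev_times)
    t = tbl2.stop
    lam_den = coxtv.cumhaz_at(viol_denom, viol_tbl, tbl2.subj, t, left=True)
    lam_num = coxtv.cumhaz_at(viol_numer, viol_base_tbl, tbl2.subj, t, left=True)
    vals = np.exp(lam_den - lam_num)
    if not np.all(np.isfinite(vals)):
        bad = np.flatnonzero(~np.isfinite(vals))[0]
        raise PositivityError(
            f"omega_D not finite for subject {tbl2.ids[tbl2.subj[bad]]!r} "
            f"at t={t[bad]:.4g}"
        )
    return OmegaD(values=vals, tbl=tbl2.with_weight(vals),
                  provenance=(id(viol_denom), id(viol_numer)))


def fit_discontinuation_models(
    disc_tbl: CountingProcessTable, omega_D: OmegaD, denom_spec, numer_spec
):
    """Fit the discontinuation hazard models.

    The denominator is the ``omega_D``-weighted time-dependent Cox fit; the
    numerator is an unweighted Cox fit on baseline covariates and treatment.
    ``omega_D`` must be the object produced by :func:`compute_omega_D`
    (weights carrying the violation-model provenance); a bare array is
    refused, enforcing the workflow order.
    """
    if not isinstance(omega_D, OmegaD):
        raise TypeError(
            "fit_discontinuation_models requires omega_D from compute_omega_D "
            "(the violation models must be fitted first)"
        )
    base = collapse_to_baseline(disc_tbl)
    if int(disc_tbl.event.sum()) == 0:
        warnings.warn("no discontinuations observed; K_D == 1", UserWarning)
        return coxtv.null_fit(denom_spec), coxtv.null_fit(numer_spec), base
    denom = coxtv.fit_cox(
        omega_D.tbl, denom_spec, use_weights=True, compute_robust=False
    )
    numer = coxtv.fit_cox(base, numer_spec, compute_robust=False)
    return denom, numer, base


def fit_nuisance(
    tbl_regime: CountingProcessTable,
    gamma_s,
    *,
    propensity_spec=("xq0",),
    viol_denom_spec=("treat", "one_minus_zv"),
    viol_numer_spec=("treat",),
    disc_denom_spec=("treat", "q"),
    disc_numer_spec=("treat",),
) -> NuisanceBundle:
    """Run the full nuisance workflow in the required order.

    ``tbl_regime`` is the artificially censored analysis table (follow-up to
    ``min(T, C, R)``); ``gamma_s`` flags, per subject, whether follow-up
    ended by regime violation.  Numerator ("stabilizing") models condition
    on treatment only by default, configurable to include baseline
    covariates.
    """
    prop = fit_propensity(tbl_regime, list(propensity_spec))
    viol_tbl = violation_table(tbl_regime, gamma_s)
    viol_denom, viol_numer, viol_base = fit_violation_models(
        viol_tbl, list(viol_denom_spec), list(viol_numer_spec)
    )
    disc_tbl = discontinuation_table(tbl_regime)
    omega = compute_omega_D(viol_denom, viol_numer, viol_tbl, viol_base, disc_tbl)
    disc_denom, disc_numer, disc_base = fit_discontinuation_models(
        disc_tbl, omega, list(disc_denom_spec), list(disc_numer_spec)
    )
    return NuisanceBundle(
        propensity=prop,
        viol_denom=viol_denom,
        viol_numer=viol_numer,
        viol_tbl=viol_tbl,
        viol_base_tbl=viol_base,
        disc_denom=disc_denom,
        disc_numer=disc_numer,
        disc_tbl=omega.tbl,
        disc_base_tbl=disc_base,
        omega_D=omega,
    )
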