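"""Treatment-specific marginal structural Cox models.

Fits, on the artificially censored and IPRC-weighted counting-process
table, the marginal structural hazard model

    lambda_{a nu}(t) = lambda_00(t) exp(b1* a + b2* d(t) + b3* a d(t)),

where ``d(t)`` is either the discontinuation indicator ``z_nu(t)`` or the
on-treatment indicator ``1 - z_nu(t)`` (both codings are supported; they
are reparameterizations of the same model).  ``beta_a = b2* + b3* a`` is
the log relative hazard of failure under "discontinue at nu" versus "never
discontinue" for arm ``a``.  The time-varying-effect variant adds
``bTD* (t - nu) z_nu(t)``, so the effect of discontinuation depends on how
long ago treatment was discontinued.

Inference defaults to Wald intervals on the clustered robust (sandwich)
standard errors; the nonparametric bootstrap over subjects is available as
an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import coxtv
from .survdata import CountingProcessTable, split_at

__all__ = ["MSMResult", "fit_msm", "wald_test_interaction", "bootstrap_ci",
           "resample_subjects"]

_Z95 = 1.959963984540054

_PARAM_NAMES = {
    "interaction": ("beta1", "beta2", "beta3"),
    "constant": ("beta1", "beta2"),
    "time_varying": ("beta1", "beta2", "beta3", "betaTD"),
}


@dataclass
class MSMResult:
    """Coefficients and inference for a fitted marginal structural model."""

    model: str
    disc_coding: str
    params: tuple
    coef: np.ndarray
    robust_se: np.ndarray
    fit: coxtv.CoxFit

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def wald_z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coef / self.robust_se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.wald_z))

    @property
    def ci(self) -> np.ndarray:
        lo = self.coef - _Z95 * self.robust_se
        hi = self.coef + _Z95 * self.robust_se
        return np.column_stack([lo, hi])

    def beta_a(self, a: int):
        """Discontinuation effect ``b2* + b3* a`` with delta-method SE."""
        i2 = self.params.index("beta2")
        if "beta3" not in self.params:
            return self.coef[i2], self.robust_se[i2]
        i3 = self.params.index("beta3")
        V = self.fit.cov_robust
        est = self.coef[i2] + a * self.coef[i3]
        var = V[i2, i2] + a * a * V[i3, i3] + 2 * a * V[i2, i3]
        return float(est), float(np.sqrt(var))

    def bonferroni(self, n_endpoints: int) -> np.ndarray:
        """Reporting utility: p-values multiplied by the endpoint count."""
        return np.minimum(1.0, self.p * n_endpoints)

    def coefficient_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "param": list(self.params),
                "coef": self.coef,
                "exp_coef": self.hr,
                "robust_se": self.robust_se,
                "p": self.p,
                "ci_low": self.ci[:, 0],
                "ci_high": self.ci[:, 1],
            }
        )


def _result(fit: coxtv.CoxFit, model: str, disc_coding: str) -> MSMResult:
    return MSMResult(
        model=model,
        disc_coding=disc_coding,
        params=_PARAM_NAMES[model],
        coef=fit.coef.copy(),
        robust_se=fit.se_robust,
        fit=fit,
    )


def fit_msm(
    tbl_weighted: CountingProcessTable,
    model: str = "interaction",
    disc_coding: str = "zv",
    use_weights: bool = True,
) -> MSMResult:
    """Fit the marginal structural Cox model on a weighted table.

    ``tbl_weighted`` must already be artificially censored at regime
    violation and carry the IPRC weights (unless ``use_weights=False``).
    ``disc_coding`` selects ``d(t) = Zv(t)`` (``"zv"``) or ``1 - Zv(t)``
    (``"one_minus_zv"``).  The time-varying model requires the ``zv``
    coding (its extra term ``(t - nu) z_nu(t)`` is defined with the
    discontinuation indicator) and evaluates ``t - nu`` at interval starts
    after splitting at all event times, keeping the covariate
    left-continuous and predictable.
    """
    if model not in _PARAM_NAMES:
        raise ValueError(f"unknown model {model!r}")
    if disc_coding not in ("zv", "one_minus_zv"):
        raise ValueError(f"unknown disc_coding {disc_coding!r}")
    if model == "time_varying" and disc_coding != "zv":
        raise ValueError("the time-varying model is defined with the zv coding")

    d = disc_coding
    tbl = tbl_weighted
    if model == "interaction":
        cols = ["treat", d, f"treat:{d}"]
    elif model == "constant":
        cols = ["treat", d]
    else:  # time_varying
        ev_times = np.unique(tbl.stop[tbl.event.astype(bool)])
        tbl = split_at(tbl, ev_times)
        disc_rows = tbl.zv == 1
        V = np.full(tbl.n_subjects, np.inf)
        np.minimum.at(V, tbl.subj[disc_rows], tbl.start[disc_rows])
        tsince = np.where(disc_rows, tbl.start - V[tbl.subj], 0.0)
        tbl = tbl.with_columns(tsince_disc=tsince)
        cols = ["treat", "zv", "treat:zv", "tsince_disc"]
    fit = coxtv.fit_cox(tbl, cols, use_weights=use_weights)
    return _result(fit, model, disc_coding)


def wald_test_interaction(res: MSMResult):
    """Two-sided Wald test of no treatment-by-discontinuation interaction
    (``b3* = 0``), using the robust SE."""
    if "beta3" not in res.params:
        raise ValueError("interaction test requires the interaction model")
    i3 = res.params.index("beta3")
    z = float(res.coef[i3] / res.robust_se[i3]) if res.robust_se[i3] > 0 else 0.0
    if res.coef[i3] == 0.0:
        z = 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


def resample_subjects(tbl: CountingProcessTable, rng, subject_arrays=None):
    """Draw subjects with replacement; re-key resampled copies as new ids.

    ``subject_arrays`` is an optional dict of per-subject arrays resampled
    alongside the table (e.g. the violation indicator ``Gamma_S``).
    """
    n = tbl.n_subjects
    pick = rng.integers(0, n, size=n)
    ptr = tbl.indptr()
    counts = ptr[pick + 1] - ptr[pick]
    row_idx = np.concatenate([np.arange(ptr[s], ptr[s + 1]) for s in pick])
    new_subj = np.repeat(np.arange(n), counts)
    out = CountingProcessTable(
        ids=np.arange(n),
        subj=new_subj,
        start=tbl.start[row_idx],
        stop=tbl.stop[row_idx],
        event=tbl.event[row_idx],
        treat=tbl.treat[row_idx],
        zv=tbl.zv[row_idx],
        q={k: v[row_idx] for k, v in tbl.q.items()},
        x={k: v[row_idx] for k, v in tbl.x.items()},
        weight=None if tbl.weight is None else tbl.weight[row_idx],
    )
    if subject_arrays is None:
        return out
    aux = {k: np.asarray(v)[pick] for k, v in subject_arrays.items()}
    return out, aux


def bootstrap_ci(
    pipeline,
    tbl: CountingProcessTable,
    B: int,
    seed: int,
    subject_arrays=None,
    alpha: float = 0.05,
):
    """Nonparametric bootstrap over subjects for a full fitting pipeline.

    ``pipeline(tbl_boot, **aux)`` must return a coefficient vector.
    Replicate-level failures are recorded and skipped.  Returns a dict with
    percentile intervals, bootstrap SDs, the replicate draws, and the
    failure count; reproducible given ``seed``.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    draws, failures = [], 0
    for _ in range(B):
        if subject_arrays is None:
            boot = resample_subjects(tbl, rng)
            aux = {}
        else:
            boot, aux = resample_subjects(tbl, rng, subject_arrays)
        try:
            draws.append(np.asarray(pipeline(boot, **aux), float))
        except Exception:
            failures += 1
    if not draws:
        raise RuntimeError("all bootstrap replicates failed")
    draws = np.vstack(draws)
    lo = np.quantile(draws, alpha / 2, axis=0)
    hi = np.quantile(draws, 1 - alpha / 2, axis=0)
    return {
        "ci_low": lo,
        "ci_high": hi,
        "sd": draws.std(axis=0, ddof=1),
        "draws": draws,
        "n_failed": failures,
    }
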