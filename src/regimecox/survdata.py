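"""Counting-process data model for longitudinal survival data.

Follow-up is represented as half-open intervals ``(start, stop]`` per subject,
with interval-constant covariates (left-continuous step functions), an initial
treatment indicator ``A``, and a time-dependent treatment-discontinuation
indicator ``Zv(t) = 1(V <= t) * Gamma_V`` that is absorbing (once a subject
discontinues, they stay discontinued).  Subjects that become inconsistent with
the treatment regime under study ("regime violation", at time ``R``) can be
artificially censored at ``S = min(R, U)``.

The canonical CSV dialect is comma-separated UTF-8 with a header row and
columns ``id,start,stop,event,treat,zv,q*,x*,weight`` where ``q``-prefixed
columns are time-dependent covariates and ``x``-prefixed columns are baseline
covariates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountingProcessTable",
    "SubjectOutcomes",
    "ValidationError",
    "SchemaError",
    "read_table",
    "write_table",
    "from_subject_times",
    "split_at",
]

_INF = np.inf


class ValidationError(ValueError):
    """A table violates one of the counting-process invariants."""


class SchemaError(ValueError):
    """A required column is missing or unparseable."""


@dataclass
class SubjectOutcomes:
    """Derived per-subject summary of the latent/observed times.

    Attributes
    ----------
    U : float
        End of (unartificially censored) follow-up, ``min(T, C)``.
    Delta : int
        1 if the clinical event was observed (``T <= C``).
    V : float
        ``min(D, U)`` where ``D`` is the discontinuation time.
    GammaV : int
        1 if the subject discontinued before event/censoring (``D <= U``).
    S : float
        ``min(R, U)`` where ``R`` is the regime-violation time.
    GammaS : int
        1 if the regime was violated during follow-up (``R <= U``).
    """

    U: float
    Delta: int
    V: float
    GammaV: int
    S: float
    GammaS: int


@dataclass
class CountingProcessTable:
    """Start-stop interval records for a cohort, numpy-backed.

    Rows are grouped by subject and time-ordered within subject.  ``subj``
    holds integer subject codes (0..n_subjects-1) indexing into ``ids``.
    ``q`` maps time-dependent covariate names to row-aligned arrays; ``x``
    maps baseline covariate names to row-aligned arrays (constant within
    subject).  ``weight`` is optional (case weights for the weighted partial
    likelihood).
    """

    ids: np.ndarray
    subj: np.ndarray
    start: np.ndarray
    stop: np.ndarray
    event: np.ndarray
    treat: np.ndarray
    zv: np.ndarray
    q: dict = field(default_factory=dict)
    x: dict = field(default_factory=dict)
    weight: np.ndarray | None = None

    # -- basic introspection -------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.start.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.ids.shape[0]

    @property
    def q_names(self) -> list:
        return list(self.q)

    @property
    def x_names(self) -> list:
        return list(self.x)

    def indptr(self) -> np.ndarray:
        """Row offsets of each subject (subjects are contiguous, sorted)."""
        return np.searchsorted(self.subj, np.arange(self.n_subjects + 1))

    def column(self, name: str) -> np.ndarray:
        """Resolve a design column by name.

        Recognized names: ``treat``, ``zv``, ``one_minus_zv``, ``start``,
        ``stop``, any q/x covariate, and products ``a:b`` of two columns.
        """
        if ":" in name:
            left, right = name.split(":", 1)
            return self.column(left) * self.column(right)
        if name == "treat":
            return self.treat.astype(float)
        if name == "zv":
            return self.zv.astype(float)
        if name == "one_minus_zv":
            return 1.0 - self.zv
        if name == "start":
            return self.start
        if name == "stop":
            return self.stop
        if name in self.q:
            return self.q[name]
        if name in self.x:
            return self.x[name]
        raise SchemaError(f"unknown column {name!r}")

    def design(self, names) -> np.ndarray:
        """Stack design columns into an (n_rows, p) float matrix."""
        if not names:
            return np.empty((self.n_rows, 0))
        return np.column_stack([np.asarray(self.column(n), float) for n in names])

    def with_columns(self, **cols) -> "CountingProcessTable":
        """Return a copy with extra time-dependent covariate columns."""
        new_q = dict(self.q)
        for name, arr in cols.items():
            arr = np.asarray(arr, float)
            if arr.shape[0] != self.n_rows:
                raise ValueError(f"column {name!r} has wrong length")
            new_q[name] = arr
        return dataclasses.replace(self, q=new_q)

    def with_weight(self, weight) -> "CountingProcessTable":
        w = np.asarray(weight, float)
        if w.shape[0] != self.n_rows:
            raise ValueError("weight has wrong length")
        return dataclasses.replace(self, weight=w)

    def with_event(self, event) -> "CountingProcessTable":
        e = np.asarray(event, np.int8)
        return dataclasses.replace(self, event=e)

    def take(self, idx) -> "CountingProcessTable":
        """Row subset (caller is responsible for keeping invariants)."""
        return CountingProcessTable(
            ids=self.ids,
            subj=self.subj[idx],
            start=self.start[idx],
            stop=self.stop[idx],
            event=self.event[idx],
            treat=self.treat[idx],
            zv=self.zv[idx],
            q={k: v[idx] for k, v in self.q.items()},
            x={k: v[idx] for k, v in self.x.items()},
            weight=None if self.weight is None else self.weight[idx],
        )

    # -- invariants ----------------------------------------------------------

    def validate(self) -> "CountingProcessTable":
        """Check all counting-process invariants, raising ValidationError."""
        if self.n_rows == 0:
            return self
        if np.any(self.stop <= self.start):
            bad = self.ids[self.subj[np.flatnonzero(self.stop <= self.start)[0]]]
            raise ValidationError(f"subject {bad!r}: interval with stop <= start")
        if np.any(self.start < 0):
            bad = self.ids[self.subj[np.flatnonzero(self.start < 0)[0]]]
            raise ValidationError(f"subject {bad!r}: negative start time")
        if np.any(np.diff(self.subj) < 0):
            raise ValidationError("rows are not grouped by subject")
        same = np.flatnonzero(np.diff(self.subj) == 0)
        if same.size:
            if np.any(self.start[same + 1] != self.stop[same]):
                k = same[np.flatnonzero(self.start[same + 1] != self.stop[same])[0]]
                raise ValidationError(
                    f"subject {self.ids[self.subj[k]]!r}: intervals not contiguous"
                )
            if np.any(self.zv[same + 1] < self.zv[same]):
                k = same[np.flatnonzero(self.zv[same + 1] < self.zv[same])[0]]
                raise ValidationError(
                    f"subject {self.ids[self.subj[k]]!r}: Zv decreases in time"
                )
            if np.any(self.treat[same + 1] != self.treat[same]):
                k = same[np.flatnonzero(self.treat[same + 1] != self.treat[same])[0]]
                raise ValidationError(
                    f"subject {self.ids[self.subj[k]]!r}: treatment not constant"
                )
            for name, col in self.x.items():
                if np.any(col[same + 1] != col[same]):
                    k = same[np.flatnonzero(col[same + 1] != col[same])[0]]
                    raise ValidationError(
                        f"subject {self.ids[self.subj[k]]!r}: baseline "
                        f"covariate {name!r} not constant"
                    )
            # event only on the last interval of a subject
            if np.any(self.event[same] != 0):
                k = same[np.flatnonzero(self.event[same] != 0)[0]]
                raise ValidationError(
                    f"subject {self.ids[self.subj[k]]!r}: event before last interval"
                )
        counts = np.bincount(self.subj, weights=self.event, minlength=self.n_subjects)
        if np.any(counts > 1):
            bad = self.ids[np.flatnonzero(counts > 1)[0]]
            raise ValidationError(f"subject {bad!r}: more than one event")
        if self.weight is not None and np.any(self.weight < 0):
            bad = self.ids[self.subj[np.flatnonzero(self.weight < 0)[0]]]
            raise ValidationError(f"subject {bad!r}: negative weight")
        return self

    # -- pandas / CSV bridge -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "id": self.ids[self.subj] if self.n_rows else np.array([]),
            "start": self.start,
            "stop": self.stop,
            "event": self.event,
            "treat": self.treat,
            "zv": self.zv,
        }
        for name, arr in self.q.items():
            cols[name] = arr
        for name, arr in self.x.items():
            cols[name] = arr
        if self.weight is not None:
            cols["weight"] = self.weight
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountingProcessTable":
        required = ["id", "start", "stop", "event", "treat", "zv"]
        for col in required:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        ids, subj = np.unique(np.asarray(df["id"]), return_inverse=True)
        # preserve first-appearance order of subjects
        first = np.zeros(ids.shape[0], dtype=int)
        np.minimum.at(first, subj, np.arange(len(subj)))
        order = np.argsort(first, kind="stable")
        remap = np.empty_like(order)
        remap[order] = np.arange(order.size)
        ids = ids[order]
        subj = remap[subj]
        row_order = np.lexsort((np.asarray(df["start"], float), subj))
        subj = subj[row_order]

        def col(name, dtype=float):
            try:
                return np.asarray(df[name], dtype)[row_order]
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"column {name!r} not numeric: {exc}") from exc

        q = {c: col(c) for c in df.columns if c.startswith("q")}
        x = {c: col(c) for c in df.columns if c.startswith("x")}
        weight = col("weight") if "weight" in df.columns else None
        tbl = cls(
            ids=ids,
            subj=subj,
            start=col("start"),
            stop=col("stop"),
            event=col("event", np.int8),
            treat=col("treat", np.int8),
            zv=col("zv", np.int8),
            q=q,
            x=x,
            weight=weight,
        )
        return tbl.validate()


def read_table(path, schema: dict | None = None) -> CountingProcessTable:
    """Read a counting-process CSV, optionally renaming source columns.

    ``schema`` maps source column names to the canonical names
    (``id,start,stop,event,treat,zv,q*,x*,weight``).
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=schema)
    return CountingProcessTable.from_frame(df)


def write_table(tbl: CountingProcessTable, path) -> None:
    """Write a table as canonical CSV (header always present)."""
    df = tbl.to_frame()
    if tbl.n_rows == 0:
        df = pd.DataFrame(columns=["id", "start", "stop", "event", "treat", "zv"])
    df.to_csv(path, index=False)


def from_subject_times(
    subject_id,
    A: int,
    X: dict | None = None,
    Q_path: dict | None = None,
    D: float | None = None,
    R: float | None = None,
    T: float | None = None,
    C: float | None = None,
    censor_at_violation: bool = False,
):
    """Build one subject's interval rows and outcomes from latent times.

    Parameters
    ----------
    Q_path : dict
        Maps each time-dependent covariate name to ``(breaks, values)`` where
        ``values[k]`` holds on ``(breaks[k-1], breaks[k]]`` (breaks are the
        interior change times; ``len(values) == len(breaks) + 1``).
    censor_at_violation : bool
        If True, follow-up for the emitted table ends at ``min(T, C, R)``
        (artificial censoring at regime violation).

    Returns
    -------
    (CountingProcessTable, SubjectOutcomes)

    Notes
    -----
    Exact ties between latent times have probability zero under continuous
    models; they are broken with priority ``T < C < R < D``.
    """
    t_ = _INF if T is None else float(T)
    c_ = _INF if C is None else float(C)
    d_ = _INF if D is None else float(D)
    r_ = _INF if R is None else float(R)
    if not np.isfinite(min(t_, c_)):
        raise ValueError("at least one of T, C must be given (no follow-up end)")
    for name, val in (("T", t_), ("C", c_), ("D", d_), ("R", r_)):
        if val <= 0:
            raise ValueError(f"{name} must be > 0")

    U = min(t_, c_)
    Delta = int(t_ <= c_)
    V = min(d_, U)
    GammaV = int(d_ <= U)
    S = min(r_, U)
    GammaS = int(r_ <= U)

    end = min(U, r_) if censor_at_violation else U
    obs_event = int(t_ <= min(c_, r_)) if censor_at_violation else Delta

    breaks = set()
    Q_path = Q_path or {}
    for bks, _vals in Q_path.values():
        breaks.update(b for b in bks if 0.0 < b < end)
    if d_ < end:
        breaks.add(d_)
    bounds = [0.0] + sorted(breaks) + [end]

    n_int = len(bounds) - 1
    start = np.array(bounds[:-1])
    stop = np.array(bounds[1:])
    event = np.zeros(n_int, np.int8)
    event[-1] = obs_event
    # Zv turns on strictly after D; starts are < end so this is automatically
    # all-zero when D >= end of follow-up
    zv = (start >= d_).astype(np.int8)

    q_cols = {}
    for name, (bks, vals) in Q_path.items():
        bks = np.asarray(bks, float)
        vals = np.asarray(vals, float)
        piece = np.searchsorted(bks, start, side="right")
        q_cols[name] = vals[piece]
    x_cols = {name: np.full(n_int, float(val)) for name, val in (X or {}).items()}

    tbl = CountingProcessTable(
        ids=np.asarray([subject_id]),
        subj=np.zeros(n_int, int),
        start=start,
        stop=stop,
        event=event,
        treat=np.full(n_int, int(A), np.int8),
        zv=zv,
        q=q_cols,
        x=x_cols,
    ).validate()
    return tbl, SubjectOutcomes(U=U, Delta=Delta, V=V, GammaV=GammaV, S=S, GammaS=GammaS)


def split_at(tbl: CountingProcessTable, times) -> CountingProcessTable:
    """Split every interval at the interior members of ``times``.

    Covariates, ``Zv`` and weights are carried onto the sub-intervals; the
    event stays on the final sub-interval of its original interval.  Times
    outside a subject's follow-up are ignored.  Total at-risk time per
    subject is conserved, and splitting at already-present boundaries is the
    identity.
    """
    times = np.unique(np.asarray(list(times), float))
    if times.size == 0 or tbl.n_rows == 0:
        return tbl
    lo = np.searchsorted(times, tbl.start, side="right")
    hi = np.searchsorted(times, tbl.stop, side="left")
    n_cuts = hi - lo  # interior split points per row
    if not np.any(n_cuts):
        return tbl
    reps = n_cuts + 1
    row_idx = np.repeat(np.arange(tbl.n_rows), reps)
    # position of each sub-interval within its original row
    offsets = np.concatenate(([0], np.cumsum(reps)))
    pos = np.arange(reps.sum()) - offsets[row_idx]

    new_start = np.where(pos == 0, tbl.start[row_idx], 0.0)
    new_stop = np.where(pos == n_cuts[row_idx], tbl.stop[row_idx], 0.0)
    interior_s = pos > 0
    new_start[interior_s] = times[lo[row_idx[interior_s]] + pos[interior_s] - 1]
    interior_e = pos < n_cuts[row_idx]
    new_stop[interior_e] = times[lo[row_idx[interior_e]] + pos[interior_e]]

    last = pos == n_cuts[row_idx]
    new_event = np.where(last, tbl.event[row_idx], 0).astype(np.int8)

    return CountingProcessTable(
        ids=tbl.ids,
        subj=tbl.subj[row_idx],
        start=new_start,
        stop=new_stop,
        event=new_event,
        treat=tbl.treat[row_idx],
        zv=tbl.zv[row_idx],
        q={k: v[row_idx] for k, v in tbl.q.items()},
        x={k: v[row_idx] for k, v in tbl.x.items()},
        weight=None if tbl.weight is None else tbl.weight[row_idx],
    )
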