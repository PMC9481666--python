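import numpy as np
import pytest

from regimecox.simulate import DGPConfig, draw_cohort
from regimecox.survdata import CountingProcessTable


def make_table(rows, q_names=(), x_names=(), weight=None):
    """Build a CountingProcessTable from (id, start, stop, event, treat, zv,
    *covs) tuples, covs ordered as q_names then x_names."""
    rows = list(rows)
    ids_seq = [r[0] for r in rows]
    ids = list(dict.fromkeys(ids_seq))
    code = {i: k for k, i in enumerate(ids)}
    arr = lambda j, dt=float: np.array([r[j] for r in rows], dtype=dt)
    nq = len(q_names)
    q = {nm: arr(6 + j) for j, nm in enumerate(q_names)}
    x = {nm: arr(6 + nq + j) for j, nm in enumerate(x_names)}
    return CountingProcessTable(
        ids=np.array(ids),
        subj=np.array([code[i] for i in ids_seq]),
        start=arr(1),
        stop=arr(2),
        event=arr(3, np.int8),
        treat=arr(4, np.int8),
        zv=arr(5, np.int8),
        q=q,
        x=x,
        weight=None if weight is None else np.asarray(weight, float),
    ).validate()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared across tests."""
    return draw_cohort(DGPConfig(n=400, seed=42, beta=(0.2, 0.3, -0.1)))


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort at the null effect setting."""
    return draw_cohort(DGPConfig(n=500, seed=9, beta=(0.0, 0.0, 0.0)))
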