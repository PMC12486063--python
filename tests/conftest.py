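import numpy as np
import pytest
from scipy import sparse

from letopt import RunConfig, build_case
from letopt.constraints import StackedConstraints
from letopt.influence import InfluenceMatrix


@pytest.fixture(scope="session")
def default_case():
    """The standard synthetic case: 20^3 phantom, opposed fields, 120 spots."""
    return build_case(RunConfig())


def make_planted(seed, n_vox=50, n_beam=10, margin_frac=0.05):
    """Interval system with a planted strictly feasible point.

    Returns ``(stacked, x_star, x0)``: the intervals are centred on
    ``A @ x_star`` with a margin, so ``x_star`` is feasible by
    construction; references equal the planted row values, so the
    objective is zero exactly at a point reproducing them.
    """
    rng = np.random.default_rng(seed)
    dense = rng.uniform(0, 1, (n_vox, n_beam)) * (rng.uniform(size=(n_vox, n_beam)) < 0.4)
    empty = dense.sum(axis=1) == 0
    dense[empty, rng.integers(0, n_beam, size=empty.sum())] = rng.uniform(0.5, 1.0)
    a = sparse.csr_matrix(dense)
    x_star = rng.uniform(0.5, 1.5, n_beam)
    t = a @ x_star
    m = margin_frac * t.mean()
    sc = StackedConstraints(
        A=a,
        lower=t - m,
        upper=t + m,
        weight=np.ones(n_vox),
        reference=t.copy(),
        space=np.full(n_vox, "dose", dtype=object),
        voxel=np.arange(n_vox),
        structure=np.full(n_vox, "TOY", dtype=object),
        row_norm_sq=np.asarray(a.multiply(a).sum(axis=1)).ravel(),
    )
    x0 = rng.uniform(0, 2, n_beam)
    return sc, x_star, x0


@pytest.fixture
def planted():
    return make_planted


def toy_influence(dose_dense, letd_per_entry=None, grid=None):
    """Dense dose matrix (+ per-entry LET factors) -> InfluenceMatrix."""
    d = np.asarray(dose_dense, dtype=float)
    n = d * (1.0 if letd_per_entry is None else np.asarray(letd_per_entry, dtype=float))
    return InfluenceMatrix(dose=sparse.csr_matrix(d), letd_numerator=sparse.csr_matrix(n), grid=grid)
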