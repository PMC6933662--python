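import numpy as np
import pytest

from deepmf import OmicsMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, mask=None, prefix=("f", "s")):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isfinite(values)
    m, n = values.shape
    return OmicsMatrix(
        values,
        np.asarray(mask, dtype=bool),
        [f"{prefix[0]}{i}" for i in range(m)],
        [f"{prefix[1]}{j}" for j in range(n)],
    )


@pytest.fixture
def small_sparse(rng):
    vals = rng.normal(size=(6, 4))
    mask = rng.random((6, 4)) > 0.25
    vals = np.where(mask, vals, np.nan)
    return make_matrix(vals, mask)
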