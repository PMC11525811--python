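import numpy as np
import pytest

from raybnn.geometry import CellPopulation, GeometryConfig, populate_sphere
from raybnn.network import (
    RayBNNModel,
    SparseWeights,
    UAFParams,
    identity_uaf_params,
    init_uaf_params,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_population():
    """~120-cell population with inputs on the surface and outputs at the
    origin, suitable for exhaustive oracle checks."""
    cfg = GeometryConfig(n_hidden=50, n_glial=50, n_input=6, n_output=2,
                         input_layout="helix", seed=7)
    pop, _ = populate_sphere(cfg)
    return pop


def make_random_model(seed, n=10, n_input=3, n_output=2, k=2, density=0.4,
                      uaf_jitter=0.3):
    """Small dense-ish random model honoring the structural-zero layout."""
    rng = np.random.default_rng(seed)
    rows, cols = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    mask = (
        (rng.random((n, n)) < density)
        & (rows >= n_input)
        & (cols < n - n_output)
        & (rows != cols)
    )
    r, c = np.nonzero(mask)
    weights = SparseWeights(n, r, c, 0.5 * rng.standard_normal(mask.sum()))
    types = np.array(
        ["input"] * n_input + ["hidden"] * (n - n_input - n_output) + ["output"] * n_output,
        dtype=object,
    )
    pop = CellPopulation(positions=rng.standard_normal((n, 3)), cell_type=types, r_s=10.0)
    h = 0.3 * rng.standard_normal(n)
    model = RayBNNModel(
        population=pop,
        weights=weights,
        H=h,
        uaf=UAFParams(init_uaf_params(n, rng, uaf_jitter)),
        n_input=n_input,
        n_output=n_output,
        k=k,
        slot_cell=np.arange(n),
    )
    return model


def make_linear_model(w_dense, n_input, n_output, k=1):
    """Model with an explicit dense weight matrix, zero bias and identity
    activations (the worked-example configuration)."""
    w_dense = np.asarray(w_dense, dtype=float)
    n = w_dense.shape[0]
    r, c = np.nonzero(w_dense)
    weights = SparseWeights(n, r, c, w_dense[r, c])
    types = np.array(
        ["input"] * n_input + ["hidden"] * (n - n_input - n_output) + ["output"] * n_output,
        dtype=object,
    )
    pop = CellPopulation(positions=np.zeros((n, 3)), cell_type=types, r_s=1.0)
    return RayBNNModel(
        population=pop,
        weights=weights,
        H=np.zeros(n),
        uaf=UAFParams(identity_uaf_params(n)),
        n_input=n_input,
        n_output=n_output,
        k=k,
        slot_cell=np.arange(n),
    )
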