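import numpy as np
import pytest

from dynppi.dynamic_networks import NetworkSeries, build_series
from dynppi.io_formats import ExpressionMatrix
from dynppi.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Desk-scale generator settings used by most integration tests."""
    return SyntheticSpec(
        n_proteins=24,
        n_timepoints=8,
        n_replicates=2,
        n_modules=4,
        n_critical=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def small_series(small_dataset) -> NetworkSeries:
    expr, edges, _ = small_dataset
    return build_series(expr, edges)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_expression(values, gene_ids=None) -> ExpressionMatrix:
    """3-D array (genes x T x R) -> ExpressionMatrix with default ids."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[:, :, None]
    ids = gene_ids or [f"G{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(ids, values)
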