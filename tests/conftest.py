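import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from degas.containers import ExpressionMatrix
from degas.synthetic import SimDesign, generate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_matrix():
    values = np.array([[0.0, 1.0, 3.0], [5.0, 5.0, 5.0], [2.0, 0.0, 4.0]])
    return ExpressionMatrix(values, ["s1", "s2", "s3"], ["gA", "gB", "gC"], stage="raw")


@pytest.fixture(scope="session")
def small_design():
    # A miniature scenario: 5 groups x 100 cells, 600-gene panel, 60
    # patients of 150 cells each.  Small enough for fast training while
    # keeping the cell types clearly separable.
    return SimDesign(scenario="sim1", n_genes=600, cells_per_group=100,
                     holdout_for_patients=200, n_patients=60,
                     cells_per_patient=150, seed=7)


@pytest.fixture(scope="session")
def small_data(small_design):
    return generate_dataset(small_design)
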