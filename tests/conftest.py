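import numpy as np
import pytest

from dosepath import synthetic


@pytest.fixture(scope="session")
def design():
    return synthetic.DoseDesign()


@pytest.fixture(scope="session")
def planted_study():
    """Scaled-down planted reciprocal study shared across test modules."""
    return synthetic.generate_reciprocal_study(seed=11, n_genes=2000)


@pytest.fixture(scope="session")
def noise_expr(design):
    """Pure-noise expression matrix (no planted structure)."""
    genes = [f"G{i:04d}" for i in range(1000)]
    truth = synthetic.PlantedTruth(
        frozenset(), frozenset(), frozenset(genes),
        effect_size=1.0, noise_sd=0.5,
    )
    return synthetic.generate_dose_expression(design, truth, seed=99)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
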