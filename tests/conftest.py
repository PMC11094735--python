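import numpy as np
import pytest

from nanofp.synthetic import SyntheticConfig, generate_matrix


@pytest.fixture(scope="session")
def default_synthetic():
    """One default-config synthetic matrix plus its planted labels."""
    return generate_matrix(SyntheticConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """A small random free-energy matrix for structural tests."""
    from nanofp.matrix_io import FreeEnergyMatrix

    values = rng.normal(-10, 5, (6, 5))
    return FreeEnergyMatrix(
        molecule_ids=[f"m{i}" for i in range(6)],
        material_ids=[f"s{j}" for j in range(5)],
        values=values,
    )
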