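import numpy as np
import pytest

from dnctest import synthetic


@pytest.fixture(scope="session")
def grid():
    return synthetic.default_wavelength_grid()


@pytest.fixture(scope="session")
def basis(grid):
    """Two-fluorophore dopamine-sensor / reference basis."""
    return synthetic.make_basis([synthetic.DLIGHT, synthetic.TDTOMATO], grid)


def normal_equations_oracle(S: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent closed-form least-squares solution (S^T S)^-1 S^T y."""
    return np.linalg.solve(S.T @ S, S.T @ y)
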