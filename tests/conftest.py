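import numpy as np
import pytest

import surveygap as sg


@pytest.fixture(scope="session")
def landscape():
    return sg.generate_landscape(20, 20, n_env=4, n_drivers_per_group=2,
                                 smoothness=3.0, seed=1)


@pytest.fixture(scope="session")
def species(landscape):
    return sg.generate_species(landscape, 12, beta_scale=1.5, seed=7)


@pytest.fixture(scope="session")
def env_stack(landscape):
    return sg.EnvStack.from_landscape(landscape)


def morans_i(grid: np.ndarray) -> float:
    """Independent Moran's I oracle with rook contiguity (used by tests only)."""
    z = grid - grid.mean()
    n = grid.size
    num = 0.0
    wsum = 0
    rows, cols = grid.shape
    for r in range(rows):
        for c in range(cols):
            for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    num += z[r, c] * z[rr, cc]
                    wsum += 1
    return (n / wsum) * num / (z * z).sum()
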