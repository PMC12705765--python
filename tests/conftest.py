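import numpy as np
import pytest

import flarequant as fq


@pytest.fixture(scope="session")
def noiseless():
    return fq.NoiseSpec.noiseless()


@pytest.fixture(scope="session")
def single_cell_field(noiseless):
    """One noise-free cell with an invagination and foci, plus its truth."""
    spec = fq.CellSpec(
        center=(60.0, 60.0), radii=(22.0, 20.0), pm_fraction=0.6,
        sorting_factor=3.0, n_invaginations=1, n_foci=2,
    )
    stack, mask, gt = fq.generate_field([spec], noiseless, shape=(128, 128))
    return stack, mask, gt


@pytest.fixture(scope="session")
def five_cell_field(noiseless):
    """Five separated noise-free cells, none touching the border."""
    specs = fq.random_cell_specs(5, shape=(256, 256), seed=7, n_foci=0)
    return fq.generate_field(specs, noiseless)


def disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
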