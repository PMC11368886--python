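import numpy as np
import pytest

from fermspec import (
    CalibrationDataset,
    ConcentrationTable,
    NoiseModel,
    WavelengthGrid,
    generate_pure_spectra,
    synthesize_from_concentrations,
)


@pytest.fixture(scope="session")
def grid2():
    """Full-resolution 2 nm instrument grid (376 points)."""
    return WavelengthGrid.regular(step=2.0)


@pytest.fixture(scope="session")
def grid4():
    """Coarser 4 nm grid used to keep simulation-heavy tests fast."""
    return WavelengthGrid.regular(step=4.0)


@pytest.fixture(scope="session")
def grid8():
    return WavelengthGrid.regular(step=8.0)


def make_mixture_dataset(
    grid,
    components=("a", "b", "c"),
    n=60,
    noise=None,
    seed=0,
    conc_range=(1.0, 100.0),
    solids=None,
):
    """Random uniform concentration design pushed through the forward model."""
    components = list(components)
    pure = generate_pure_spectra(components, grid, seed=1000 + seed)
    rng = np.random.default_rng(seed)
    conc = ConcentrationTable(
        components,
        rng.uniform(conc_range[0], conc_range[1], size=(n, len(components))),
        [f"s{i:04d}" for i in range(n)],
    )
    dataset = synthesize_from_concentrations(
        conc, pure, noise or NoiseModel.silent(), grid, seed=2000 + seed,
        solids=solids,
    )
    return dataset, pure


@pytest.fixture(scope="session")
def mixture_factory():
    return make_mixture_dataset


@pytest.fixture(scope="session")
def mixture3_noise_free(grid4):
    """Noise-free 3-component Beer-Lambert dataset, n=60."""
    return make_mixture_dataset(grid4, n=60, seed=0)
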