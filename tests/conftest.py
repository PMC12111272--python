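import numpy as np
import pytest
from hypothesis import settings

from spectrastack.core_io import SpectraSet, WavelengthGrid
from spectrastack.synth import fixture_small

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_data() -> SpectraSet:
    """Tiny deterministic labelled dataset: 5 classes x 10 samples x 40 channels."""
    return fixture_small()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def random_spectra(rng) -> SpectraSet:
    """Unlabelled random 5 x 10 spectra for round-trip style tests."""
    grid = WavelengthGrid.uniform(10)
    A = rng.normal(0.5, 0.1, size=(5, 10))
    return SpectraSet(A, grid, [f"s{i}" for i in range(5)])


@pytest.fixture()
def labelled_spectra(rng) -> SpectraSet:
    grid = WavelengthGrid.uniform(12)
    A = rng.normal(0.5, 0.1, size=(6, 12))
    return SpectraSet(
        A,
        grid,
        [f"s{i}" for i in range(6)],
        labels=np.array([0, 0, 1, 1, 2, 2]),
        class_names=["ZY", "BY", "DH"],
    )
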