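import numpy as np
import pytest

from procspec.dataset import PairedData, ProcessDataset, ReferenceSet, SpectraBatch
from procspec.simulate import SimParams, simulate_campaign


@pytest.fixture
def tiny_batch() -> SpectraBatch:
    """3 spectra x 4 wavelengths, hand-enumerable."""
    return SpectraBatch(
        batch_id="T1",
        times=np.array([0.0, 5.0, 10.0]),
        wavelengths=np.array([1100.0, 1400.0, 1700.0, 1900.0]),
        intensities=np.arange(12, dtype=float).reshape(3, 4),
    )


@pytest.fixture
def tiny_refs() -> ReferenceSet:
    return ReferenceSet(
        batch_id="T1",
        sample_times=np.array([1.0, 6.0]),
        lod_values=np.array([20.0, 5.0]),
    )


def make_linear_paired(
    n: int = 12, p: int = 6, n_batches: int = 3, noise: float = 0.0, seed: int = 0
) -> PairedData:
    """Paired data whose spectra are an exact (optionally noisy) linear
    function of a single moisture factor — ground truth for PLS tests."""
    rng = np.random.default_rng(seed)
    lod = np.linspace(25.0, 3.0, n)
    direction = rng.normal(size=p)
    base = rng.normal(size=p)
    spectra = base + np.outer(lod, direction)
    if noise:
        spectra = spectra + rng.normal(0.0, noise, size=spectra.shape)
    return PairedData(
        batch_ids=np.array([f"B{i % n_batches}" for i in range(n)], dtype=object),
        sample_times=np.arange(n, dtype=float) * 50,
        spectra=spectra,
        lod=lod,
        wavelengths=np.linspace(1100, 2100, p),
    )


@pytest.fixture
def linear_paired() -> PairedData:
    return make_linear_paired()


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """Reduced-scale batches (150-300 spectra) so simulations stay fast."""
    return SimParams(n_spectra_range=(150, 300))


@pytest.fixture(scope="session")
def small_campaign(small_params) -> ProcessDataset:
    """A 6-batch campaign shared across structural tests."""
    return simulate_campaign(small_params, n_batches=6, validation_batches=2, seed=11)
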