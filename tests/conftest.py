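import numpy as np
import pytest

from strokemsi.dataset import MassAxis, MSIDataset
from strokemsi.phantom import PhantomConfig, generate
from strokemsi.preprocess import integrate, mean_spectrum, pick_peaks, tic_normalize


def phantom_features(config: PhantomConfig):
    """Standard phantom -> normalized feature-matrix chain used across tests."""
    dataset, truth = generate(config)
    normalized = tic_normalize(dataset)
    peaks = pick_peaks(normalized.axis.values, mean_spectrum(normalized))
    return integrate(normalized, peaks), truth


def phantom_bundle(config: PhantomConfig):
    """Like :func:`phantom_features` but keeping both the TIC-normalized and
    the raw integrated matrix (the raw one is the scale on which the phantom's
    ground-truth multipliers are defined)."""
    from types import SimpleNamespace

    dataset, truth = generate(config)
    normalized = tic_normalize(dataset)
    peaks = pick_peaks(normalized.axis.values, mean_spectrum(normalized))
    return SimpleNamespace(norm=integrate(normalized, peaks),
                           raw=integrate(dataset, peaks), truth=truth)


@pytest.fixture(scope="session")
def pos_phantom():
    """Default positive-mode 24 h phantom (seed 0) with ground truth."""
    return generate(PhantomConfig(polarity="positive", time_point=24, seed=0))


@pytest.fixture(scope="session")
def pos_features(pos_phantom):
    dataset, truth = pos_phantom
    normalized = tic_normalize(dataset)
    peaks = pick_peaks(normalized.axis.values, mean_spectrum(normalized))
    return integrate(normalized, peaks), truth


@pytest.fixture(scope="session")
def neg_features():
    """Default negative-mode 24 h phantom feature matrix with ground truth."""
    return phantom_features(PhantomConfig(polarity="negative", time_point=24, seed=0))


@pytest.fixture(scope="session")
def noisefree_pos():
    """Noise-free, unit-TIC positive phantom for closed-form expectations."""
    config = PhantomConfig(polarity="positive", time_point=24, seed=0,
                           poisson_noise=False, gaussian_sigma=0.0, tic_sigma=0.0)
    return generate(config)


@pytest.fixture()
def small_dataset():
    """Tiny continuous-mode dataset for I/O and mask tests."""
    axis = MassAxis(np.array([500.0, 500.1, 500.2, 500.3]))
    coords = np.array([[0, 0], [1, 0], [0, 1], [2, 2]])
    intensities = np.array([
        [1.0, 5.0, 2.0, 0.0],
        [0.5, 4.0, 1.5, 0.2],
        [2.0, 6.0, 3.0, 1.0],
        [0.0, 1.0, 0.5, 0.1],
    ])
    return MSIDataset(coords=coords, axis=axis, intensities=intensities,
                      polarity="positive", pixel_size_um=50.0)
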