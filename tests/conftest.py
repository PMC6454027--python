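import numpy as np
import pytest

import wavemeg as wm


def random_distance_rdm(n_conditions: int, seed: int, dim: int = 4) -> np.ndarray:
    """Pairwise-distance RDM of random Gaussian points (symmetric, zero diag)."""
    pts = np.random.default_rng(seed).standard_normal((n_conditions, dim))
    return np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))


@pytest.fixture(scope="session")
def geometry_rdm() -> np.ndarray:
    return random_distance_rdm(8, seed=0)


@pytest.fixture(scope="session")
def signal_epochs(geometry_rdm) -> tuple[wm.EpochSet, wm.GroundTruth]:
    """Epochs carrying one known geometry peaking at 120 ms (moderate noise)."""
    truth = wm.GroundTruth(model_rdm=geometry_rdm, signal_peak_ms=120.0,
                           signal_width_ms=60.0, noise_sd=0.7, seed=3)
    epochs = wm.generate_epochs(truth, n_subjects=4, n_conditions=8, n_trials=12,
                                n_channels=24, window_ms=(-100.0, 300.0), step_ms=10.0)
    return epochs, truth


@pytest.fixture(scope="session")
def decoded_series(signal_epochs) -> tuple[wm.RDMSeries, wm.GroundTruth]:
    """Decoding RDM series of the preprocessed signal fixture."""
    epochs, truth = signal_epochs
    clean = wm.preprocess_pipeline(epochs, remove_blinks=False)
    series = wm.decoding_rdm_series(clean, K=4, group_size=3, n_reps=5, seed=7)
    return series, truth
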