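import numpy as np
import pytest

from hoinet.cohort import CohortConfig, generate_epochs, participant_table
from hoinet.preprocessing import (
    BandTrial,
    DEFAULT_BANDS,
    bandpass_trial,
    representative_trial,
)

DELTA, THETA, ALPHA, BETA, GAMMA = DEFAULT_BANDS


def gaussian_sample(R: np.ndarray, T: int, rng: np.random.Generator) -> np.ndarray:
    """Exact multivariate Gaussian sample (channels x time) with correlation R."""
    L = np.linalg.cholesky(R)
    return L @ rng.standard_normal((R.shape[0], T))


def raw_band_trials(
    config: CohortConfig, band, session: str
) -> tuple[dict[str, BandTrial], dict[str, str]]:
    """Trial-average + band-filter each participant-session, no re-referencing.

    The generator emits source-like channels, so search-logic tests skip the
    sensor-space average reference to keep planted geometry intact.
    """
    trials, groups = {}, {}
    for participant, group in participant_table(config):
        es = generate_epochs(config, participant, group, session)
        rep = bandpass_trial(representative_trial(es.data), band, config.fs)
        trials[participant] = BandTrial(participant, session, band, rep, config.fs)
        groups[participant] = group
    return trials, groups


def small_config(**kwargs) -> CohortConfig:
    """Reduced-scale cohort used throughout the suite: 8 ch, 32 trials, 2 bands."""
    defaults = dict(n_channels=8, n_trials=32, bands=(DELTA, BETA))
    defaults.update(kwargs)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def equicorr_triplet():
    """Correlation matrix of an equicorrelated (rho = 0.5) triplet."""
    R = np.full((3, 3), 0.5)
    np.fill_diagonal(R, 1.0)
    return R


@pytest.fixture(scope="session")
def collider_triplet():
    """Collider geometry: rho12 = 0, rho13 = rho23 = 1/sqrt(3) (hub last)."""
    r = 1.0 / np.sqrt(3.0)
    R = np.eye(3)
    R[0, 2] = R[2, 0] = r
    R[1, 2] = R[2, 1] = r
    return R
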