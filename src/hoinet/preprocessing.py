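"""Signal preparation for band-limited network analysis.

Epoched multichannel data are turned into one representative trial per
participant, session, and frequency band:

1. re-reference every sample to the instantaneous average of all channels,
2. average across trials (the stimulus-locked evoked response),
3. zero-phase Butterworth band-pass filtering into canonical EEG bands.

All three steps are linear, so their order commutes; the pipeline applies
them in the order listed above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "BandTrial",
    "average_reference",
    "representative_trial",
    "bandpass_trial",
    "band_limited_noise",
]

#: Butterworth order used for each pass (high-pass, then low-pass).
FILTER_ORDER = 3


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with [lo, hi] corner frequencies in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lo < self.hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < lo < hi, got lo={self.lo}, hi={self.hi}"
            )

    def validate_against(self, fs: float) -> None:
        if self.hi >= fs / 2:
            raise ValueError(
                f"band {self.name!r}: hi={self.hi} Hz is at or above Nyquist ({fs / 2} Hz)"
            )


#: Canonical EEG band definitions.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta", 12.0, 30.0),
    BandSpec("gamma", 30.0, 40.0),
)


@dataclass
class BandTrial:
    """A participant's trial-averaged, band-filtered signal.

    ``data`` is channels x time; each row is one analyzed variable.
    """

    participant: str
    session: str
    band: BandSpec
    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BandTrial data must be channels x time")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BandTrial data must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


def average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the across-channel mean at every sample.

    ``data`` is channels x time or channels x time x trials; the returned
    array has zero channel mean at every time point (and trial).
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("average reference requires at least 2 channels")
    return data - data.mean(axis=0, keepdims=True)


def representative_trial(data: np.ndarray) -> np.ndarray:
    """Average a channels x time x trials array over the trial axis."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("expected channels x time x trials")
    if data.shape[2] < 1:
        raise ValueError("need at least one trial")
    return data.mean(axis=2)


def _design_band(band: BandSpec, fs: float) -> np.ndarray:
    band.validate_against(fs)
    return sps.butter(
        FILTER_ORDER, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos"
    )


def bandpass_trial(data: np.ndarray, band: BandSpec, fs: float) -> np.ndarray:
    """Zero-phase band-pass filter along the time axis (axis 1 if >= 2-D).

    An order-3 Butterworth band-pass (combining the high- and low-pass
    corner pairs in one section cascade) is applied forward and backward
    (``sosfiltfilt``), giving zero phase distortion and a flat in-band
    response.  Epoch edges are mirror-padded by up to three settling
    lengths of the low corner before filtering, then trimmed, so that slow
    components (the 0.5 Hz corner on 800 ms epochs) do not leak filter
    transients into the analysis window.
    """
    data = np.asarray(data, dtype=float)
    axis = 1 if data.ndim >= 2 else 0
    n = data.shape[axis]
    if n < 12:
        raise ValueError(f"epoch too short to filter ({n} samples)")
    sos = _design_band(band, fs)
    pad = min(int(3 * fs / band.lo), 10 * n)
    pad_width = [(0, 0)] * data.ndim
    pad_width[axis] = (pad, pad)
    padded = np.pad(data, pad_width, mode="reflect")
    out = sps.sosfiltfilt(sos, padded, axis=axis, padlen=min(3 * len(sos), pad))
    return np.moveaxis(np.moveaxis(out, axis, 0)[pad : pad + n], 0, axis)


def band_limited_noise(
    rng: np.random.Generator,
    band: BandSpec,
    fs: float,
    n_samples: int,
    size: tuple[int, ...] = (),
) -> np.ndarray:
    """White Gaussian noise filtered into ``band`` and scaled to unit variance.

    The same filter as :func:`bandpass_trial` is used, so generated signals
    live exactly inside the analyzed pass-band.  Shape is ``size + (n_samples,)``.
    """
    white = rng.standard_normal(size + (n_samples,))
    moved = white if white.ndim == 1 else np.moveaxis(white, -1, 1 if white.ndim >= 2 else 0)
    # bandpass_trial filters axis 1 for >=2-D input, axis 0 for 1-D
    if white.ndim == 1:
        filt = bandpass_trial(white, band, fs)
    else:
        filt = np.moveaxis(bandpass_trial(moved, band, fs), 1, -1)
    sd = filt.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return filt / sd
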