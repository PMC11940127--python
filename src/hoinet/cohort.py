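"""Synthetic two-group, two-session EEG cohort with planted higher-order structure.

The generator emulates the study design every downstream stage expects:
64-channel recordings at 1000 Hz, stimulus-locked 0-800 ms epochs, 576
trials per session, a treatment group of 17 and a control group of 15
participants, and a behavioral table per participant-session (two image
types x two coherence levels, responses against a 1.25 s deadline).

Background activity is modeled per channel as a trial-invariant
"evoked-like" component — one unit-variance band-limited Gaussian process
per analysis band, summed — plus independent white noise per trial.  Trial
averaging suppresses the trial noise and leaves the evoked component, so
structure planted into the evoked component survives the preprocessing
pipeline with a known correlation geometry:

* ``common_driver`` adds one shared band-limited signal to every target
  channel (pairwise correlation ``a^2 / (1 + a^2)`` at amplitude ``a``),
  raising total correlation and redundancy;
* ``collider`` adds private band-limited signals to all but the first
  target channel and their scaled sum to the first (hub) channel, producing
  hub-private correlation ``a^2 / (sqrt(k-1) (1 + a^2))`` and zero
  private-private correlation — a synergy-dominated (negative
  O-information) motif.

Everything is deterministic given the configuration seed; each
participant-session draws from its own seeded stream, so cohorts can be
generated one participant at a time without changing the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocessing import BandSpec, DEFAULT_BANDS, band_limited_noise

__all__ = [
    "CohortConfig",
    "PlantSpec",
    "EpochSet",
    "Cohort",
    "generate_cohort",
    "generate_epochs",
    "plant_structure",
    "generate_behavior",
    "participant_table",
    "common_driver_amplitude",
    "collider_amplitude",
    "implied_correlation",
]

SESSIONS = ("baseline", "follow_up")
GROUPS = ("treatment", "control")


@dataclass(frozen=True)
class PlantSpec:
    """One planted dependency structure.

    ``target_channels`` are montage indices; for ``collider`` the first
    index is the hub that receives the summed private signals.
    """

    target_channels: tuple[int, ...]
    band: BandSpec
    structure: str  # "common_driver" | "collider"
    amplitude: float
    group: str = "treatment"
    session: str = "follow_up"

    def __post_init__(self) -> None:
        if self.structure not in ("common_driver", "collider"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if len(self.target_channels) == 0:
            raise ValueError("empty target channel set")
        if len(set(self.target_channels)) != len(self.target_channels):
            raise ValueError("duplicate target channels")
        if self.structure == "collider" and len(self.target_channels) < 3:
            raise ValueError("collider needs at least 3 target channels")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.group not in GROUPS or self.session not in SESSIONS:
            raise ValueError(f"unknown group/session {self.group}/{self.session}")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the synthetic cohort."""

    n_treatment: int = 17
    n_control: int = 15
    n_channels: int = 64
    fs: float = 1000.0
    epoch_ms: float = 800.0
    n_trials: int = 576
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    planted_effects: tuple[PlantSpec, ...] = ()
    noise_sd: float = 1.0
    gain_jitter: float = 0.10
    # behavioral model: log-normal RTs, per-(group, session) median shifts
    rt_median_ms: float = 620.0
    rt_sigma: float = 0.22
    rt_shift_ms: tuple[tuple[tuple[str, str], float], ...] = (
        (("treatment", "follow_up"), 10.0),
        (("control", "follow_up"), 30.0),
    )
    p_correct_easy: float = 0.90
    p_correct_hard: float = 0.82
    deadline_ms: float = 1250.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_treatment < 2 or self.n_control < 2:
            raise ValueError("need at least 2 participants per group")
        n_samp = self.epoch_ms * self.fs / 1000.0
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("epoch_ms x fs must give an integer sample count")
        if self.n_trials % 16 != 0:
            raise ValueError(
                "n_trials must be divisible by 16 (4 blocks x 2 imType x 2 imCoh)"
            )
        for plant in self.planted_effects:
            if max(plant.target_channels) >= self.n_channels:
                raise ValueError(
                    f"planted channel {max(plant.target_channels)} out of range "
                    f"for {self.n_channels}-channel montage"
                )
            plant.band.validate_against(self.fs)

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_ms * self.fs / 1000.0))

    @property
    def channel_names(self) -> list[str]:
        return [f"ch{i:02d}" for i in range(self.n_channels)]


@dataclass
class EpochSet:
    """One participant-session's epoched data: channels x time x trials."""

    participant: str
    group: str
    session: str
    data: np.ndarray
    fs: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet data must be channels x time x trials")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel_names length must match channel axis")


@dataclass
class Cohort:
    """All participant-sessions plus group labels and behavior tables."""

    config: CohortConfig
    groups: dict[str, str]
    epochs: dict[tuple[str, str], EpochSet]
    behavior: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)

    @property
    def participants(self) -> list[str]:
        return list(self.groups)

    def by_group(self, group: str) -> list[str]:
        return [p for p, g in self.groups.items() if g == group]


def participant_table(config: CohortConfig) -> list[tuple[str, str]]:
    """Deterministic (participant id, group) assignment."""
    rows = [(f"T{i:02d}", "treatment") for i in range(config.n_treatment)]
    rows += [(f"C{i:02d}", "control") for i in range(config.n_control)]
    return rows


def _participant_index(config: CohortConfig, participant: str) -> int:
    ids = [p for p, _ in participant_table(config)]
    return ids.index(participant)


# -- amplitude geometry helpers ------------------------------------------------


def common_driver_amplitude(rho: float) -> float:
    """Amplitude giving pairwise correlation ``rho`` for a common driver."""
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    return math.sqrt(rho / (1.0 - rho))


def collider_amplitude(rho: float, k: int) -> float:
    """Amplitude giving hub-private correlation ``rho`` for a k-channel collider."""
    r = rho * math.sqrt(k - 1)
    if not 0 <= r < 1:
        raise ValueError(f"hub-private correlation {rho} unreachable for k={k}")
    return math.sqrt(r / (1.0 - r))


def implied_correlation(spec: PlantSpec) -> np.ndarray:
    """Within-band correlation matrix the plant induces on its target subset."""
    k = len(spec.target_channels)
    a2 = spec.amplitude**2
    R = np.eye(k)
    if spec.structure == "common_driver":
        rho = a2 / (1.0 + a2)
        R[:] = rho
        np.fill_diagonal(R, 1.0)
    else:  # collider: index 0 is the hub
        rho = a2 / (math.sqrt(k - 1) * (1.0 + a2))
        R[0, 1:] = R[1:, 0] = rho
    return R


# -- EEG generation ------------------------------------------------------------


def _background(
    config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Evoked-like trial-invariant component: channels x time."""
    n, t = config.n_channels, config.n_samples
    evoked = np.zeros((n, t))
    for band in config.bands:
        evoked += band_limited_noise(rng, band, config.fs, t, size=(n,))
    return evoked


def plant_structure(
    epochs: EpochSet, spec: PlantSpec, rng: np.random.Generator | None = None
) -> EpochSet:
    """Add one planted dependency structure to an epoch set.

    Planted signals are trial-invariant (added identically to every trial),
    band-limited with the same filter as the analysis pipeline, and touch
    only the target channels.  Amplitude 0 returns the input unchanged.
    """
    if spec.amplitude == 0:
        return epochs
    if rng is None:
        rng = np.random.default_rng(0)
    targets = list(spec.target_channels)
    if max(targets) >= epochs.data.shape[0]:
        raise ValueError("planted channel index out of range")
    t = epochs.data.shape[1]
    data = epochs.data.copy()
    if spec.structure == "common_driver":
        z = band_limited_noise(rng, spec.band, epochs.fs, t)
        add = spec.amplitude * z
        for ch in targets:
            data[ch] += add[:, None]
    elif spec.structure == "collider":
        k = len(targets)
        privates = band_limited_noise(rng, spec.band, epochs.fs, t, size=(k - 1,))
        for ch, s in zip(targets[1:], privates):
            data[ch] += spec.amplitude * s[:, None]
        hub_sig = privates.sum(axis=0) / math.sqrt(k - 1)
        data[targets[0]] += spec.amplitude * hub_sig[:, None]
    else:  # pragma: no cover - PlantSpec validates
        raise ValueError(f"unknown structure {spec.structure!r}")
    return replace(epochs, data=data)


def generate_epochs(
    config: CohortConfig, participant: str, group: str, session: str
) -> EpochSet:
    """Generate one participant-session epoch set, deterministically.

    The random stream is seeded by (config seed, participant, session), so
    any participant-session can be regenerated in isolation, and adding or
    removing planted effects never alters the background draws.
    """
    idx = _participant_index(config, participant)
    s_idx = SESSIONS.index(session)
    bg_rng = np.random.default_rng([config.seed, 0, idx, s_idx])
    n, t, m = config.n_channels, config.n_samples, config.n_trials

    evoked = _background(config, bg_rng)
    gain_rng = np.random.default_rng([config.seed, 3, idx])
    gain = 1.0 + config.gain_jitter * gain_rng.standard_normal()
    data = np.empty((n, t, m))
    data[:] = (gain * evoked)[:, :, None]
    data += config.noise_sd * bg_rng.standard_normal((n, t, m))

    epochs = EpochSet(
        participant=participant,
        group=group,
        session=session,
        data=data,
        fs=config.fs,
        channel_names=config.channel_names,
    )
    plant_rng = np.random.default_rng([config.seed, 1, idx, s_idx])
    for spec in config.planted_effects:
        if spec.group == group and spec.session == session:
            epochs = plant_structure(epochs, spec, plant_rng)
    return epochs


def generate_behavior(
    config: CohortConfig,
    group: str,
    session: str,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One participant-session trial table of the object categorization task.

    Four blocks of ``n_trials / 4`` trials; within each block, image type
    (face/car) and phase coherence (37.5% easy / 32.5% hard) are each
    balanced 50/50.  Reaction times are log-normal with a per-(group,
    session) median shift; draws beyond the response deadline are recorded
    as timeouts with no RT and count as incorrect.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n_blocks = 4
    per_block = config.n_trials // n_blocks
    cell = per_block // 4  # imType x imCoh cells per block
    shift = dict(config.rt_shift_ms).get((group, session), 0.0)
    median = config.rt_median_ms + shift

    rows = []
    for block in range(1, n_blocks + 1):
        im_type = np.repeat(["face", "car"], per_block // 2)
        im_coh = np.tile(np.repeat([37.5, 32.5], cell), 2)
        order = rng.permutation(per_block)
        im_type, im_coh = im_type[order], im_coh[order]
        rt = median * np.exp(config.rt_sigma * rng.standard_normal(per_block))
        p_corr = np.where(im_coh == 37.5, config.p_correct_easy, config.p_correct_hard)
        correct = rng.random(per_block) < p_corr
        timeout = rt > config.deadline_ms
        outcome = np.where(timeout, "timeout", np.where(correct, "correct", "incorrect"))
        rt = np.where(timeout, np.nan, rt)
        rows.append(
            pd.DataFrame(
                {
                    "block": block,
                    "imType": im_type,
                    "imCoh": im_coh,
                    "rt_ms": rt,
                    "outcome": outcome,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Materialize the full cohort: epochs and behavior for every
    participant and session.

    Identical configurations (including seed) give bit-identical cohorts.
    For large configurations prefer :func:`generate_epochs` per
    participant-session to bound memory.
    """
    groups = dict(participant_table(config))
    epochs: dict[tuple[str, str], EpochSet] = {}
    behavior: dict[tuple[str, str], pd.DataFrame] = {}
    for participant, group in groups.items():
        idx = _participant_index(config, participant)
        for s_idx, session in enumerate(SESSIONS):
            epochs[(participant, session)] = generate_epochs(
                config, participant, group, session
            )
            beh_rng = np.random.default_rng([config.seed, 2, idx, s_idx])
            behavior[(participant, session)] = generate_behavior(
                config, group, session, beh_rng
            )
    return Cohort(config=config, groups=groups, epochs=epochs, behavior=behavior)
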