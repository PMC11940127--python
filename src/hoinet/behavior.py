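"""Behavioral analysis: trial filtering, RT/accuracy summaries, group tests,
and within-participant Bayesian prevalence.

Trials answered faster than 300 ms are discarded as fast guesses and those
slower than 1200 ms as attentional lapses; timed-out trials have no RT but
count as incorrect for accuracy.  Median reaction times are computed over
valid correct trials only; accuracy is the percentage of all class trials
answered correctly.  Group differences use Mann-Whitney U tests; the
population prevalence of a within-participant effect is inferred from the
count of individually significant participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BehaviorSummary",
    "PrevalenceEstimate",
    "filter_trials",
    "summarize_behavior",
    "mann_whitney_u",
    "bayesian_prevalence",
]

RT_MIN_MS = 300.0
RT_MAX_MS = 1200.0

TRIAL_CLASSES = ("all", "easy", "hard", "face", "car")


@dataclass(frozen=True)
class BehaviorSummary:
    participant: str
    session: str
    trial_class: str
    median_rt_ms: float
    accuracy_pct: float
    n_trials: int
    n_valid_correct: int


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Population prevalence of a within-participant effect.

    ``k`` of ``n`` participants were individually significant at level
    ``alpha``.  Under prevalence ``gamma`` the per-participant hit rate is
    ``theta = alpha + gamma * (1 - alpha)``; with a uniform prior the
    posterior on ``theta`` is Beta(k + 1, n - k + 1), mapped to ``gamma``
    and truncated at zero.
    """

    k: int
    n: int
    alpha: float
    gamma_map: float
    interval: tuple[float, float]


def filter_trials(trials: pd.DataFrame) -> np.ndarray:
    """Validity mask for RT analyses: 300 ms <= RT <= 1200 ms inclusive.

    Timeouts (no RT) are invalid for RT analyses but still count as
    incorrect trials for accuracy.
    """
    rt = trials["rt_ms"].to_numpy(dtype=float)
    timeout = trials["outcome"].to_numpy() == "timeout"
    if np.any(np.isnan(rt) & ~timeout):
        raise ValueError("missing RT on a non-timeout trial")
    if np.any(rt[~np.isnan(rt)] < 0):
        raise ValueError("negative reaction time")
    with np.errstate(invalid="ignore"):
        return (~timeout) & (rt >= RT_MIN_MS) & (rt <= RT_MAX_MS)


def _class_mask(trials: pd.DataFrame, trial_class: str) -> np.ndarray:
    if trial_class == "all":
        return np.ones(len(trials), dtype=bool)
    if trial_class == "easy":
        return trials["imCoh"].to_numpy() == 37.5
    if trial_class == "hard":
        return trials["imCoh"].to_numpy() == 32.5
    if trial_class in ("face", "car"):
        return trials["imType"].to_numpy() == trial_class
    raise ValueError(f"unknown trial class {trial_class!r}; expected {TRIAL_CLASSES}")


def summarize_behavior(
    trials: pd.DataFrame,
    trial_class: str = "all",
    participant: str = "",
    session: str = "",
) -> BehaviorSummary:
    """Median RT (valid correct trials) and accuracy (% of all class trials)."""
    mask = _class_mask(trials, trial_class)
    if not mask.any():
        raise ValueError(f"no trials in class {trial_class!r}")
    sub = trials.loc[mask]
    valid = filter_trials(sub)
    correct = sub["outcome"].to_numpy() == "correct"
    vc = valid & correct
    median_rt = float(np.median(sub["rt_ms"].to_numpy(dtype=float)[vc])) if vc.any() else float("nan")
    accuracy = 100.0 * correct.sum() / len(sub)
    return BehaviorSummary(
        participant=participant,
        session=session,
        trial_class=trial_class,
        median_rt_ms=median_rt,
        accuracy_pct=float(accuracy),
        n_trials=int(len(sub)),
        n_valid_correct=int(vc.sum()),
    )


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (exact for small tie-free samples)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all values tied across both groups; p = 1")
        return float(a.size * b.size / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def bayesian_prevalence(
    k: int,
    n: int,
    alpha: float = 0.05,
    mc_runs: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> PrevalenceEstimate:
    """Population prevalence from a count of significant within-participant tests.

    The MAP estimate is ``max(0, (k/n - alpha) / (1 - alpha))``; the 95%
    credible interval comes from Monte Carlo draws of the Beta posterior on
    the hit rate, transformed to the prevalence scale.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n with n >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gamma_map = max(0.0, (k / n - alpha) / (1.0 - alpha))
    theta = rng.beta(k + 1, n - k + 1, size=mc_runs)
    gamma = np.clip((theta - alpha) / (1.0 - alpha), 0.0, 1.0)
    lo, hi = np.percentile(gamma, [2.5, 97.5])
    lo = min(float(lo), gamma_map)
    hi = max(float(hi), gamma_map)
    return PrevalenceEstimate(k=k, n=n, alpha=alpha, gamma_map=gamma_map,
                              interval=(lo, hi))


def within_participant_rt_tests(
    baseline: pd.DataFrame, follow_up: pd.DataFrame, alpha: float = 0.05
) -> bool:
    """Two-sided rank-sum test on valid correct-trial RTs, baseline vs follow-up.

    Returns whether the participant individually shows a significant RT
    change at level ``alpha`` (input to the prevalence analysis).
    """
    rts = []
    for table in (baseline, follow_up):
        valid = filter_trials(table) & (table["outcome"].to_numpy() == "correct")
        rts.append(table["rt_ms"].to_numpy(dtype=float)[valid])
    _, p = mann_whitney_u(rts[0], rts[1])
    return p < alpha
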