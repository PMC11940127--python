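"""Greedy search for maximally group-discriminative channel subsets.

For one frequency band and one measure (TC, DTC, O-information, or its
negation), the search starts by scoring every subset at the start order
(pairs for TC/DTC; triplets for O-information, which is identically zero on
pairs), picking the subset whose between-group Cohen's d is largest
(``maximize``) or smallest (``minimize``), and then growing that subset one
channel at a time up to a maximum interaction order (16 by default),
scoring only the supersets of the current best at each step.  This visits
``C(n, k0) + sum_k (n - k)`` subsets instead of every ``C(n, k)``, trading
global optimality for tractability.

Effect sizes are computed from follow-up-session values; the baseline
session enters only later, as an ANCOVA covariate.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import hoi
from .preprocessing import BandTrial

__all__ = [
    "EffectSize",
    "SearchStep",
    "SearchTrace",
    "cohens_d",
    "measure_from_corr",
    "participant_corr_matrices",
    "score_all_subsets",
    "expand_candidates",
    "run_gsa",
    "negate_o_information",
]

MEASURES = ("TC", "DTC", "O", "negO")

#: default seeding order per measure; O is identically 0 on pairs
DEFAULT_START_ORDER = {"TC": 2, "DTC": 2, "O": 3, "negO": 3}
DEFAULT_MAX_ORDER = 16


@dataclass(frozen=True)
class EffectSize:
    """Pooled-SD standardized mean difference (Cohen's d), treatment - control."""

    d: float
    mu_treatment: float
    mu_control: float
    s: float
    m_treatment: int
    m_control: int


@dataclass
class SearchStep:
    order: int
    subset: tuple[int, ...]
    effect: EffectSize
    values: dict[str, float]  # per-participant follow-up measure values


@dataclass
class SearchTrace:
    band: str
    measure: str
    direction: str
    steps: list[SearchStep] = field(default_factory=list)
    n_evaluations: int = 0  # measure evaluations per participant

    @property
    def best(self) -> SearchStep:
        if not self.steps:
            raise ValueError("empty search trace")
        return self.steps[-1]


def cohens_d(treatment: np.ndarray, control: np.ndarray) -> EffectSize:
    """Cohen's d with the pooled standard deviation.

    ``d = (mu_t - mu_c) / s`` with
    ``s = sqrt(((m_t - 1) s_t^2 + (m_c - 1) s_c^2) / (m_t + m_c - 2))``;
    positive values mean larger measure values in the treatment group.
    """
    t = np.asarray(treatment, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("each group needs at least 2 values")
    mt, mc = t.size, c.size
    mu_t, mu_c = t.mean(), c.mean()
    s2 = ((mt - 1) * t.var(ddof=1) + (mc - 1) * c.var(ddof=1)) / (mt + mc - 2)
    s = math.sqrt(s2)
    diff = mu_t - mu_c
    if s == 0:
        if diff == 0:
            d = 0.0
        else:
            warnings.warn("zero pooled SD with unequal means; d set to signed infinity")
            d = math.copysign(math.inf, diff)
    else:
        d = diff / s
    return EffectSize(d=d, mu_treatment=mu_t, mu_control=mu_c, s=s,
                      m_treatment=mt, m_control=mc)


def measure_from_corr(R: np.ndarray, indices, measure: str) -> float:
    """Evaluate one measure on a channel subset of a copula correlation matrix."""
    idx = np.asarray(list(indices), dtype=int)
    if measure == "TC":
        return hoi.tc_from_corr(R, idx)
    if measure == "DTC":
        return hoi.dtc_from_corr(R, idx)
    if measure == "O":
        if idx.size < 3:
            raise ValueError("O-information is identically zero for pairs; use order >= 3")
        return hoi.o_from_corr(R, idx)
    if measure == "negO":
        if idx.size < 3:
            raise ValueError("negO is identically zero for pairs; use order >= 3")
        return -hoi.o_from_corr(R, idx)
    raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")


def participant_corr_matrices(
    band_trials: dict[str, BandTrial]
) -> dict[str, np.ndarray]:
    """Copula correlation matrix per participant.

    Every subset measure is a determinant functional of this matrix, so
    computing it once per participant makes subset scoring cheap.
    """
    mats = {}
    montage = None
    for pid, trial in band_trials.items():
        if montage is None:
            montage = trial.n_channels
        elif trial.n_channels != montage:
            raise ValueError(f"participant {pid}: montage size mismatch")
        mats[pid] = hoi.copula_correlation(trial.data)
    return mats


def _subset_values(
    mats: dict[str, np.ndarray], subset: tuple[int, ...], measure: str
) -> dict[str, float]:
    return {pid: measure_from_corr(R, subset, measure) for pid, R in mats.items()}


def _effect(values: dict[str, float], groups: dict[str, str]) -> EffectSize:
    t = np.array([v for p, v in values.items() if groups[p] == "treatment"])
    c = np.array([v for p, v in values.items() if groups[p] == "control"])
    return cohens_d(t, c)


def score_all_subsets(
    band_trials: dict[str, BandTrial],
    groups: dict[str, str],
    order: int,
    measure: str,
    subsets: list[tuple[int, ...]] | str = "all",
) -> list[tuple[tuple[int, ...], EffectSize]]:
    """Between-group effect size for every channel subset of one order."""
    mats = participant_corr_matrices(band_trials)
    n = next(iter(mats.values())).shape[0]
    if subsets == "all":
        subsets = list(itertools.combinations(range(n), order))
    out = []
    for subset in subsets:
        values = _subset_values(mats, tuple(subset), measure)
        out.append((tuple(subset), _effect(values, groups)))
    return out


def expand_candidates(
    best: tuple[int, ...], montage_size: int
) -> list[tuple[int, ...]]:
    """All supersets of ``best`` with exactly one extra channel."""
    if len(best) >= montage_size:
        raise ValueError("subset already spans the montage")
    existing = set(best)
    return [
        tuple(sorted(best + (ch,)))
        for ch in range(montage_size)
        if ch not in existing
    ]


def _pick(
    scored: list[tuple[tuple[int, ...], EffectSize]], direction: str
) -> tuple[tuple[int, ...], EffectSize]:
    """Arg-best subset; ties broken by lexicographically smallest subset."""
    sign = 1.0 if direction == "maximize" else -1.0
    return max(scored, key=lambda se: (sign * se[1].d, tuple(-i for i in se[0])))


def run_gsa(
    band_trials: dict[str, BandTrial],
    groups: dict[str, str],
    measure: str,
    direction: str = "maximize",
    start_order: int | None = None,
    max_order: int = DEFAULT_MAX_ORDER,
    band_name: str | None = None,
) -> SearchTrace:
    """Greedy stepwise search for the most group-discriminative subsets.

    ``band_trials`` maps participant id to their follow-up-session
    :class:`BandTrial`; ``groups`` maps participant id to group label.
    Returns the full trace: the chosen subset, its effect size, and the
    per-participant values at every interaction order.
    """
    if direction not in ("maximize", "minimize"):
        raise ValueError(f"unknown direction {direction!r}")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    if start_order is None:
        start_order = DEFAULT_START_ORDER[measure]
    if start_order not in (2, 3):
        raise ValueError("start order must be 2 or 3")

    mats = participant_corr_matrices(band_trials)
    n = next(iter(mats.values())).shape[0]
    if n < start_order:
        raise ValueError(f"montage of {n} channels cannot seed order {start_order}")
    max_order = min(max_order, n)
    if band_name is None:
        band_name = next(iter(band_trials.values())).band.name

    trace = SearchTrace(band=band_name, measure=measure, direction=direction)

    # exhaustive seeding at the start order
    seeds = list(itertools.combinations(range(n), start_order))
    scored = []
    for subset in seeds:
        values = _subset_values(mats, subset, measure)
        scored.append((subset, _effect(values, groups)))
    trace.n_evaluations += len(seeds)
    best, effect = _pick(scored, direction)
    trace.steps.append(
        SearchStep(start_order, best, effect, _subset_values(mats, best, measure))
    )

    # stepwise expansion
    for order in range(start_order + 1, max_order + 1):
        candidates = expand_candidates(best, n)
        scored = []
        for subset in candidates:
            values = _subset_values(mats, subset, measure)
            scored.append((subset, _effect(values, groups)))
        trace.n_evaluations += len(candidates)
        best, effect = _pick(scored, direction)
        trace.steps.append(
            SearchStep(order, best, effect, _subset_values(mats, best, measure))
        )
    return trace


def negate_o_information(values: dict[str, float], measure: str = "O") -> dict[str, float]:
    """Flip the sign of O-information values (relabeling them negO).

    Maximizing the negated values finds maximally *synergistic*
    discriminative networks, the mirror of the redundancy search.
    """
    if measure != "O":
        raise ValueError("sign reversal applies to O-information values only")
    return {pid: -v for pid, v in values.items()}
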