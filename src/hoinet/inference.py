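"""Baseline-adjusted group inference over discovered networks.

For every network the search selected at follow-up, the same measure is
recomputed on the baseline-session data of every participant ("baseline
back-computation").  Each (band, order) model is then an ANCOVA,

    follow_up ~ intercept + group + baseline,

with group coded control = 0 / treatment = 1, so a positive group
coefficient means higher baseline-adjusted values in the treatment group.
The group effect is the type-III F test with (1, m - 3) degrees of
freedom.  Homoskedasticity is checked per model with White's test (reported,
never used as a filter), and the false discovery rate is controlled with
the Benjamini-Hochberg step-up procedure separately for each
(measure, direction) family across all bands and interaction orders.

Because subsets are *selected* to maximize the group difference at
follow-up, the raw per-model p values are anti-conservative by
construction; the calibration claim that matters is the family-level
false-positive behavior on null cohorts, and serialized outputs carry a
``selection_caveat`` flag for downstream readers.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import hoi
from .gsa import SearchTrace, measure_from_corr
from .preprocessing import BandTrial

__all__ = [
    "AncovaResult",
    "baseline_backcompute",
    "ancova_group_effect",
    "white_test",
    "benjamini_hochberg",
    "apply_fdr",
    "results_table",
]

SELECTION_CAVEAT = (
    "subsets were selected to maximize the follow-up group difference; "
    "per-model p values are anti-conservative and calibrated only at the "
    "null-cohort family level"
)


@dataclass
class AncovaResult:
    """One (band, measure, direction, order) baseline-adjusted group model."""

    band: str
    measure: str
    direction: str
    order: int
    F: float
    p: float
    df: tuple[int, int]
    group_coef: float
    white_lm: float = math.nan
    white_p: float = math.nan
    degenerate: bool = False
    fdr_significant: bool = False
    fdr_critical_p: float = math.nan


def baseline_backcompute(
    trace: SearchTrace, baseline_trials: dict[str, BandTrial]
) -> dict[int, dict[str, float]]:
    """Recompute the trace's chosen subsets on baseline-session data.

    Returns {order: {participant: value}} using exactly the subsets the
    follow-up search selected.  The measures are permutation-invariant in
    the channels, so subset identity, not ordering, is what is preserved.
    """
    needed = {pid for step in trace.steps for pid in step.values}
    missing = sorted(needed - set(baseline_trials))
    if missing:
        raise ValueError(f"missing baseline data for participants: {missing}")
    mats = {pid: hoi.copula_correlation(baseline_trials[pid].data) for pid in needed}
    out: dict[int, dict[str, float]] = {}
    for step in trace.steps:
        out[step.order] = {
            pid: measure_from_corr(mats[pid], step.subset, trace.measure)
            for pid in step.values
        }
    return out


def ancova_group_effect(
    follow_up: np.ndarray,
    baseline: np.ndarray,
    groups: np.ndarray,
) -> AncovaResult:
    """OLS ANCOVA of follow-up values on group (0/1) and baseline covariate.

    ``groups`` may be 0/1 integers or "treatment"/"control" labels.  A fit
    with (numerically) zero residual variance but a nonzero group effect is
    flagged degenerate and reported with an infinite-F sentinel rather than
    raising, so batch sweeps complete.
    """
    y = np.asarray(follow_up, dtype=float)
    b = np.asarray(baseline, dtype=float)
    g = np.asarray(
        [1 if x in (1, "treatment") else 0 for x in np.asarray(groups).ravel()],
        dtype=float,
    )
    m = y.size
    if b.size != m or g.size != m:
        raise ValueError("follow_up, baseline and groups must have equal length")
    if g.sum() < 3 or (m - g.sum()) < 3:
        raise ValueError("need at least 3 participants per group")
    if np.ptp(b) == 0:
        raise ValueError("constant baseline covariate gives a singular design")

    X = np.column_stack([np.ones(m), g, b])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("singular ANCOVA design matrix")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = m - 3
    sse = float(resid @ resid)
    XtX_inv = np.linalg.inv(X.T @ X)
    group_coef = float(beta[1])

    scale = max(float(y @ y), 1.0)
    if sse <= 1e-12 * scale:
        # perfect fit: the F statistic is unbounded
        if abs(group_coef) > 1e-10:
            warnings.warn("degenerate ANCOVA fit with zero residual variance")
            F, p, degen = math.inf, 0.0, True
        else:
            F, p, degen = 0.0, 1.0, True
    else:
        mse = sse / df_resid
        se = math.sqrt(mse * XtX_inv[1, 1])
        F = (group_coef / se) ** 2
        p = float(stats.f.sf(F, 1, df_resid))
        degen = False

    lm, lm_p = (math.nan, math.nan)
    if not degen:
        lm, lm_p = white_test(resid, X)
    return AncovaResult(
        band="", measure="", direction="", order=0,
        F=F, p=p, df=(1, df_resid), group_coef=group_coef,
        white_lm=lm, white_p=lm_p, degenerate=degen,
    )


def white_test(residuals: np.ndarray, design: np.ndarray) -> tuple[float, float]:
    """White's homoskedasticity test: LM = m * R^2 of the auxiliary regression.

    Squared residuals are regressed on the model regressors, their squares,
    and pairwise cross-products; the LM statistic is chi-square with the
    rank of the (de-constanted) auxiliary design as degrees of freedom.
    Collinear auxiliary columns (e.g. the square of a binary indicator) are
    absorbed into the rank, matching the chi-square reference distribution.
    """
    resid = np.asarray(residuals, dtype=float)
    X = np.asarray(design, dtype=float)
    m = resid.size
    # drop any constant column; re-added once below
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    Z = X[:, keep]
    cols = [np.ones(m)] + [Z[:, j] for j in range(Z.shape[1])]
    for j in range(Z.shape[1]):
        for k in range(j, Z.shape[1]):
            cols.append(Z[:, j] * Z[:, k])
    A = np.column_stack(cols)
    df = np.linalg.matrix_rank(A) - 1
    if df < 1:
        raise ValueError("degenerate auxiliary design for White's test")
    if m <= df + 1:
        raise ValueError("too few observations for White's test")
    u2 = resid**2
    if np.ptp(u2) == 0:
        return 0.0, 1.0
    coef, _, _, _ = np.linalg.lstsq(A, u2, rcond=None)
    fitted = A @ coef
    ss_tot = float(((u2 - u2.mean()) ** 2).sum())
    ss_res = float(((u2 - fitted) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    lm = m * r2
    return float(lm), float(stats.chi2.sf(lm, df))


def benjamini_hochberg(
    p_values: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up FDR control.

    Sort p values ascending, find the largest rank ``i`` with
    ``p_(i) <= i * q / m``; every p value at or below that critical
    ``p_(i)`` is declared significant.  Returns (mask, critical p); the
    critical p is NaN when nothing is significant.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresholds = (np.arange(1, m + 1) * q) / m
    passing = np.nonzero(sorted_p <= thresholds)[0]
    if passing.size == 0:
        return np.zeros(m, dtype=bool), math.nan
    critical = float(sorted_p[passing[-1]])
    return p <= critical, critical


def apply_fdr(results: list[AncovaResult], q: float = 0.05) -> list[AncovaResult]:
    """Control FDR separately within each (measure, direction) family.

    Each family spans all bands and interaction orders of one measure in
    one search direction; the per-family critical p values are written back
    onto the results.
    """
    keyfn = lambda r: (r.measure, r.direction)
    for _, group_iter in itertools.groupby(sorted(results, key=keyfn), key=keyfn):
        family = list(group_iter)
        mask, critical = benjamini_hochberg(
            np.array([r.p for r in family]), q=q
        )
        for r, sig in zip(family, mask):
            r.fdr_significant = bool(sig)
            r.fdr_critical_p = critical
    return results


def results_table(results: list[AncovaResult]) -> pd.DataFrame:
    """Flat table of ANCOVA results (the machine twin of an F-statistic grid)."""
    df = pd.DataFrame(
        {
            "band": [r.band for r in results],
            "measure": [r.measure for r in results],
            "direction": [r.direction for r in results],
            "order": [r.order for r in results],
            "F": [r.F for r in results],
            "p": [r.p for r in results],
            "df1": [r.df[0] for r in results],
            "df2": [r.df[1] for r in results],
            "group_coef": [r.group_coef for r in results],
            "white_lm": [r.white_lm for r in results],
            "white_p": [r.white_p for r in results],
            "degenerate": [r.degenerate for r in results],
            "fdr_critical_p": [r.fdr_critical_p for r in results],
            "fdr_significant": [r.fdr_significant for r in results],
        }
    )
    df.attrs["selection_caveat"] = SELECTION_CAVEAT
    return df
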