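"""Gaussian-copula estimation of higher-order information measures.

For a channel subset :math:`X^n = (X_1, \\dots, X_n)` the three quantities of
interest are

* total correlation  ``TC = sum_j H(X_j) - H(X_1..X_n)`` — the collective
  constraints, i.e. information that is *similar* across channels;
* dual total correlation (binding information)
  ``DTC = H(X_1..X_n) - sum_j H(X_j | X_-j)`` — shared randomness,
  i.e. *complementary* information;
* O-information ``O = TC - DTC`` — positive when the subset is
  redundancy-dominated, negative when synergy-dominated.

Each channel's time series is rank-transformed to exact standard-normal
marginals (the Gaussian copula), after which the Gaussian entropy formulas
apply to the empirical correlation matrix ``R``:

    TC  = -1/2 log2 det R
    DTC = 1/2 [ sum_j log2 det R_{-j} - (n - 1) log2 det R ]

These are lower-bound estimates of the true (non-Gaussian) quantities and
are invariant under strictly increasing per-channel transforms.  All values
are reported in bits.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

__all__ = [
    "copula_transform",
    "copula_correlation",
    "gaussian_joint_entropy",
    "total_correlation",
    "dual_total_correlation",
    "o_information",
    "tc_from_corr",
    "dtc_from_corr",
    "o_from_corr",
    "normalize_by_order",
]

#: tolerance below which small negative estimates are treated as zero
EPS = 1e-9
#: one-shot ridge applied to near-singular correlation matrices
RIDGE = 1e-10

LOG2E = math.log2(math.e)


class DegenerateInputError(ValueError):
    """Raised for constant channels or rank-deficient correlation matrices."""


def copula_transform(x: np.ndarray) -> np.ndarray:
    """Map a series to exact standard-normal marginals via empirical ranks.

    Each value is replaced by ``Phi^{-1}(r / (T + 1))`` where ``r`` is its
    (average, for ties) rank among the ``T`` samples.  The output depends on
    the input only through its ordering, so any strictly increasing
    transform of ``x`` yields the identical output.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("copula_transform expects a 1-D series")
    t = x.size
    if t < 3:
        raise ValueError(f"need at least 3 samples, got {t}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series has no copula representation")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf(ranks / (t + 1))


def copula_correlation(data: np.ndarray) -> np.ndarray:
    """Correlation matrix of the row-wise copula transform of channels x time data."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("expected channels x time")
    z = np.empty_like(data)
    for j in range(data.shape[0]):
        try:
            z[j] = copula_transform(data[j])
        except DegenerateInputError as err:
            raise DegenerateInputError(f"channel {j}: {err}") from None
    return np.corrcoef(z)


def gaussian_joint_entropy(R: np.ndarray) -> float:
    """Joint differential entropy (bits) of a Gaussian with correlation matrix R.

    ``H = 1/2 log2((2 pi e)^k det R)``.
    """
    R = _checked_corr(R)
    k = R.shape[0]
    return 0.5 * (k * math.log2(2 * math.pi * math.e) + _log2_det(R))


def _checked_corr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValueError("correlation matrix must have unit diagonal")
    return R


#: smallest eigenvalue a correlation matrix may have and still be treated as PD
PD_TOL = 1e-9


def _log2_det(R: np.ndarray, subset: str | None = None) -> float:
    """log2 det of a correlation matrix, with a single ridge retry.

    A one-shot diagonal ridge absorbs rounding-level indefiniteness; an
    effectively rank-deficient matrix (duplicate or collinear channels)
    stays below tolerance even after the ridge and is a hard error naming
    the offending subset.
    """
    eigs = np.linalg.eigvalsh(R)
    if eigs.min() < PD_TOL:
        eigs = eigs + RIDGE
        if eigs.min() < PD_TOL:
            where = f" for subset {subset}" if subset else ""
            raise DegenerateInputError(
                f"correlation matrix is rank deficient or not positive definite{where}"
            )
    return float(np.sum(np.log2(eigs)))


def tc_from_corr(R: np.ndarray, indices: np.ndarray | None = None) -> float:
    """Total correlation (bits) of a (sub)matrix of a correlation matrix."""
    sub = R if indices is None else R[np.ix_(indices, indices)]
    if sub.shape[0] < 2:
        raise ValueError("total correlation needs at least 2 channels")
    return -0.5 * _log2_det(sub, subset=_fmt(indices))


def dtc_from_corr(R: np.ndarray, indices: np.ndarray | None = None) -> float:
    """Dual total correlation (bits) of a (sub)matrix of a correlation matrix."""
    sub = R if indices is None else R[np.ix_(indices, indices)]
    k = sub.shape[0]
    if k < 2:
        raise ValueError("dual total correlation needs at least 2 channels")
    logdet = _log2_det(sub, subset=_fmt(indices))
    acc = 0.0
    for j in range(k):
        keep = [i for i in range(k) if i != j]
        acc += _log2_det(sub[np.ix_(keep, keep)], subset=_fmt(indices))
    return 0.5 * (acc - (k - 1) * logdet)


def o_from_corr(R: np.ndarray, indices: np.ndarray | None = None) -> float:
    """O-information (bits): exactly ``tc_from_corr - dtc_from_corr``."""
    return tc_from_corr(R, indices) - dtc_from_corr(R, indices)


def _fmt(indices: np.ndarray | None) -> str | None:
    return None if indices is None else str(list(np.asarray(indices)))


def total_correlation(data: np.ndarray) -> float:
    """TC (bits) of channels x time data via the Gaussian copula."""
    return tc_from_corr(copula_correlation(data))


def dual_total_correlation(data: np.ndarray) -> float:
    """DTC (bits) of channels x time data via the Gaussian copula."""
    return dtc_from_corr(copula_correlation(data))


def o_information(data: np.ndarray) -> float:
    """O-information (bits) of channels x time data via the Gaussian copula.

    Identically zero for channel pairs (TC = DTC when n = 2); at least three
    channels are needed for an informative value.
    """
    R = copula_correlation(data)
    return tc_from_corr(R) - dtc_from_corr(R)


def normalize_by_order(value: float, order: int) -> float:
    """Divide an information value by its interaction order (bits / channel)."""
    if order < 2:
        raise ValueError("interaction order must be >= 2")
    return value / order
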