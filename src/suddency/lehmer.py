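"""The Lehmer transform and its suddency-moment domain.

For a strictly positive sample ``x = (x_1, ..., x_n)`` the Lehmer
transform is the ratio of consecutive power sums

    L(s) = sum_i x_i**s / sum_i x_i**(s-1),

extended to ``s = +inf`` (the maximum) and ``s = -inf`` (the minimum).
``s`` is called the suddency moment: sweeping it generates the familiar
statistics (harmonic mean at 0, arithmetic mean at 1, contra-harmonic
mean at 2, extremes at +-inf), so L acts as a statistic-generating
function.  For a sample with at least two distinct values L is strictly
increasing in s and maps the extended reals onto [min x, max x], which
makes it invertible: every statistic value in that range has a unique
suddency moment.

Power sums are evaluated in log space (log-sum-exp) so the transform is
stable for |s| of several hundred even on samples spanning many decades.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .signal import DomainError, PositiveSignal, preprocess_to_positive, as_positive_values

__all__ = [
    "lehmer_transform",
    "lehmer_derivative",
    "inverse_lehmer",
    "lagrange_burmann_inverse",
    "windowed_transform",
    "pointwise_inverse_series",
    "flag_anomalies",
    "SeriesDivergenceWarning",
]

#: beyond this |s| the transform is numerically indistinguishable from the
#: extreme order statistics and is returned as such
LARGE_S_CUTOFF = 700.0


class SeriesDivergenceWarning(UserWarning):
    """Lagrange-Buermann series terms stopped decreasing; the partial sum
    (attached as ``partial_sum``) is returned but should not be trusted."""

    def __init__(self, message, partial_sum):
        super().__init__(message)
        self.partial_sum = partial_sum


def _logs(x) -> np.ndarray:
    return np.log(as_positive_values(x))


def transform_many(logx: np.ndarray, s: np.ndarray, cutoff: float = LARGE_S_CUTOFF) -> np.ndarray:
    """Vectorized L(s) over an array of finite suddency moments.

    ``logx`` are the log-values of the signal.  Values of |s| beyond
    ``cutoff`` are evaluated as the exact limit (max/min).
    """
    s = np.asarray(s, dtype=float)
    out = np.empty(s.shape, dtype=float)
    hi = s > cutoff
    lo = s < -cutoff
    mid = ~(hi | lo)
    if np.any(hi):
        out[hi] = np.exp(logx.max())
    if np.any(lo):
        out[lo] = np.exp(logx.min())
    if np.any(mid):
        sm = s[mid][:, None]
        num = logsumexp(sm * logx[None, :], axis=1)
        den = logsumexp((sm - 1.0) * logx[None, :], axis=1)
        out[mid] = np.exp(num - den)
    return out


def transform_with_derivative(logx: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (L(s), dL/ds) at finite s, sharing the power-sum work.

    The derivative is L(s) times the difference between the log-value
    means under the softmax weights x**s and x**(s-1); it is nonnegative
    and zero only for constant samples.
    """
    s = np.asarray(s, dtype=float)
    sm = s[:, None]
    a = sm * logx[None, :]
    b = a - logx[None, :]
    la = logsumexp(a, axis=1, keepdims=True)
    lb = logsumexp(b, axis=1, keepdims=True)
    wa = np.exp(a - la)
    wb = np.exp(b - lb)
    L = np.exp(la - lb).ravel()
    delta = wa @ logx - wb @ logx
    return L, L * np.maximum(delta, 0.0)


def derivative_many(logx: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Vectorized first derivative dL/ds at finite s."""
    return transform_with_derivative(logx, s)[1]


def lehmer_transform(x, s: float) -> float:
    """Evaluate the Lehmer transform L(s) of a positive signal.

    Parameters
    ----------
    x : array_like or PositiveSignal
        Strictly positive sample.
    s : float
        Suddency moment; ``+inf`` / ``-inf`` return the max / min.

    Returns
    -------
    float
        A statistic in ``[min(x), max(x)]``.
    """
    v = as_positive_values(x)
    s = float(s)
    if np.isnan(s):
        raise DomainError("suddency moment must not be NaN")
    if s >= LARGE_S_CUTOFF:
        return float(v.max())
    if s <= -LARGE_S_CUTOFF:
        return float(v.min())
    t = float(transform_many(np.log(v), np.array([s]))[0])
    return float(min(max(t, v.min()), v.max()))


def lehmer_derivative(x, s: float, order: int = 1, step: float = 1e-4) -> float:
    """Derivative of L with respect to the suddency moment at finite s.

    Order 1 uses the closed form; higher orders are evaluated by nested
    central differences of the analytic first derivative (documented
    numerical approximation).
    """
    v = as_positive_values(x)
    s = float(s)
    if not np.isfinite(s):
        raise DomainError("derivative requires a finite suddency moment")
    if not (isinstance(order, (int, np.integer)) and order >= 1):
        raise ValueError("order must be a positive integer")
    logx = np.log(v)
    if order == 1:
        return float(derivative_many(logx, np.array([s]))[0])

    def dk(sval: float, k: int) -> float:
        if k == 1:
            return float(derivative_many(logx, np.array([sval]))[0])
        h = step * max(1.0, abs(sval))
        return (dk(sval + h, k - 1) - dk(sval - h, k - 1)) / (2.0 * h)

    return dk(s, order)


def _require_nondegenerate(v: np.ndarray) -> None:
    if np.unique(v).size < 2:
        raise DomainError(
            "constant signal: the Lehmer transform is not injective, no inverse exists"
        )


def inverse_lehmer(x, t: float, tol: float = 1e-12, max_bracket: float = 1e6) -> float:
    """Suddency moment s with L(s) = t (the inverse Lehmer transform).

    ``t = max(x)`` maps to ``+inf`` and ``t = min(x)`` to ``-inf``; interior
    statistics are inverted by expanding-bracket bisection (Brent) on the
    strictly increasing map ``s -> L(s)``.

    Raises
    ------
    DomainError
        For a constant signal (L is not injective) or t outside
        ``[min(x), max(x)]``.
    """
    v = as_positive_values(x)
    _require_nondegenerate(v)
    t = float(t)
    vmin, vmax = float(v.min()), float(v.max())
    eps = 1e-13 * (vmax - vmin)
    if t > vmax + eps or t < vmin - eps:
        raise DomainError(f"t={t} outside the transform range [{vmin}, {vmax}]")
    if t >= vmax - eps:
        return np.inf
    if t <= vmin + eps:
        return -np.inf
    logx = np.log(v)

    def f(s):
        return float(transform_many(logx, np.array([s]))[0]) - t

    lo, hi = -1.0, 1.0
    flo, fhi = f(lo), f(hi)
    while flo > 0:
        lo *= 2.0
        if -lo > max_bracket:
            return -np.inf
        flo = f(lo)
    while fhi < 0:
        hi *= 2.0
        if hi > max_bracket:
            return np.inf
        fhi = f(hi)
    return float(brentq(f, lo, hi, xtol=tol))


def _taylor_coeffs(logx: np.ndarray, s0: float, order: int, h: float = 0.5) -> np.ndarray:
    """Approximate Taylor coefficients of L around s0 up to ``order``.

    Least-squares polynomial fit on Chebyshev nodes in [s0-h, s0+h]; the
    returned ``c[j]`` approximates ``L^(j)(s0) / j!``.
    """
    m = 4 * (order + 1)
    nodes = s0 + h * np.cos(np.pi * (np.arange(m) + 0.5) / m)
    vals = transform_many(logx, nodes)
    coeffs = np.polynomial.polynomial.polyfit(nodes - s0, vals, order)
    return coeffs


def _reverse_series(a: np.ndarray, K: int) -> np.ndarray:
    """Compositional inverse of t = sum_{j>=1} a_j u^j, truncated at order K.

    Returns b with u = sum_{k>=1} b_k w^k (w = t shift).  Uses fixed-point
    iteration u <- u + (w - P(u)) / a_1 on truncated polynomials.
    """
    if abs(a[1]) < 1e-300:
        raise DomainError("series reversal requires a nonzero first derivative")

    def mul(p, q):
        return np.convolve(p, q)[: K + 1]

    # u(w) as coefficients in w, u[0] = 0
    u = np.zeros(K + 1)
    u[1] = 1.0 / a[1]
    w = np.zeros(K + 1)
    w[1] = 1.0
    for _ in range(K + 2):
        # P(u(w)) truncated
        pu = np.zeros(K + 1)
        upow = np.zeros(K + 1)
        upow[0] = 1.0
        for j in range(1, len(a)):
            upow = mul(upow, u)
            if j < len(a):
                pu = pu + a[j] * upow
        u = u + (w - pu) / a[1]
    return u


def lagrange_burmann_inverse(x, t: float, s0: float = 0.0, K: int = 8) -> float:
    """Series approximation of the inverse transform around an expansion point.

    Implements the Lagrange-Buermann inversion of ``t = L(s)`` about
    ``s0``: the K-term truncation of the reverted power series of L.  This
    is a diagnostic companion to :func:`inverse_lehmer` (the production
    inverse); it converges only for targets near ``L(s0)``.  When the
    series terms stop shrinking a :class:`SeriesDivergenceWarning` carrying
    the partial sum is emitted.
    """
    v = as_positive_values(x)
    _require_nondegenerate(v)
    if not (isinstance(K, (int, np.integer)) and K >= 1):
        raise ValueError("K must be a positive integer")
    logx = np.log(v)
    t0 = float(transform_many(logx, np.array([float(s0)]))[0])
    a = _taylor_coeffs(logx, float(s0), K)
    b = _reverse_series(a, K)
    w = t - t0
    terms = b[1:] * w ** np.arange(1, K + 1)
    result = float(s0 + terms.sum())
    mags = np.abs(terms)
    if K >= 3 and mags[-1] > 1e-12 and mags[-1] >= mags[-2] >= mags[-3]:
        warnings.warn(
            SeriesDivergenceWarning(
                f"Lagrange-Buermann terms are not decreasing at K={K}; "
                "target t is outside the empirical convergence region",
                partial_sum=result,
            )
        )
    return result


def windowed_transform(series, window: int, hop: int, s: float):
    """Sliding-window Lehmer transform of a (positive) series.

    One transform value per window position; output length is
    ``floor((len(series) - window) / hop) + 1``.  The series must already
    be positive (see :func:`suddency.signal.preprocess_to_positive`).
    """
    v = as_positive_values(series)
    if not (window >= 1 and hop >= 1):
        raise ValueError("window and hop must be positive integers")
    if window > v.size:
        raise DomainError(f"window {window} exceeds series length {v.size}")
    starts = np.arange(0, v.size - window + 1, hop)
    s = float(s)
    if s == np.inf:
        return np.array([v[i : i + window].max() for i in starts])
    if s == -np.inf:
        return np.array([v[i : i + window].min() for i in starts])
    out = np.empty(starts.size)
    for k, i in enumerate(starts):
        out[k] = float(transform_many(np.log(v[i : i + window]), np.array([s]))[0])
    return out


def pointwise_inverse_series(
    x, clip: float = 20.0, grid_points: int = 2001, newton_iters: int = 8
) -> np.ndarray:
    """Per-sample suddency moments: ``s_i = L^{-1}(x_i)`` for every sample.

    Extremal samples (whose exact inverse is +-inf) and any |s| beyond
    ``clip`` are clipped to ``+-clip``.  The inversion is vectorized: a
    monotone grid of L values seeds a Newton polish, which agrees with the
    per-sample root-finder :func:`inverse_lehmer` to ~1e-10 in the
    interior.
    """
    v = as_positive_values(x)
    _require_nondegenerate(v)
    if not clip > 0:
        raise ValueError("clip must be positive")
    logx = np.log(v)
    grid = np.linspace(-clip, clip, grid_points)
    Lg = transform_many(logx, grid)
    s = np.interp(v, Lg, grid)
    for _ in range(newton_iters):
        interior = (s > -clip) & (s < clip)
        if not np.any(interior):
            break
        Ls = transform_many(logx, s[interior])
        dLs = derivative_many(logx, s[interior])
        step = np.where(dLs > 1e-300, (Ls - v[interior]) / np.maximum(dLs, 1e-300), 0.0)
        s[interior] = np.clip(s[interior] - step, -clip, clip)
    return np.clip(s, -clip, clip)


def flag_anomalies(smoments, threshold: float) -> np.ndarray:
    """Boolean mask of samples whose |suddency moment| exceeds ``threshold``."""
    return np.abs(np.asarray(smoments, dtype=float)) > threshold
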