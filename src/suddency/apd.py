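"""Action potential distributions on the suddency-moment domain.

A signal rescaled so that its Lehmer transform satisfies

    L(-inf) = exp(W0(0)) = 1   and   L(+inf) = exp(W0(a*b) / (a*b))

(W0 the principal Lambert-W branch, a = alpha in (0, 1], b = beta > 0)
induces a two-parameter probability law on suddency moments, the action
potential distribution (APD), with density

    f(s) = (C / a) * (1 + a*b*L(s)) * exp(b*L(s)) * L(s)**(1/a - 1) * L'(s)

and closed-form distribution function

    F(s) = A + B * L(s)**(1/a) * exp(b*L(s)).

The normalization constants follow from the boundary conditions
F(-inf) = 0 and F(+inf) = 1, which force  B = C = 1 / (D - e**b)  with
D = exp(W0(ab)/(a**2 b) + b * exp(W0(ab)/(ab))),  and  A = -B * e**b.
(The additive constant must be negative for the lower limit to vanish;
see the regression test exercising the limits.)

The law models the suddency fingerprint of membrane action potentials:
alpha controls the shape exponent of the rising branch, beta the
exponential weighting of the transform level.  Fitting is by maximum
likelihood over (alpha, beta) on unconstrained transformed coordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .lehmer import pointwise_inverse_series, transform_many, transform_with_derivative
from .signal import DomainError, PositiveSignal, as_positive_values

__all__ = [
    "lambert_w0",
    "OMEGA",
    "membrane_voltage",
    "MembraneVoltageParams",
    "APDParams",
    "normalization_constants",
    "rescale_for_apd",
    "ActionPotentialDistribution",
    "fit_apd_mle",
    "ApdFit",
    "FitConvergenceError",
    "signal_to_smoments",
]

_INV_E = math.exp(-1.0)


def lambert_w0(z: float, tol: float = 1e-13, max_iter: int = 100) -> float:
    """Principal branch of the Lambert-W function by Halley root-finding.

    Solves ``w * exp(w) = z`` for ``w >= -1``, valid for ``z >= -1/e``.
    The residual ``|w e^w - z|`` of the returned root is below ``1e-12``.
    """
    z = float(z)
    if z < -_INV_E - 1e-15:
        raise DomainError(f"lambert_w0 requires z >= -1/e; got {z}")
    z = max(z, -_INV_E)
    if z == 0.0:
        return 0.0
    # initial guess: branch-point series near -1/e, else a log-based seed
    if z < -0.3:
        p = math.sqrt(2.0 * (math.e * z + 1.0))
        w = -1.0 + p - p * p / 3.0 + 11.0 / 72.0 * p**3
    elif z < 1.0:
        w = z / (1.0 + z)
    else:
        w = math.log(z)
        w -= math.log(max(w, 1e-10)) if w > 1 else 0.0
    for _ in range(max_iter):
        ew = math.exp(w)
        r = w * ew - z
        if abs(r) < tol * max(1.0, abs(z)):
            return w
        denom = ew * (w + 1.0) - (w + 2.0) * r / (2.0 * w + 2.0)
        w -= r / denom
    raise RuntimeError(f"lambert_w0 did not converge for z={z}")


#: the Omega constant, W0(1) ~ 0.5671
OMEGA = lambert_w0(1.0)


@dataclass(frozen=True)
class MembraneVoltageParams:
    """Constant ``c`` of the membrane voltage functional (enters as 1/(c*e))."""

    c: float

    def __post_init__(self):
        if self.c == 0:
            raise ValueError("c must be nonzero")


_BP1 = _INV_E
_BP2 = (math.e + 1.0) / math.e


def membrane_voltage(t: float, params: MembraneVoltageParams) -> float:
    """Piecewise membrane voltage V(t; c) built on the Lambert-W function.

    Branches: ``W0(t - 1/e) - 1/(c e)`` on (0, 1/e); ``t^2 e^t - 1/e`` on
    (1/e, (e+1)/e); ``t^2 e^{-t} - 1/e`` beyond.  The breakpoints are not
    part of any branch (the functional is defined on open intervals) and
    raise.
    """
    t = float(t)
    if not t > 0:
        raise DomainError("membrane voltage is defined for t > 0")
    if abs(t - _BP1) < 1e-12 or abs(t - _BP2) < 1e-12:
        raise DomainError(
            f"t={t} is a breakpoint of the membrane voltage functional (undefined)"
        )
    if t < _BP1:
        return lambert_w0(t - _INV_E) - 1.0 / (params.c * math.e)
    if t < _BP2:
        return t * t * math.exp(t) - _INV_E
    return t * t * math.exp(-t) - _INV_E


@dataclass(frozen=True)
class APDParams:
    """Shape parameters of the action potential distribution.

    ``alpha`` in (0, 1] (shape exponent), ``beta`` > 0 (exponential rate).
    """

    alpha: float
    beta: float

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1]; got {self.alpha}")
        if not (self.beta > 0.0):
            raise ValueError(f"beta must be positive; got {self.beta}")


def _lmax(params: APDParams) -> float:
    ab = params.alpha * params.beta
    return math.exp(lambert_w0(ab) / ab)


def normalization_constants(params: APDParams) -> tuple[float, float, float]:
    """Normalization constants (C, A, B) of the APD.

    ``C = B = 1 / (D - e**beta)`` with
    ``D = exp(W0(ab)/(a**2 b) + b * exp(W0(ab)/(ab)))``, and
    ``A = -C * e**beta`` so that the distribution function runs from 0 to 1.
    """
    a, b = params.alpha, params.beta
    ab = a * b
    w = lambert_w0(ab)
    try:
        D = math.exp(w / (a * a * b) + b * math.exp(w / ab))
        denom = D - math.exp(b)
    except OverflowError as exc:
        raise DomainError(f"normalization overflow at alpha={a}, beta={b}") from exc
    if not (np.isfinite(denom) and denom > 0):
        raise DomainError(f"invalid normalization denominator {denom} at alpha={a}, beta={b}")
    B = 1.0 / denom
    C = B
    A = -C * math.exp(b)
    return C, A, B


def rescale_for_apd(x, params: APDParams) -> PositiveSignal:
    """Affinely rescale a signal onto the APD boundary conditions.

    After rescaling, ``min = exp(W0(0)) = 1`` and
    ``max = exp(W0(ab)/(ab))`` (which lies in (1, e)), so the induced
    suddency-moment law is exactly the APD with the given parameters.
    """
    v = as_positive_values(x)
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        raise DomainError("constant signal cannot satisfy the APD boundary conditions")
    lmax = _lmax(params)
    scale = (lmax - 1.0) / (hi - lo)
    return PositiveSignal(1.0 + (v - lo) * scale)


class ActionPotentialDistribution:
    """The APD induced on suddency moments by a signal and (alpha, beta).

    The signal is rescaled internally to the boundary conditions; the
    density, distribution function, quantile function and sampler are all
    exposed vectorized over s.
    """

    def __init__(self, signal, params: APDParams):
        self.params = params
        self.signal = rescale_for_apd(signal, params)
        self._logx = np.log(self.signal.values)
        self.C, self.A, self.B = normalization_constants(params)
        self.lmax = _lmax(params)

    # -- density -------------------------------------------------------
    def logpdf(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        a, b = self.params.alpha, self.params.beta
        L, dL = transform_with_derivative(self._logx, s)
        with np.errstate(divide="ignore"):
            out = (
                math.log(self.C / a)
                + np.log1p(a * b * L)
                + b * L
                + (1.0 / a - 1.0) * np.log(L)
                + np.log(dL)
            )
        return out

    def pdf(self, s) -> np.ndarray:
        return np.exp(self.logpdf(s))

    # -- distribution function -----------------------------------------
    def cdf(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        a, b = self.params.alpha, self.params.beta
        L = transform_many(self._logx, s)
        F = self.A + self.B * L ** (1.0 / a) * np.exp(b * L)
        return np.clip(F, 0.0, 1.0)

    def ppf(self, u, tol: float = 1e-10) -> np.ndarray:
        """Quantile function by monotone grid inversion + Newton polish."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        if np.any((u <= 0) | (u >= 1)):
            raise DomainError("ppf requires u strictly inside (0, 1)")
        lo, hi = -20.0, 20.0
        while self.cdf(lo)[0] > min(u.min(), 1e-12) and lo > -500:
            lo *= 2.0
        while self.cdf(hi)[0] < max(u.max(), 1 - 1e-12) and hi < 500:
            hi *= 2.0
        grid = np.linspace(lo, hi, 4001)
        Fg = self.cdf(grid)
        # strictly increasing interpolation table
        keep = np.concatenate([[True], np.diff(Fg) > 0])
        s = np.interp(u, Fg[keep], grid[keep])
        for _ in range(6):
            f = self.pdf(s)
            F = self.cdf(s)
            step = np.where(f > 1e-300, (F - u) / np.maximum(f, 1e-300), 0.0)
            s = np.clip(s - step, lo, hi)
        return s

    def sample(self, n: int, seed=None) -> np.ndarray:
        """Inverse-CDF sampling; reproducible under a fixed seed."""
        if not n >= 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        u = rng.uniform(1e-12, 1.0 - 1e-12, size=n)
        return self.ppf(u)


def apd_pdf(s, dist: ActionPotentialDistribution) -> np.ndarray:
    """Functional alias for :meth:`ActionPotentialDistribution.pdf`."""
    return dist.pdf(s)


def apd_cdf(s, dist: ActionPotentialDistribution) -> np.ndarray:
    """Functional alias for :meth:`ActionPotentialDistribution.cdf`."""
    return dist.cdf(s)


def apd_sample(dist: ActionPotentialDistribution, n: int, seed=None) -> np.ndarray:
    """Functional alias for :meth:`ActionPotentialDistribution.sample`."""
    return dist.sample(n, seed)


class FitConvergenceError(RuntimeError):
    """MLE optimizer failed; ``best_fit`` carries the best point found."""

    def __init__(self, message, best_fit):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass(frozen=True)
class ApdFit:
    """Result of a maximum-likelihood APD fit."""

    params: APDParams
    loglik: float
    n_obs: int
    converged: bool

    def __iter__(self):  # allows ``params, loglik = fit``
        return iter((self.params, self.loglik))


def _expit(u):
    return 1.0 / (1.0 + np.exp(-u))


def fit_apd_mle(
    observations,
    x,
    init: APDParams = APDParams(0.5, 1.0),
    n_starts: int = 3,
    seed: int = 0,
    maxiter: int = 400,
    min_obs: int = 10,
) -> ApdFit:
    """Maximum-likelihood fit of (alpha, beta) to suddency-moment observations.

    The likelihood is the APD density on the signal ``x``; because the APD
    boundary conditions depend on the parameters, the signal is re-rescaled
    at every candidate point.  Optimization is derivative-free
    (Nelder-Mead) on unconstrained coordinates (logit(alpha), log(beta))
    with seeded multistart.

    Raises
    ------
    ValueError
        Fewer than ``min_obs`` finite observations.
    FitConvergenceError
        If no start converges and the best point does not improve on the
        initial parameters.
    """
    obs = np.asarray(observations, dtype=float).ravel()
    obs = obs[np.isfinite(obs)]
    if obs.size < min_obs:
        raise ValueError(f"need at least {min_obs} finite observations; got {obs.size}")
    base = as_positive_values(x)
    if np.unique(base).size < 2:
        raise DomainError("degenerate signal: needs at least two distinct values")

    def nll(u):
        a = float(_expit(u[0]))
        b = float(np.exp(u[1]))
        if not (1e-6 < a <= 1.0) or not (1e-8 < b < 1e6):
            return 1e10
        try:
            dist = ActionPotentialDistribution(base, APDParams(a, b))
        except DomainError:
            return 1e10
        lp = dist.logpdf(obs)
        if not np.all(np.isfinite(lp)):
            return 1e10
        return -float(lp.mean())

    def to_u(p: APDParams):
        a = min(p.alpha, 1.0 - 1e-9)
        return np.array([math.log(a / (1.0 - a)), math.log(p.beta)])

    rng = np.random.default_rng(seed)
    starts = [to_u(init)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(to_u(init) + rng.normal(0.0, 0.7, size=2))

    best = None
    any_converged = False
    for u0 in starts:
        res = minimize(nll, u0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-9})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    a = float(_expit(best.x[0]))
    b = float(np.exp(best.x[1]))
    fit = ApdFit(
        params=APDParams(min(a, 1.0), b),
        loglik=-best.fun * obs.size,
        n_obs=obs.size,
        converged=any_converged,
    )
    nll_init = nll(to_u(init))
    if not any_converged and best.fun > nll_init:
        raise FitConvergenceError("APD MLE failed to improve on the initial point", fit)
    if not any_converged:
        warnings.warn("APD MLE reached the iteration limit without formal convergence")
    return fit


def signal_to_smoments(x, clip: float = 20.0) -> np.ndarray:
    """Pointwise suddency moments of a signal (the MLE observations).

    ``s_i = L^{-1}(x_i)`` for every sample, with extremal samples clipped
    to ``+-clip``; delegates to
    :func:`suddency.lehmer.pointwise_inverse_series`.
    """
    return pointwise_inverse_series(x, clip=clip)
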