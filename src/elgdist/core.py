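"""Exponentiated Lindley geometric (ELG) distribution.

Closed-form distribution functions and exact inverse-CDF sampling for the
three-parameter lifetime law obtained by compounding an exponentiated
Lindley component law with a geometric system count:

    F(x) = G(x)^alpha / (1 - p + p * G(x)^alpha),   x > 0,

where ``G`` is the Lindley(theta) CDF.  The family is well defined for any
``p < 1`` (negative values included); ``alpha = 1`` gives the
Lindley-geometric (LG) law and ``alpha = 1, p = 0`` the plain Lindley law.

All distribution functions accept scalars or array-likes and broadcast over
``x``.  Quantiles are evaluated through the negative branch of the Lambert W
function, which makes inverse-transform sampling exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "ELGParams",
    "Sample",
    "lindley_cdf",
    "elg_cdf",
    "elg_pdf",
    "elg_logpdf",
    "elg_sf",
    "elg_hazard",
    "lambert_w_m1",
    "elg_quantile",
    "elg_rvs",
]

_BRANCH_POINT = -np.exp(-1.0)


@dataclass(frozen=True)
class ELGParams:
    """Parameter triple (alpha, theta, p) of the ELG distribution.

    Parameters
    ----------
    alpha : float
        Exponent (number of parallel components per system), ``alpha > 0``.
    theta : float
        Lindley rate, ``theta > 0``.
    p : float
        Geometric compounding parameter, ``p < 1``.  Negative values are
        admitted; the density remains proper on the whole half-line
        ``p < 1``.
    """

    alpha: float
    theta: float
    p: float

    def __post_init__(self) -> None:
        a, t, p = float(self.alpha), float(self.theta), float(self.p)
        if not (np.isfinite(a) and a > 0.0):
            raise ValueError(f"alpha must be a positive finite real, got {self.alpha!r}")
        if not (np.isfinite(t) and t > 0.0):
            raise ValueError(f"theta must be a positive finite real, got {self.theta!r}")
        if not (np.isfinite(p) and p < 1.0):
            raise ValueError(f"p must be a finite real < 1, got {self.p!r}")
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "theta", t)
        object.__setattr__(self, "p", p)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.theta, self.p)


@dataclass(frozen=True)
class Sample:
    """An i.i.d. sample of positive observation times."""

    times: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.times, dtype=float))
        if t.ndim != 1 or t.size < 1:
            raise ValueError("Sample requires a one-dimensional, non-empty array of times")
        if not np.all(np.isfinite(t)) or np.any(t <= 0.0):
            raise ValueError("all observation times must be positive finite reals")
        object.__setattr__(self, "times", t)

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def sorted_times(self) -> np.ndarray:
        return np.sort(self.times)

    def __len__(self) -> int:
        return self.n


def _check_theta(theta: float) -> float:
    theta = float(theta)
    if not (np.isfinite(theta) and theta > 0.0):
        raise ValueError(f"theta must be positive, got {theta!r}")
    return theta


def _log_lindley_sf(x, theta):
    """log(1 - G(x)) for the Lindley CDF, stable for all x >= 0.

    1 - G = (1 + theta*x/(theta+1)) * exp(-theta*x), so the log is
    log1p(theta*x/(theta+1)) - theta*x with no cancellation.
    """
    x = np.asarray(x, dtype=float)
    return np.log1p(theta * x / (theta + 1.0)) - theta * x


def _log_lindley_cdf(x, theta):
    """log G(x), stable both near x=0 (G ~ theta^2 x/(theta+1)) and x→∞."""
    lsf = _log_lindley_sf(x, theta)
    # G = -expm1(lsf); switch between the two exact forms at G = 1/2.
    with np.errstate(divide="ignore"):
        small = np.log(-np.expm1(np.minimum(lsf, -0.0)))  # accurate for G small
        large = np.log1p(-np.exp(lsf))  # accurate for G near 1
    return np.where(lsf > -np.log(2.0), small, large)


def lindley_cdf(x, theta: float):
    """CDF of the Lindley(theta) distribution.

    ``G(x) = 1 - (theta + 1 + theta*x)/(theta + 1) * exp(-theta*x)`` for
    ``x >= 0`` and 0 for ``x < 0``.
    """
    theta = _check_theta(theta)
    x = np.asarray(x, dtype=float)
    out = -np.expm1(_log_lindley_sf(np.maximum(x, 0.0), theta))
    out = np.where(x <= 0.0, 0.0, out)
    return out if out.ndim else float(out)

def _log_denominator(log_ga, p):
    """log(1 - p + p*G^alpha) = log1p(p * expm1(alpha*log G)), stable."""
    return np.log1p(p * np.expm1(log_ga))


def elg_cdf(x, params: ELGParams):
    """ELG cumulative distribution function ``G^alpha/(1-p+p G^alpha)``."""
    a, t, p = params.as_tuple()
    x = np.asarray(x, dtype=float)
    log_ga = a * _log_lindley_cdf(np.maximum(x, 0.0), t)
    out = np.exp(log_ga - _log_denominator(log_ga, p))
    out = np.where(x <= 0.0, 0.0, out)
    return out if out.ndim else float(out)


def elg_sf(x, params: ELGParams):
    """Survival function ``S = (1-p)(1-G^alpha)/(1-p+p G^alpha)``."""
    a, t, p = params.as_tuple()
    x = np.asarray(x, dtype=float)
    log_ga = a * _log_lindley_cdf(np.maximum(x, 0.0), t)
    one_m_ga = -np.expm1(log_ga)
    out = (1.0 - p) * one_m_ga / (1.0 - p * one_m_ga)
    out = np.where(x <= 0.0, 1.0, out)
    return out if out.ndim else float(out)


def elg_logpdf(x, params: ELGParams):
    """Log-density, evaluated in log space.

    Stable down to denormal ``x`` (the density behaves like
    ``c * x**(alpha-1)`` near the origin) and far into the right tail.
    Returns ``-inf`` for ``x <= 0``.
    """
    a, t, p = params.as_tuple()
    x = np.asarray(x, dtype=float)
    xs = np.where(x > 0.0, x, 1.0)  # placeholder, masked below
    log_g = _log_lindley_cdf(xs, t)
    log_den = _log_denominator(a * log_g, p)
    out = (
        np.log(a)
        + 2.0 * np.log(t)
        - np.log(t + 1.0)
        + np.log1p(-p)
        + np.log1p(xs)
        - t * xs
        + (a - 1.0) * log_g
        - 2.0 * log_den
    )
    out = np.where(x > 0.0, out, -np.inf)
    return out if out.ndim else float(out)


def elg_pdf(x, params: ELGParams):
    """ELG density; 0 for ``x <= 0`` by the support convention."""
    out = np.exp(elg_logpdf(x, params))
    return out if np.ndim(out) else float(out)


def elg_hazard(x, params: ELGParams):
    """Hazard rate ``h = f/S`` computed from the log forms.

    The initial value behaves like ``c * x**(alpha-1)``: infinite at 0+ for
    ``alpha < 1``, equal to ``theta^2/((theta+1)(1-p))`` for ``alpha = 1``
    and 0 for ``alpha > 1``.
    """
    a, t, p = params.as_tuple()
    x = np.asarray(x, dtype=float)
    xs = np.where(x > 0.0, x, 1.0)
    log_g = _log_lindley_cdf(xs, t)
    log_ga = a * log_g
    log_den = _log_denominator(log_ga, p)
    with np.errstate(divide="ignore"):
        log_sf = np.log1p(-p) + np.log(-np.expm1(log_ga)) - log_den
    log_h = elg_logpdf(xs, params) - log_sf
    out = np.where(x > 0.0, np.exp(log_h), 0.0)
    return out if out.ndim else float(out)


def lambert_w_m1(z):
    """Negative branch W_{-1} of the Lambert W function on [-1/e, 0).

    Returns the solution ``w <= -1`` of ``w * exp(w) = z``.  Backed by
    :func:`scipy.special.lambertw` and polished with a Halley step so that
    ``|w exp(w) - z| < 1e-12``.
    """
    z = np.asarray(z, dtype=float)
    if np.any(z >= 0.0) or np.any(z < _BRANCH_POINT * (1.0 + 1e-12)):
        raise ValueError("lambert_w_m1 requires z in [-1/e, 0)")
    zc = np.maximum(z, _BRANCH_POINT)
    with np.errstate(invalid="ignore"):
        w = special.lambertw(zc, k=-1).real
    # Near the branch point the direct evaluation is ill-conditioned (w e^w
    # is quadratically flat).  Substitute w = -1 - sigma and solve
    # (1 + sigma) e^{-sigma} = -e z  by Newton in sigma, which has a simple,
    # well-separated root sigma ~ sqrt(2 eps) with eps = 1 + e z.
    eps = np.maximum(1.0 + np.e * zc, 0.0)
    near = eps < 1e-4
    if np.any(near):
        target = eps
        sigma = np.sqrt(2.0 * np.maximum(target, 0.0))
        for _ in range(6):
            es = np.exp(-sigma)
            h = (1.0 + sigma) * es - (1.0 - target)
            dh = -sigma * es
            step = np.where(np.abs(dh) > 0.0, h / np.where(dh == 0.0, 1.0, dh), 0.0)
            sigma = np.maximum(sigma - step, 0.0)
        w = np.where(near, -1.0 - sigma, w)
    # Halley cleanup away from the branch point.
    for _ in range(3):
        ew = np.exp(w)
        f = w * ew - zc
        wp1 = w + 1.0
        denom = ew * wp1 - (w + 2.0) * f / (2.0 * np.where(wp1 == 0.0, 1.0, wp1))
        step = np.where(
            near | (np.abs(denom) == 0.0), 0.0, f / np.where(denom == 0.0, 1.0, denom)
        )
        w = w - step
    w = np.minimum(w, -1.0)
    return w if w.ndim else float(w)


def _quantile_raw(u, params: ELGParams):
    a, t, p = params.as_tuple()
    u = np.asarray(u, dtype=float)
    # G(x) = v with log v = (log u + log(1-p) - log(1-u p))/alpha
    log_v = (np.log(u) + np.log1p(-p) - np.log1p(-u * p)) / a
    one_m_v = -np.expm1(log_v)
    z = np.maximum(-(t + 1.0) * np.exp(-(t + 1.0)) * one_m_v, _BRANCH_POINT)
    x = -1.0 - 1.0 / t - lambert_w_m1(z) / t
    # Deep lower tail: x ~ v (theta+1)/theta^2 is lost to cancellation in the
    # closed form; invert the Lindley CDF directly by Newton (G is computed
    # stably down to denormal x).
    tiny = log_v < np.log(1e-6)
    if np.any(tiny):
        v = np.exp(log_v)
        xt = v * (t + 1.0) / t**2
        for _ in range(4):
            g = -np.expm1(_log_lindley_sf(xt, t))
            dg = t**2 * (1.0 + xt) * np.exp(-t * xt) / (t + 1.0)
            xt = np.maximum(xt - (g - v) / dg, xt * 0.25)
        x = np.where(tiny, xt, x)
    return x


def elg_quantile(u, params: ELGParams):
    """Exact quantile function via the Lambert W_{-1} branch.

    The Lambert argument ``-(theta+1) e^{-(theta+1)} (1 - v)`` with
    ``v = [u(1-p)/(1-up)]^{1/alpha}`` always lies in (-1/e, 0), so the
    branch value is unique.  Near the branch point the closed form loses
    digits and the result is polished by monotone Newton/bisection on
    ``F(x) = u`` to |F(q) - u| <= 1e-10.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(~np.isfinite(u_arr)) or np.any(u_arr <= 0.0) or np.any(u_arr >= 1.0):
        raise ValueError("u must lie strictly inside (0, 1)")
    x = np.atleast_1d(_quantile_raw(u_arr, params))
    uu = np.atleast_1d(u_arr)
    x = np.maximum(x, np.finfo(float).tiny)
    # Newton polish on the CDF; the closed form already gives ~1e-14 except
    # very near the branch point, so this converges in one or two steps.
    for _ in range(4):
        err = np.atleast_1d(elg_cdf(x, params)) - uu
        bad = np.abs(err) > 1e-12
        if not np.any(bad):
            break
        f = np.atleast_1d(elg_pdf(x, params))
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(bad & (f > 0.0), err / np.where(f > 0.0, f, 1.0), 0.0)
        x = np.maximum(x - step, x * 0.5)
    # Bracketed fallback for any stragglers.
    err = np.abs(np.atleast_1d(elg_cdf(x, params)) - uu)
    for i in np.flatnonzero(err > 1e-10):
        lo, hi = 0.0, max(2.0 * x[i], 1.0)
        while elg_cdf(hi, params) < uu[i]:
            hi *= 4.0
        x[i] = optimize.brentq(
            lambda s: elg_cdf(s, params) - uu[i], lo, hi, xtol=1e-14, rtol=8.9e-16
        )
    return x if np.ndim(u_arr) else float(x[0])


def elg_rvs(n: int, params: ELGParams, seed=None, rng=None) -> Sample:
    """Draw ``n`` i.i.d. variates by inverse-transform sampling.

    A single integer ``seed`` fully determines the output: the uniform
    stream is drawn once, in order, from ``numpy.random.default_rng(seed)``.
    An explicit ``rng`` may be passed instead.
    """
    n = int(n)
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    u = rng.random(n)
    tiny = np.finfo(float).tiny
    u = np.clip(u, tiny, 1.0 - 1e-16)
    return Sample(elg_quantile(u, params))
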