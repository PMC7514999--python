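"""Likelihood-based estimation for the ELG distribution.

Direct maximum likelihood (multi-start quasi-Newton on a transformed
parameter space), an EM algorithm exploiting the latent geometric system
count, observed Fisher information with Wald intervals, likelihood-ratio
tests against nested submodels, and a multicensored likelihood.

The internal optimisation parameterisation is ``(log alpha, log theta,
eta)`` with ``p = 1 - exp(-eta)``, which maps the unconstrained
``eta in R`` onto exactly the admissible domain ``p < 1`` (negative ``p``
included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core import ELGParams, Sample, elg_cdf, elg_logpdf, elg_sf

__all__ = [
    "FitResult",
    "CensoredSample",
    "LRTestResult",
    "elg_loglik",
    "elg_score",
    "fit_mle",
    "fit_em",
    "observed_information",
    "wald_intervals",
    "lr_test",
    "censored_loglik",
    "fit_mle_censored",
]


@dataclass(frozen=True)
class FitResult:
    """Estimates with likelihood value, covariance and convergence metadata."""

    params_hat: ELGParams
    loglik: float
    vcov: np.ndarray | None
    se: np.ndarray | None
    n_iter: int
    converged: bool
    method: str
    message: str = ""
    n_obs: int = 0

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik

    @property
    def k(self) -> int:
        return 3

    def summary(self) -> dict:
        a, t, p = self.params_hat.as_tuple()
        out = {
            "alpha": a,
            "theta": t,
            "p": p,
            "loglik": self.loglik,
            "method": self.method,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        if self.se is not None:
            out["se"] = list(map(float, self.se))
        return out


@dataclass(frozen=True)
class CensoredSample:
    """Multicensored data: exact, interval-bracketed and right-censored records.

    ``n = n0 + n1 + n2`` with ``n0`` exact failure times, ``n1`` failures
    known only to lie in ``(left_i, right_i]`` and ``n2`` right-censored
    survival times.
    """

    exact: np.ndarray = field(default_factory=lambda: np.empty(0))
    intervals: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    right_censored: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        exact = np.atleast_1d(np.asarray(self.exact, dtype=float))
        ivals = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        rc = np.atleast_1d(np.asarray(self.right_censored, dtype=float))
        if exact.size and (np.any(exact <= 0) or not np.all(np.isfinite(exact))):
            raise ValueError("exact times must be positive finite reals")
        if rc.size and (np.any(rc <= 0) or not np.all(np.isfinite(rc))):
            raise ValueError("right-censoring times must be positive finite reals")
        if ivals.size:
            if np.any(ivals <= 0) or not np.all(np.isfinite(ivals)):
                raise ValueError("interval endpoints must be positive finite reals")
            if np.any(ivals[:, 0] >= ivals[:, 1]):
                raise ValueError("interval records require left < right")
        if exact.size + ivals.shape[0] + rc.size < 1:
            raise ValueError("censored sample must contain at least one record")
        object.__setattr__(self, "exact", exact)
        object.__setattr__(self, "intervals", ivals)
        object.__setattr__(self, "right_censored", rc)

    @property
    def n(self) -> int:
        return int(self.exact.size + self.intervals.shape[0] + self.right_censored.size)


@dataclass(frozen=True)
class LRTestResult:
    omega: float
    df: int
    p_value: float
    full: FitResult
    restricted: FitResult


def _as_times(data) -> np.ndarray:
    if isinstance(data, Sample):
        return data.times
    return Sample(np.asarray(data, dtype=float)).times


def elg_loglik(data, params: ELGParams | tuple) -> float:
    """Log-likelihood of an uncensored sample.

    Invalid parameter values return ``-inf`` (a sentinel, not an exception)
    so optimisers may probe outside the domain.
    """
    x = _as_times(data)
    if not isinstance(params, ELGParams):
        try:
            params = ELGParams(*params)
        except ValueError:
            return -np.inf
    ll = float(np.sum(elg_logpdf(x, params)))
    return ll if np.isfinite(ll) else -np.inf


def _tau_terms(x, alpha, theta):
    """tau_i = Lindley CDF at x_i, with log tau and d tau/d theta.

    Works for real or complex ``alpha``/``theta`` so the score admits
    complex-step differentiation.
    """
    u = theta * x / (theta + 1.0)
    log_sf = np.log1p(u) - theta * x
    tau = -np.expm1(log_sf)
    log_tau = np.where(
        np.real(log_sf) > -np.log(2.0),
        np.log(-np.expm1(log_sf)),
        np.log1p(-np.exp(log_sf)),
    )
    dtau_dtheta = theta * x * (2.0 + theta + theta * x + x) * np.exp(-theta * x) / (theta + 1.0) ** 2
    return tau, log_tau, dtau_dtheta


def _score_impl(x, alpha, theta, p):
    n = x.size
    tau, log_tau, dtau = _tau_terms(x, alpha, theta)
    tau_a = np.exp(alpha * log_tau)
    den = 1.0 - p + p * tau_a
    d_alpha = n / alpha + np.sum(log_tau) - 2.0 * p * np.sum(tau_a * log_tau / den)
    d_theta = (
        2.0 * n / theta
        - n / (theta + 1.0)
        - np.sum(x)
        + (alpha - 1.0) * np.sum(dtau / tau)
        - 2.0 * alpha * p * np.sum(np.exp((alpha - 1.0) * log_tau) * dtau / den)
    )
    d_p = -n / (1.0 - p) + 2.0 * np.sum((1.0 - tau_a) / den)
    return np.array([d_alpha, d_theta, d_p])


def elg_score(data, params: ELGParams) -> np.ndarray:
    """Analytic score vector ``(dl/dalpha, dl/dtheta, dl/dp)``."""
    x = _as_times(data)
    a, t, p = params.as_tuple()
    return _score_impl(x, a, t, p).astype(float)


def observed_information(data, params: ELGParams) -> np.ndarray:
    """Observed Fisher information (negated Hessian of the log-likelihood).

    Evaluated by complex-step differentiation of the analytic score, which
    is exact to machine precision (the score is holomorphic in each
    parameter); the matrix is symmetrised.
    """
    x = _as_times(data)
    a, t, p = params.as_tuple()
    h = 1e-200
    hess = np.empty((3, 3))
    base = np.array([a, t, p], dtype=complex)
    for j in range(3):
        pt = base.copy()
        pt[j] += 1j * h
        hess[:, j] = np.imag(_score_impl(x, *pt)) / h
    info = -0.5 * (hess + hess.T)
    return info


# ---------------------------------------------------------------------------
# Direct maximum likelihood
# ---------------------------------------------------------------------------


def _to_internal(alpha, theta, p):
    return np.array([np.log(alpha), np.log(theta), -np.log1p(-p)])


def _from_internal(psi):
    return np.exp(psi[0]), np.exp(psi[1]), -np.expm1(-psi[2])


def _neg_loglik_grad(psi, x):
    a, t, p = _from_internal(psi)
    if not np.isfinite(a) or not np.isfinite(t) or a <= 0 or t <= 0 or p >= 1.0:
        return np.inf, np.zeros(3)
    try:
        params = ELGParams(a, t, p)
    except ValueError:
        return np.inf, np.zeros(3)
    ll = float(np.sum(elg_logpdf(x, params)))
    if not np.isfinite(ll):
        return np.inf, np.zeros(3)
    g = _score_impl(x, a, t, p)
    # chain rule to (log alpha, log theta, eta) with dp/deta = exp(-eta) = 1-p
    grad = np.array([g[0] * a, g[1] * t, g[2] * (1.0 - p)])
    return -ll, -grad


def _default_starts(x):
    theta0 = 2.0 / float(np.mean(x))
    starts = []
    for a0 in (0.5, 1.0, 2.0):
        for p0 in (-0.5, 0.0, 0.5, 0.9):
            starts.append((a0, theta0, p0))
    return starts


def _minimize_free(x, start, fixed: dict | None, gtol=1e-8):
    """Minimise the negative log-likelihood over the non-fixed coordinates."""
    fixed = fixed or {}
    names = ("alpha", "theta", "p")
    free_idx = [i for i, nm in enumerate(names) if nm not in fixed]
    full0 = list(start)
    for i, nm in enumerate(names):
        if nm in fixed:
            full0[i] = fixed[nm]
    psi_full0 = _to_internal(*full0)

    def embed(psi_free):
        psi = psi_full0.copy()
        psi[free_idx] = psi_free
        return psi

    def fun(psi_free):
        f, g = _neg_loglik_grad(embed(psi_free), x)
        return f, g[free_idx]

    if not free_idx:  # fully pinned model: nothing to optimise
        f, _ = _neg_loglik_grad(psi_full0, x)
        a, t, p = _from_internal(psi_full0)
        res = optimize.OptimizeResult(
            x=np.empty(0), fun=f, nit=0, success=True, message="all parameters fixed"
        )
        return res, ELGParams(a, t, p)

    res = optimize.minimize(
        fun,
        psi_full0[free_idx],
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-14, "gtol": gtol},
    )
    psi_hat = embed(res.x)
    a, t, p = _from_internal(psi_hat)
    return res, ELGParams(a, t, p)


def fit_mle(
    data,
    init: ELGParams | None = None,
    fixed: dict | None = None,
    compute_vcov: bool = True,
) -> FitResult:
    """Direct MLE by multi-start quasi-Newton with the analytic gradient.

    ``fixed`` pins a subset of {"alpha", "theta", "p"} to given values
    (used for the LG and Lindley submodels and by the LR test).  With
    ``init`` supplied, only that start is used.
    """
    x = _as_times(data)
    fixed = dict(fixed or {})
    starts = [init.as_tuple()] if init is not None else _default_starts(x)

    best = None
    best_res = None
    n_fail = 0
    for s in starts:
        try:
            res, params = _minimize_free(x, s, fixed)
        except (ValueError, FloatingPointError, OverflowError):
            n_fail += 1
            continue
        if not np.isfinite(res.fun):
            n_fail += 1
            continue
        if best is None or res.fun < best_res.fun - 1e-9 or (
            abs(res.fun - best_res.fun) < 1e-6
            and np.linalg.norm(params.as_tuple()) < np.linalg.norm(best.as_tuple())
        ):
            best, best_res = params, res
    if best is None:
        raise RuntimeError(f"all {len(starts)} optimisation starts failed")

    loglik = -float(best_res.fun)
    vcov = se = None
    message = str(best_res.message)
    if compute_vcov and not fixed:
        info = observed_information(x, best)
        try:
            eigvals = np.linalg.eigvalsh(info)
            if np.all(eigvals > 0):
                vcov = np.linalg.inv(info)
                se = np.sqrt(np.diag(vcov))
            else:
                message += "; information matrix not positive definite, SEs unavailable"
        except np.linalg.LinAlgError:
            message += "; information matrix inversion failed"
    if best.p > 1.0 - 1e-8 or best.alpha < 1e-6:
        message += "; estimate at the boundary of the parameter domain"
    return FitResult(
        params_hat=best,
        loglik=loglik,
        vcov=vcov,
        se=se,
        n_iter=int(best_res.nit),
        converged=bool(best_res.success),
        method="direct",
        message=message,
        n_obs=x.size,
    )


# ---------------------------------------------------------------------------
# EM algorithm
# ---------------------------------------------------------------------------


def _em_z(x, alpha, theta, p):
    """Conditional expectation of the latent geometric count given the data.

    With q_i = p * (1 - tau_i^alpha), the conditional law of Z_i is
    z * q_i^(z-1) * (1-q_i)^2, whose mean is (1+q_i)/(1-q_i).  (The naive
    weight 1/(1-q_i) breaks the EM ascent property; the posterior mean
    leaves the MLE as the exact fixed point of the iteration.)
    """
    _, log_tau, _ = _tau_terms(x, alpha, theta)
    q = -p * np.expm1(alpha * log_tau)
    return (1.0 + q) / (1.0 - q)


def _em_mstep_alpha_theta(x, z, alpha0, theta0):
    """Maximise the complete-data log-likelihood over (alpha, theta).

    Solves the pair of stationarity equations of the pseudo log-likelihood
    (with the latent counts replaced by their conditional expectations) by
    quasi-Newton on (log alpha, log theta); the two routes coincide because
    the objective is smooth and the solution interior.
    """
    n = x.size
    sum_x = np.sum(x)
    zm1 = z - 1.0

    def neg_q(v):
        a, t = np.exp(v)
        tau, log_tau, dtau = _tau_terms(x, a, t)
        one_m_tau_a = -np.expm1(a * log_tau)
        if np.any(one_m_tau_a <= 0.0):
            return np.inf, np.zeros(2)
        q = (
            n * np.log(a)
            + 2.0 * n * np.log(t)
            - n * np.log(t + 1.0)
            - t * sum_x
            + (a - 1.0) * np.sum(log_tau)
            + np.sum(zm1 * np.log(one_m_tau_a))
        )
        tau_a = np.exp(a * log_tau)
        d_a = n / a + np.sum(log_tau) - np.sum(zm1 * tau_a * log_tau / one_m_tau_a)
        d_t = (
            2.0 * n / t
            - n / (t + 1.0)
            - sum_x
            + (a - 1.0) * np.sum(dtau / tau)
            - a * np.sum(zm1 * np.exp((a - 1.0) * log_tau) * dtau / one_m_tau_a)
        )
        if not np.isfinite(q):
            return np.inf, np.zeros(2)
        return -q, -np.array([d_a * a, d_t * t])

    res = optimize.minimize(
        neg_q,
        np.log([alpha0, theta0]),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 200, "ftol": 1e-15, "gtol": 1e-10},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError("EM M-step failed: " + str(res.message))
    a, t = np.exp(res.x)
    return float(a), float(t)


def fit_em(
    data,
    init: ELGParams | None = None,
    max_iter: int = 2000,
    tol: float = 1e-7,
    compute_vcov: bool = True,
) -> FitResult:
    """EM algorithm treating the geometric system count as missing data.

    Requires ``0 < p < 1`` (the latent-count construction is only
    meaningful for a proper geometric distribution); use :func:`fit_mle`
    for ``p <= 0``.  The observed-data log-likelihood is checked to be
    nondecreasing at every iteration.
    """
    x = _as_times(data)
    if init is None:
        init = ELGParams(1.0, 2.0 / float(np.mean(x)), 0.5)
    a, t, p = init.as_tuple()
    if not (0.0 < p < 1.0):
        raise ValueError("fit_em requires 0 < p < 1; use fit_mle for p <= 0")

    n = x.size

    def em_step(a, t, p):
        z = _em_z(x, a, t, p)
        a_new, t_new = _em_mstep_alpha_theta(x, z, a, t)
        p_new = 1.0 - n / float(np.sum(z))
        return a_new, t_new, min(max(p_new, 1e-12), 1.0 - 1e-12)

    def to_psi(v):
        a, t, p = v
        return np.array([np.log(a), np.log(t), np.log(p / (1.0 - p))])

    def from_psi(psi):
        return (np.exp(psi[0]), np.exp(psi[1]), 1.0 / (1.0 + np.exp(-psi[2])))

    ll = elg_loglik(x, ELGParams(a, t, p))
    n_iter = 0
    converged = False
    # SQUAREM-accelerated EM: each cycle takes two EM steps and attempts a
    # quadratic extrapolation in unconstrained coordinates; the extrapolated
    # point is kept only if it does not decrease the observed-data
    # log-likelihood, so the ascent property of plain EM is preserved.
    while n_iter < max_iter:
        v0 = (a, t, p)
        v1 = em_step(*v0)
        v2 = em_step(*v1)
        n_iter += 2
        psi0, psi1, psi2 = to_psi(v0), to_psi(v1), to_psi(v2)
        r = psi1 - psi0
        v = (psi2 - psi1) - r
        cand = v2
        nv = float(np.linalg.norm(v))
        if nv > 0.0:
            step = -float(np.linalg.norm(r)) / nv
            psi_x = psi0 - 2.0 * step * r + step**2 * v
            try:
                vx = em_step(*from_psi(psi_x))  # stabilising EM step
                n_iter += 1
                if elg_loglik(x, ELGParams(*vx)) >= elg_loglik(x, ELGParams(*v2)):
                    cand = vx
            except (RuntimeError, ValueError, FloatingPointError, OverflowError):
                pass
        ll_new = elg_loglik(x, ELGParams(*cand))
        if ll_new < ll - 1e-8:
            raise RuntimeError(
                f"EM ascent violated at iteration {n_iter}: {ll:.10f} -> {ll_new:.10f}"
            )
        delta = max(abs(c - o) for c, o in zip(cand, (a, t, p)))
        a, t, p = cand
        ll = ll_new
        if delta < tol:
            converged = True
            break

    params = ELGParams(a, t, p)
    vcov = se = None
    message = ""
    if compute_vcov:
        info = observed_information(x, params)
        try:
            if np.all(np.linalg.eigvalsh(info) > 0):
                vcov = np.linalg.inv(info)
                se = np.sqrt(np.diag(vcov))
            else:
                message = "information matrix not positive definite, SEs unavailable"
        except np.linalg.LinAlgError:
            message = "information matrix inversion failed"
    return FitResult(
        params_hat=params,
        loglik=float(ll),
        vcov=vcov,
        se=se,
        n_iter=n_iter,
        converged=converged,
        method="em",
        message=message,
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def wald_intervals(fit: FitResult, level: float = 0.95) -> dict[str, tuple[float, float]]:
    """Asymptotic-normal confidence intervals ``estimate +/- z * SE``."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if fit.se is None:
        raise ValueError("fit has no standard errors (vcov unavailable)")
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    a, t, p = fit.params_hat.as_tuple()
    out = {}
    for name, est, se in zip(("alpha", "theta", "p"), (a, t, p), fit.se):
        out[name] = (est - zcrit * se, est + zcrit * se)
    return out


_NULL_SPECS = {"lg": {"alpha": 1.0}, "lindley": {"alpha": 1.0, "p": 0.0}}


def lr_test(data, null_spec: dict | str) -> LRTestResult:
    """Likelihood-ratio test of a fixed-parameter restriction of the ELG law.

    ``null_spec`` is either a dict such as ``{"alpha": 1.0}`` or one of the
    shortcuts ``"lg"`` (alpha = 1) and ``"lindley"`` (alpha = 1, p = 0).
    """
    if isinstance(null_spec, str):
        try:
            null_spec = _NULL_SPECS[null_spec.lower()]
        except KeyError:
            raise ValueError(f"unknown null specification {null_spec!r}") from None
    if not null_spec or not set(null_spec) <= {"alpha", "theta", "p"}:
        raise ValueError("null_spec must restrict a nonempty subset of alpha/theta/p")
    full = fit_mle(data, compute_vcov=False)
    restricted = fit_mle(data, fixed=null_spec, compute_vcov=False)
    omega = 2.0 * (full.loglik - restricted.loglik)
    if omega < -1e-6:
        raise RuntimeError(f"negative LR statistic {omega}; restricted fit beat the full fit")
    omega = max(omega, 0.0)
    df = len(null_spec)
    return LRTestResult(
        omega=float(omega),
        df=df,
        p_value=float(stats.chi2.sf(omega, df)),
        full=full,
        restricted=restricted,
    )


# ---------------------------------------------------------------------------
# Multicensored likelihood
# ---------------------------------------------------------------------------


def censored_loglik(data: CensoredSample, params: ELGParams | tuple) -> float:
    """Log-likelihood for multicensored data.

    Exact records contribute ``log f``, interval records
    ``log[F(right) - F(left)]`` and right-censored records ``log S``.
    With no censoring this reduces exactly to :func:`elg_loglik`.
    """
    if not isinstance(params, ELGParams):
        try:
            params = ELGParams(*params)
        except ValueError:
            return -np.inf
    ll = 0.0
    if data.exact.size:
        ll += float(np.sum(elg_logpdf(data.exact, params)))
    if data.intervals.shape[0]:
        mass = elg_cdf(data.intervals[:, 1], params) - elg_cdf(data.intervals[:, 0], params)
        if np.any(mass <= 0.0):
            return -np.inf
        ll += float(np.sum(np.log(mass)))
    if data.right_censored.size:
        sf = elg_sf(data.right_censored, params)
        if np.any(sf <= 0.0):
            return -np.inf
        ll += float(np.sum(np.log(sf)))
    return ll if np.isfinite(ll) else -np.inf


def fit_mle_censored(
    data: CensoredSample,
    init: ELGParams | None = None,
    fixed: dict | None = None,
) -> FitResult:
    """Multi-start MLE under multicensoring (point estimation only).

    No information matrix is attempted for the censored model; ``vcov`` and
    ``se`` are always ``None``.
    """
    if not isinstance(data, CensoredSample):
        raise TypeError("fit_mle_censored expects a CensoredSample")
    fixed = dict(fixed or {})
    names = ("alpha", "theta", "p")
    free_idx = [i for i, nm in enumerate(names) if nm not in fixed]

    all_times = np.concatenate(
        [data.exact, data.intervals.ravel(), data.right_censored]
    )
    starts = [init.as_tuple()] if init is not None else _default_starts(all_times)

    def neg_ll(psi_free, psi_full0):
        psi = psi_full0.copy()
        psi[free_idx] = psi_free
        a, t, p = _from_internal(psi)
        try:
            return -censored_loglik(data, ELGParams(a, t, p))
        except ValueError:
            return np.inf

    best = best_res = None
    for s in starts:
        full0 = list(s)
        for i, nm in enumerate(names):
            if nm in fixed:
                full0[i] = fixed[nm]
        psi0 = _to_internal(*full0)
        res = optimize.minimize(
            neg_ll,
            psi0[free_idx],
            args=(psi0,),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best_res.fun:
            psi = psi0.copy()
            psi[free_idx] = res.x
            best, best_res = ELGParams(*_from_internal(psi)), res
    if best is None:
        raise RuntimeError("all censored-fit starts failed")
    return FitResult(
        params_hat=best,
        loglik=-float(best_res.fun),
        vcov=None,
        se=None,
        n_iter=int(best_res.nit),
        converged=bool(best_res.success),
        method="direct",
        message="censored fit: standard errors not computed",
        n_obs=data.n,
    )
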