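"""Clinician uptake estimated from pragmatic-trial recruitment cascades.

A recruitment cascade — practices approached, practices participating,
clinicians participating within those practices — multiplies down to a single
uptake proportion.  Its *effective denominator* is the number of clinicians
who could have participated had every approached practice taken part: the
innermost denominator scaled by the inverse participation fraction of each
outer level (e.g. 92 clinicians in 22 of 61 approached practices give
92 * 61/22 = 255 potential clinicians).

A single trial gets an exact (Clopper-Pearson) or asymptotic binomial CI on
numerator / effective denominator.  Several trials of the same intervention
are pooled with a one-observation-per-trial binomial GLMM,

    x_j ~ Binomial(n_j, expit(beta0 + u_j)),   u_j ~ Normal(0, sigma^2),

fitted by maximum marginal likelihood with adaptive Gauss-Hermite quadrature,
and summarised on the population-averaged scale E[expit(beta0 + sigma Z)].
Adaptive (mode-and-curvature rescaled) quadrature matters here: with
thousands of clinicians per trial the integrand is far narrower than the
standard-normal prior, and fixed-node quadrature misses the peak.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, stats
from scipy.special import expit, logit
from statsmodels.stats.proportion import proportion_confint

from .trial_io import RecruitmentCascade

logger = logging.getLogger("popimpact")

#: map from our CI-method names to statsmodels' proportion_confint methods
_CI_METHOD_MAP = {"clopper_pearson": "beta", "wilson": "wilson", "wald": "normal"}

_SIGMA_BOUNDARY_TOL = 1e-4


class CascadeError(ValueError):
    """The effective-denominator scaling is undefined for this cascade."""


class ConvergenceError(RuntimeError):
    """The GLMM optimiser failed to converge; carries the optimiser trace."""

    def __init__(self, message: str, trace: object = None) -> None:
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class UptakeEstimate:
    """Uptake proportion with effective counts, CI and method provenance."""

    intervention_id: str
    proportion: float
    numerator: int
    effective_denominator: int
    ci: tuple[float, float]
    method: str  # "single_trial" | "pooled_glmm"
    ci_method: str

    def __post_init__(self) -> None:
        lo, hi = self.ci
        if not (0.0 <= lo <= self.proportion <= hi <= 1.0):
            raise ValueError(
                f"'{self.intervention_id}': need 0 <= ci.low <= proportion <= "
                f"ci.high <= 1, got {lo}, {self.proportion}, {hi}"
            )
        if self.numerator > self.effective_denominator:
            raise ValueError(
                f"'{self.intervention_id}': numerator {self.numerator} exceeds "
                f"effective denominator {self.effective_denominator}"
            )


@dataclass(frozen=True)
class GlmmFit:
    """Fitted random-intercept logistic model for pooled uptake."""

    beta0: float
    sigma: float
    loglik: float
    converged: bool
    n_quadrature: int
    boundary: bool = False  # sigma estimated at the 0 boundary

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


def cascade_uptake(c: RecruitmentCascade) -> tuple[float, int, float]:
    """Reduce a cascade to (proportion, numerator, effective denominator).

    proportion = product over levels of participated/approached; numerator is
    the innermost participated count; the effective denominator is returned
    *unrounded* (round only for reporting) and satisfies
    proportion == numerator / effective_denominator to machine precision.
    """
    for i, lv in enumerate(c.levels[:-1]):
        if lv.participated == 0:
            raise CascadeError(
                f"trial '{c.trial_id}': outer level '{lv.unit_label}' (order {i + 1}) "
                "has zero participating units; effective-denominator scaling undefined"
            )
    proportion = 1.0
    for lv in c.levels:
        proportion *= lv.participated / lv.approached
    inner = c.levels[-1]
    scale = 1.0
    for lv in c.levels[:-1]:
        scale *= lv.approached / lv.participated
    return proportion, inner.participated, inner.approached * scale


def binomial_ci(
    x: int, n: int, level: float = 0.95, method: str = "clopper_pearson"
) -> tuple[float, float]:
    """CI for a single binomial proportion; low floored at 0, high capped at 1."""
    if not 0 <= x <= n or n < 1:
        raise ValueError(f"need 0 <= x <= n and n >= 1, got x={x}, n={n}")
    try:
        sm_method = _CI_METHOD_MAP[method]
    except KeyError:
        raise ValueError(
            f"unknown CI method '{method}' (choose from {sorted(_CI_METHOD_MAP)})"
        ) from None
    lo, hi = proportion_confint(x, n, alpha=1.0 - level, method=sm_method)
    return max(0.0, float(lo)), min(1.0, float(hi))


def single_trial_uptake(
    c: RecruitmentCascade, level: float = 0.95, ci_method: str = "clopper_pearson"
) -> UptakeEstimate:
    """Uptake estimate from one cascade with a single-proportion binomial CI.

    The CI treats the rounded effective denominator as the binomial sample
    size; for a single-level cascade this is exact, for nested cascades it is
    the paper-style approximation on the scaled denominator.
    """
    proportion, num, eff = cascade_uptake(c)
    n_eff = int(round(eff))
    ci = binomial_ci(num, n_eff, level=level, method=ci_method)
    lo = min(ci[0], proportion)  # guard: rounding eff can nudge p past a bound
    hi = max(ci[1], proportion)
    return UptakeEstimate(
        intervention_id=c.intervention_id,
        proportion=proportion,
        numerator=num,
        effective_denominator=n_eff,
        ci=(lo, hi),
        method="single_trial",
        ci_method=ci_method,
    )


# ---------------------------------------------------------------------------
# random-intercept logistic pooling
# ---------------------------------------------------------------------------

def _binom_logpmf_kernel(x: np.ndarray, n: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # kernel of the binomial log-pmf on the logit scale; the x-choose-n constant
    # cancels in the MLE and is dropped (n may be a non-integer effective count)
    return x * eta - n * np.logaddexp(0.0, eta)


def _neg_marginal_loglik(
    theta: np.ndarray, x: np.ndarray, n: np.ndarray, t: np.ndarray, w: np.ndarray
) -> float:
    """Negative log marginal likelihood by adaptive Gauss-Hermite quadrature.

    For each observation the integral over the random intercept z ~ N(0,1) is
    recentred at the conditional mode z* and rescaled by the curvature there,
    so the nodes land on the (possibly very narrow) integrand peak.
    """
    b0, sigma = float(theta[0]), float(theta[1])
    total = 0.0
    for xj, nj in zip(x, n):
        if sigma < 1e-12:
            # degenerate random effect: the integral collapses to the kernel
            # (offset by the per-observation constant subtracted below)
            total += float(_binom_logpmf_kernel(xj, nj, np.array(b0)))
            total += 0.5 * math.log(2.0 * math.pi)
            continue
        # Newton for the mode of h(z) = loglik(b0 + sigma z) - z^2/2
        z = 0.0
        for _ in range(50):
            p = expit(b0 + sigma * z)
            g = sigma * (xj - nj * p) - z
            hpp = -(sigma**2) * nj * p * (1.0 - p) - 1.0
            step = g / hpp
            z -= step
            if abs(step) < 1e-10:
                break
        p = expit(b0 + sigma * z)
        tau = 1.0 / math.sqrt((sigma**2) * nj * p * (1.0 - p) + 1.0)
        zi = z + math.sqrt(2.0) * tau * t
        h = _binom_logpmf_kernel(xj, nj, b0 + sigma * zi) - 0.5 * zi**2
        # log of sqrt(2) * tau * sum_i w_i exp(t_i^2) exp(h_i), stabilised
        log_terms = np.log(w) + t**2 + h
        m = float(np.max(log_terms))
        total += (
            math.log(math.sqrt(2.0) * tau)
            + m
            + math.log(float(np.sum(np.exp(log_terms - m))))
        )
    # 1/sqrt(2 pi) of the N(0,1) random-intercept density, once per observation
    total -= len(x) * 0.5 * math.log(2.0 * math.pi)
    return -total


def marginal_mean(beta0: float, sigma: float, n_quad: int = 201) -> float:
    """Population-averaged uptake E[expit(beta0 + sigma Z)], Z ~ N(0,1)."""
    if sigma < 1e-12:
        return float(expit(beta0))
    nodes, wts = hermgauss(n_quad)
    z = math.sqrt(2.0) * nodes
    w = wts / math.sqrt(math.pi)
    return float(np.sum(w * expit(beta0 + sigma * z)))


def pool_uptake_glmm(
    cascades: Sequence[RecruitmentCascade],
    level: float = 0.95,
    n_quad: int = 21,
    fix_sigma: Optional[float] = None,
) -> tuple[UptakeEstimate, GlmmFit]:
    """Pool uptake across trials with a random-intercept logistic model.

    Each population-based cascade is reduced to (numerator, effective
    denominator) and treated as one binomial observation.  The reported
    proportion is the population-averaged mean; the CI is the Wald interval
    for beta0 pushed through the same marginalisation (sigma held at its
    estimate), with the lower bound floored at 0.  ``fix_sigma`` pins the
    random-intercept SD (0 gives the simple pooled-binomial estimate).
    """
    usable = [c for c in cascades if c.population_based]
    skipped = len(cascades) - len(usable)
    if skipped:
        logger.info("excluding %d non-population-based cascade(s) from pooling", skipped)
    if len(usable) < 2:
        raise ValueError(
            "pooling needs >= 2 population-based cascades; for a single trial use "
            "cascade_uptake + binomial_ci (single_trial_uptake)"
        )
    reduced = [cascade_uptake(c) for c in usable]
    x = np.array([r[1] for r in reduced], dtype=float)
    n = np.array([r[2] for r in reduced], dtype=float)

    nodes, wts = hermgauss(n_quad)
    args = (x, n, nodes, wts)

    p_pool = float(np.sum(x) / np.sum(n))
    b0_pool = float(logit(p_pool))

    if fix_sigma is not None:
        if fix_sigma < 0:
            raise ValueError("fix_sigma must be >= 0")
        res = optimize.minimize_scalar(
            lambda b: _neg_marginal_loglik(np.array([b, fix_sigma]), *args),
            bracket=(b0_pool - 1.0, b0_pool, b0_pool + 1.0),
        )
        beta0, sigma = float(res.x), float(fix_sigma)
        nll = float(res.fun)
        converged = bool(res.success)
        trace = res
    else:
        # one-observation-per-cluster GLMMs are fragile: restart the optimiser
        # from three fixed points and keep the best converged fit
        starts = [(b0_pool, 0.1), (b0_pool, 0.5), (b0_pool - 0.5, 1.0)]
        best = None
        for s in starts:
            res = optimize.minimize(
                _neg_marginal_loglik, np.array(s), args=args,
                method="Nelder-Mead",
                options=dict(xatol=1e-8, fatol=1e-10, maxiter=2000),
            )
            # reflect sigma into [0, inf): the likelihood is even in sigma
            res.x[1] = abs(res.x[1])
            if res.success and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise ConvergenceError("GLMM optimiser failed from all starting points",
                                   trace=res)
        beta0, sigma = float(best.x[0]), float(best.x[1])
        nll = float(best.fun)
        converged = True
        trace = best
        # the profile in sigma is quadratically flat at 0; snap to the boundary
        # when sigma = 0 attains an (effectively) equal likelihood
        prof0 = optimize.minimize_scalar(
            lambda b: _neg_marginal_loglik(np.array([b, 0.0]), *args),
            bracket=(beta0 - 1.0, beta0, beta0 + 1.0),
        )
        if prof0.fun <= nll + 1e-6:
            beta0, sigma, nll = float(prof0.x), 0.0, float(prof0.fun)

    boundary = sigma <= _SIGMA_BOUNDARY_TOL
    if boundary:
        logger.info("random-intercept SD estimated at the 0 boundary")

    # observed information for (beta0, sigma) by central finite differences;
    # at the sigma boundary fall back to the binomial information for beta0
    if boundary:
        p0 = expit(beta0)
        se_b0 = 1.0 / math.sqrt(float(np.sum(n)) * p0 * (1.0 - p0))
    else:
        h = 1e-5
        th = np.array([beta0, sigma])
        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                ei = np.zeros(2); ei[i] = h
                ej = np.zeros(2); ej[j] = h
                H[i, j] = (
                    _neg_marginal_loglik(th + ei + ej, *args)
                    - _neg_marginal_loglik(th + ei - ej, *args)
                    - _neg_marginal_loglik(th - ei + ej, *args)
                    + _neg_marginal_loglik(th - ei - ej, *args)
                ) / (4.0 * h * h)
        try:
            cov = np.linalg.inv(H)
            se_b0 = math.sqrt(max(cov[0, 0], 0.0))
        except np.linalg.LinAlgError:
            raise ConvergenceError("singular observed information", trace=trace)

    z = stats.norm.ppf(0.5 + level / 2.0)
    prop = marginal_mean(beta0, sigma)
    lo = marginal_mean(beta0 - z * se_b0, sigma)
    hi = marginal_mean(beta0 + z * se_b0, sigma)
    lo, hi = max(0.0, min(lo, prop)), min(1.0, max(hi, prop))

    iv = usable[0].intervention_id
    est = UptakeEstimate(
        intervention_id=iv,
        proportion=prop,
        numerator=int(np.sum(x)),
        effective_denominator=int(round(float(np.sum(n)))),
        ci=(lo, hi),
        method="pooled_glmm",
        ci_method=f"glmm_wald_marginal(level={level})",
    )
    fit = GlmmFit(
        beta0=beta0, sigma=sigma, loglik=-nll, converged=converged,
        n_quadrature=n_quad, boundary=boundary,
    )
    return est, fit
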