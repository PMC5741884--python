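"""Population impact: trial effectiveness times clinician uptake.

population impact = RRR x uptake — the fraction of clinical encounters, among
those where the outcome (e.g. an antibiotic prescription) would otherwise
occur, in which the intervention is both taken up and effective.  Each
encounter falls into exactly one of three strata:

* ``averted``          — intervention used, outcome averted: uptake x RRR
* ``uptake_no_effect`` — intervention used, outcome still occurs: uptake x RR
* ``no_uptake``        — intervention not used: 1 - uptake

The paper-style point estimate is deterministic; the interval is obtained by
Monte-Carlo propagation of the two input CIs under independence (the sources
— effectiveness meta-analysis and recruitment-based uptake — share no data).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .effectiveness import EffectEstimate
from .uptake import UptakeEstimate

logger = logging.getLogger("popimpact")


@dataclass(frozen=True)
class ImpactEstimate:
    """RRR x uptake with the three-way encounter decomposition."""

    intervention_id: str
    rrr: float
    uptake: float
    impact: float
    strata: tuple[float, float, float]  # (averted, uptake_no_effect, no_uptake)
    ci: Optional[tuple[float, float]] = None
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.impact != self.rrr * self.uptake:
            raise ValueError(
                f"'{self.intervention_id}': impact must equal rrr * uptake exactly"
            )
        if abs(sum(self.strata) - 1.0) > 1e-12:
            raise ValueError(f"'{self.intervention_id}': strata must sum to 1")


def decompose_encounters(u: float, rr: float) -> tuple[float, float, float]:
    """Split encounters into (averted, uptake-but-no-effect, no-uptake)."""
    if not (0.0 <= u <= 1.0 and 0.0 <= rr <= 1.0):
        raise ValueError(f"need uptake and RR in [0, 1], got u={u}, rr={rr}")
    return u * (1.0 - rr), u * rr, 1.0 - u


def population_impact(e: EffectEstimate, u: UptakeEstimate) -> ImpactEstimate:
    """Point estimate of population impact (CI and rank filled in later)."""
    if e.rrr < 0:
        logger.warning(
            "'%s': negative RRR %.3f (harmful intervention) propagated as-is",
            e.intervention_id, e.rrr,
        )
        strata = (u.proportion * e.rrr, u.proportion * (1.0 - e.rrr), 1.0 - u.proportion)
    else:
        strata = decompose_encounters(u.proportion, e.pooled_rr)
    return ImpactEstimate(
        intervention_id=e.intervention_id,
        rrr=e.rrr,
        uptake=u.proportion,
        impact=e.rrr * u.proportion,
        strata=strata,
    )


def _se_from_rr_ci(e: EffectEstimate, level: float) -> float:
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = e.ci
    return (math.log(hi) - math.log(lo)) / (2.0 * z)


def _se_from_uptake_ci(u: UptakeEstimate, level: float) -> float:
    """Logit-scale SE recovered from the uptake CI (delta method).

    A lower bound floored at 0 (or a bound at 1) is uninformative on the logit
    scale, so the SE is then taken from the finite side alone.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = u.ci
    p = u.proportion
    if 0.0 < lo and hi < 1.0:
        return (logit(hi) - logit(lo)) / (2.0 * z)
    if hi < 1.0:
        return (logit(hi) - logit(p)) / z
    if lo > 0.0:
        return (logit(p) - logit(lo)) / z
    raise ValueError(f"'{u.intervention_id}': uptake CI {u.ci} unusable on logit scale")


def impact_ci_mc(
    e: EffectEstimate,
    u: UptakeEstimate,
    draws: int = 100_000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile Monte-Carlo CI for impact, propagating both input CIs.

    Draws log-RR ~ Normal(log pooled RR, SE from the RR CI) and uptake on the
    logit scale ~ Normal(logit p, SE from the uptake CI), independently;
    impact draw = (1 - RR) x uptake.  Deterministic given ``seed``; the lower
    bound is floored at 0.
    """
    if draws < 1000:
        raise ValueError(f"draws must be >= 1000, got {draws}")
    point = e.rrr * u.proportion
    rr_width = e.ci[1] - e.ci[0]
    up_width = u.ci[1] - u.ci[0]
    if rr_width == 0.0 and up_width == 0.0:
        logger.warning("'%s': both input CIs degenerate; returning point-mass interval",
                       e.intervention_id)
        return point, point

    rng = np.random.default_rng(seed)
    if rr_width > 0.0:
        se_log_rr = _se_from_rr_ci(e, level)
        log_rr = rng.normal(math.log(e.pooled_rr), se_log_rr, size=draws)
    else:
        log_rr = np.full(draws, math.log(e.pooled_rr))
    if up_width > 0.0:
        se_logit_u = _se_from_uptake_ci(u, level)
        up = expit(rng.normal(logit(u.proportion), se_logit_u, size=draws))
    else:
        up = np.full(draws, u.proportion)

    impacts = (1.0 - np.exp(log_rr)) * up
    alpha = 1.0 - level
    lo, hi = np.quantile(impacts, [alpha / 2.0, 1.0 - alpha / 2.0])
    return max(0.0, float(lo)), float(hi)


def rank_interventions(estimates: Sequence[ImpactEstimate]) -> list[ImpactEstimate]:
    """Rank by impact descending; ties by higher uptake, then intervention_id."""
    if len(estimates) == 0:
        raise ValueError("need at least one impact estimate to rank")
    order = sorted(
        range(len(estimates)),
        key=lambda i: (-estimates[i].impact, -estimates[i].uptake,
                       estimates[i].intervention_id),
    )
    ranked = list(estimates)
    for rank, i in enumerate(order, start=1):
        ranked[i] = replace(estimates[i], rank=rank)
    return ranked
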