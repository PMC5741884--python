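"""Synthetic multi-trial datasets with the generative structure the analysis
assumes, so every pipeline stage is testable without external data.

Trial outcomes follow the random-effects model the meta-analysis pools: each
trial draws a true log relative risk from Normal(mu_log_rr, tau^2) and
binomial event counts in both arms.  Recruitment follows the random-intercept
logistic model the uptake pooling fits: each trial draws a unit-level random
effect on the participation log-odds at every cascade level.

Default scenario values mirror the antibiotic-prescribing setting the method
was developed on: a strongly effective intervention (mu_log_rr = ln 0.36,
the largest pooled RR reduction observed there), substantial between-trial
heterogeneity (tau = 0.3), and a participation operating point near 19%
uptake (beta0 = logit 0.19) with moderate between-trial spread (sigma = 0.5).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .trial_io import RecruitmentCascade, RecruitmentLevel, TrialOutcome, ArmCount

logger = logging.getLogger("popimpact")

_LOGIT_019 = math.log(0.19 / 0.81)


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters for synthetic trials and recruitment cascades.

    ``clinicians_per_practice_range = None`` produces single-level cascades
    (clinicians recruited directly from a population of size drawn from
    ``practices_approached_range``), matching trials that invite individual
    physicians rather than practices.
    """

    n_interventions: int = 1
    trials_per_intervention: int = 5
    mu_log_rr: float = math.log(0.36)
    tau: float = 0.3
    control_risk: float = 0.6
    arm_size_range: tuple[int, int] = (100, 500)
    uptake_beta0: float = _LOGIT_019
    uptake_sigma: float = 0.5
    practices_approached_range: tuple[int, int] = (20, 60)
    clinicians_per_practice_range: Optional[tuple[int, int]] = (1, 5)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("arm_size_range", "practices_approached_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a nonempty positive range, got {lo, hi}")
        if self.clinicians_per_practice_range is not None:
            lo, hi = self.clinicians_per_practice_range
            if not (0 < lo <= hi):
                raise ValueError("clinicians_per_practice_range must be nonempty positive")
        if not 0.0 < self.control_risk < 1.0:
            raise ValueError(f"control_risk must be in (0, 1), got {self.control_risk}")
        if self.tau < 0 or self.uptake_sigma < 0:
            raise ValueError("tau and uptake_sigma must be >= 0")
        if self.n_interventions < 1 or self.trials_per_intervention < 1:
            raise ValueError("need >= 1 intervention and >= 1 trial per intervention")


def _trial_streams(s: SimScenario, salt: int) -> list[np.random.Generator]:
    """One independent, reproducible stream per trial (spawned from the seed)."""
    n = s.n_interventions * s.trials_per_intervention
    root = np.random.SeedSequence([s.seed, salt])
    return [np.random.default_rng(ss) for ss in root.spawn(n)]


def _ids(s: SimScenario) -> list[tuple[str, str]]:
    return [
        (f"iv{i}_t{j}", f"iv{i}")
        for i in range(s.n_interventions)
        for j in range(s.trials_per_intervention)
    ]


def simulate_trials(s: SimScenario) -> list[TrialOutcome]:
    """Draw two-arm binomial outcomes under trial-specific true log RRs."""
    out: list[TrialOutcome] = []
    for (tid, iv), rng in zip(_ids(s), _trial_streams(s, salt=1)):
        log_rr = rng.normal(s.mu_log_rr, s.tau)
        n = int(rng.integers(s.arm_size_range[0], s.arm_size_range[1] + 1))
        risk_t = s.control_risk * math.exp(log_rr)
        if risk_t > 1.0:
            logger.warning("trial '%s': treated risk %.3f clipped at 1", tid, risk_t)
            risk_t = 1.0
        events_c = int(rng.binomial(n, s.control_risk))
        events_t = int(rng.binomial(n, risk_t))
        out.append(
            TrialOutcome(tid, iv, treated=ArmCount(events_t, n),
                         control=ArmCount(events_c, n))
        )
    return out


def simulate_recruitment(s: SimScenario) -> list[RecruitmentCascade]:
    """Draw recruitment cascades under the random-intercept logistic model.

    Each trial draws its own random effect per cascade level; participation
    at a level is binomial with probability expit(uptake_beta0 + effect).
    A cascade whose outer level ends with zero participating units is still
    returned (it is a legitimate outcome of the process) but flagged in the
    log; downstream uptake reduction rejects it.
    """
    out: list[RecruitmentCascade] = []
    for (tid, iv), rng in zip(_ids(s), _trial_streams(s, salt=2)):
        n_outer = int(rng.integers(s.practices_approached_range[0],
                                   s.practices_approached_range[1] + 1))
        u = rng.normal(0.0, s.uptake_sigma)
        part_outer = int(rng.binomial(n_outer, expit(s.uptake_beta0 + u)))
        if s.clinicians_per_practice_range is None:
            levels = (RecruitmentLevel("clinician", part_outer, n_outer),)
        else:
            lo, hi = s.clinicians_per_practice_range
            n_clin = int(part_outer * rng.integers(lo, hi + 1)) if part_outer else 1
            v = rng.normal(0.0, s.uptake_sigma)
            part_clin = int(rng.binomial(n_clin, expit(s.uptake_beta0 + v)))
            levels = (
                RecruitmentLevel("practice", part_outer, n_outer),
                RecruitmentLevel("clinician", part_clin, n_clin),
            )
        c = RecruitmentCascade(tid, iv, levels)
        if not c.usable:
            logger.warning("trial '%s': zero participating outer units; cascade unusable",
                           tid)
        out.append(c)
    return out


def true_marginal_uptake(s: SimScenario, n_quad: int = 201) -> float:
    """Population-averaged uptake implied by the scenario, per cascade level
    product (outer x inner for two-level cascades)."""
    from .uptake import marginal_mean

    m = marginal_mean(s.uptake_beta0, s.uptake_sigma, n_quad)
    return m if s.clinicians_per_practice_range is None else m * m
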