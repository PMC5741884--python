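"""Random-effects meta-analysis of relative risks (the trial-effectiveness step).

Per-trial log relative risks and their sampling variances are pooled with the
DerSimonian-Laird moment estimator of the between-study variance tau^2 and a
Wald confidence interval on the log scale — the random-effects default of
RevMan, the tool pragmatic-trial meta-analyses are most often run in.  A zero
event cell triggers the RevMan-style continuity correction (add ``cc`` to all
four cells of that trial's 2x2 table).

REML is available as an alternative tau^2 estimator for sensitivity analyses;
DL remains the default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .trial_io import TrialOutcome

logger = logging.getLogger("popimpact")


class UndefinedEffectError(ValueError):
    """Both arms have zero events even after continuity correction."""


@dataclass(frozen=True)
class StudyEffect:
    """One study's log relative risk and its sampling variance."""

    trial_id: str
    log_rr: float
    var_log_rr: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if not self.var_log_rr > 0:
            raise ValueError(
                f"trial '{self.trial_id}': var_log_rr must be > 0, got {self.var_log_rr}"
            )


@dataclass(frozen=True)
class EffectEstimate:
    """Pooled relative risk with CI and heterogeneity statistics.

    ``k`` is None when the pooled RR was supplied externally (e.g. copied from
    a published meta-analysis) rather than pooled here.  ``rrr`` is the
    relative risk reduction, 1 - pooled_rr.
    """

    intervention_id: str
    pooled_rr: float
    ci: tuple[float, float]
    k: Optional[int] = None
    tau2: float = 0.0
    q: float = 0.0
    i2: float = 0.0
    single_study: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.ci
        if not (lo <= self.pooled_rr <= hi):
            raise ValueError(
                f"'{self.intervention_id}': CI ({lo}, {hi}) must bracket pooled RR "
                f"{self.pooled_rr}"
            )
        if self.tau2 < 0:
            raise ValueError(f"tau2 must be >= 0, got {self.tau2}")

    @property
    def rrr(self) -> float:
        return 1.0 - self.pooled_rr


def study_log_rr(t: TrialOutcome, cc: float = 0.5) -> StudyEffect:
    """Log relative risk and variance for one trial.

    log RR = ln[(a/n1)/(c/n2)], var = 1/a - 1/n1 + 1/c - 1/n2.  If either
    event count is zero, ``cc`` is added to all four cells (events and
    non-events in both arms) first and the result is flagged ``corrected``.
    """
    if cc < 0:
        raise ValueError(f"continuity correction must be >= 0, got {cc}")
    a, n1 = float(t.treated.events), float(t.treated.total)
    c, n2 = float(t.control.events), float(t.control.total)
    corrected = False
    if a == 0 or c == 0:
        if (a == 0 and c == 0) and cc == 0:
            raise UndefinedEffectError(
                f"trial '{t.trial_id}': zero events in both arms and cc = 0"
            )
        a, c = a + cc, c + cc
        n1, n2 = n1 + 2 * cc, n2 + 2 * cc
        corrected = True
        if a == 0 or c == 0:
            raise UndefinedEffectError(
                f"trial '{t.trial_id}': effect undefined after continuity correction"
            )
        logger.warning("trial '%s': zero cell, continuity correction %.2g applied",
                       t.trial_id, cc)
    log_rr = math.log((a / n1) / (c / n2))
    var = 1.0 / a - 1.0 / n1 + 1.0 / c - 1.0 / n2
    return StudyEffect(t.trial_id, log_rr, var, corrected)


def _dl_tau2(y: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """DerSimonian-Laird tau^2 and Cochran's Q from effects y and variances v."""
    w = 1.0 / v
    y_fe = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - y_fe) ** 2))
    k = len(y)
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    return tau2, q


def _reml_tau2(y: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """REML tau^2 (1-d bounded maximisation); Q reported as for DL."""
    _, q = _dl_tau2(y, v)

    def neg_restricted_ll(tau2: float) -> float:
        wi = 1.0 / (v + tau2)
        mu = np.sum(wi * y) / np.sum(wi)
        return 0.5 * float(
            np.sum(np.log(v + tau2)) + math.log(np.sum(wi)) + np.sum(wi * (y - mu) ** 2)
        )

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(0.0, float(np.var(y) * 10 + 1.0)), method="bounded",
    )
    return max(0.0, float(res.x)), q


def pool_dersimonian_laird(
    studies: Sequence[StudyEffect],
    level: float = 0.95,
    intervention_id: str = "",
    tau2_estimator: str = "dl",
) -> EffectEstimate:
    """Pool study log relative risks under the random-effects model.

    Random-effects weights are 1/(v_i + tau^2) with tau^2 from the
    DerSimonian-Laird moment estimator (or REML when requested); the pooled
    log RR gets a Wald CI and is exponentiated.  A single study is returned
    as-is with tau^2 = 0 and flagged ``single_study``.
    """
    k = len(studies)
    if k == 0:
        raise ValueError("cannot pool zero studies")
    y = np.array([s.log_rr for s in studies])
    v = np.array([s.var_log_rr for s in studies])
    z = stats.norm.ppf(0.5 + level / 2.0)

    if k == 1:
        se = math.sqrt(v[0])
        return EffectEstimate(
            intervention_id=intervention_id,
            pooled_rr=math.exp(y[0]),
            ci=(math.exp(y[0] - z * se), math.exp(y[0] + z * se)),
            k=1, tau2=0.0, q=0.0, i2=0.0, single_study=True,
        )

    if tau2_estimator == "dl":
        tau2, q = _dl_tau2(y, v)
    elif tau2_estimator == "reml":
        tau2, q = _reml_tau2(y, v)
    else:
        raise ValueError(f"unknown tau2_estimator '{tau2_estimator}'")

    w_star = 1.0 / (v + tau2)
    mu = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(np.sum(w_star) ** -0.5)
    i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    return EffectEstimate(
        intervention_id=intervention_id,
        pooled_rr=math.exp(mu),
        ci=(math.exp(mu - z * se), math.exp(mu + z * se)),
        k=k, tau2=tau2, q=q, i2=i2,
    )


def meta_analyse(
    trials: Sequence[TrialOutcome],
    level: float = 0.95,
    cc: float = 0.5,
    tau2_estimator: str = "dl",
) -> list[EffectEstimate]:
    """Group trials by intervention and pool each group."""
    by_iv: dict[str, list[StudyEffect]] = {}
    for t in trials:
        by_iv.setdefault(t.intervention_id, []).append(study_log_rr(t, cc=cc))
    return [
        pool_dersimonian_laird(effs, level=level, intervention_id=iv,
                               tau2_estimator=tau2_estimator)
        for iv, effs in by_iv.items()
    ]
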