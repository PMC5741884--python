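"""Worked example: four interventions to reduce antibiotic prescribing for
acute respiratory infections in primary care.

The inputs are the published summary numbers for the case study the method
was developed on: pooled relative risks from four systematic reviews of
pragmatic trials, and clinician recruitment counts from six of those trials.

Effectiveness here is *supplied*, not re-pooled: the per-study 2x2 tables
live in the underlying reviews, so the pooled RRs and their CIs are taken as
given (the meta-analysis engine is validated separately on synthetic and
hand-computed data).  The aggregate intervention/control event totals are
also provided as single-trial fixtures for exercising the log-RR machinery.

Shared decision making pools three trials.  The published totals are 281
participating out of 3389 potential clinicians, but the per-trial recruitment
counts reported for the three trials (45/345; 101/2036; and a two-level
cascade of 4/24 family-medicine groups then 33/42 physicians) do not sum to
those totals under the effective-denominator rule.  Both versions ship:
:func:`sdm_cascades_reported` carries the counts as reported, and
:func:`sdm_counts_reconstructed` carries the third trial backed out by
subtraction (281-45-101 = 135 of 3389-345-2036 = 1008), which reproduces the
published totals and is what the pooled-uptake reproduction uses.  The
discrepancy is documented, not resolved.
"""

from __future__ import annotations

from .effectiveness import EffectEstimate
from .trial_io import ArmCount, RecruitmentCascade, RecruitmentLevel, TrialOutcome

INTERVENTIONS = ("delayed_prescribing", "procalcitonin", "crp", "shared_decision_making")

#: published pooled relative risks (95% CI) per intervention
PUBLISHED_RR = {
    "delayed_prescribing": (0.36, (0.27, 0.48)),
    "procalcitonin": (0.39, (0.17, 0.86)),
    "crp": (0.78, (0.66, 0.92)),
    "shared_decision_making": (0.61, (0.55, 0.68)),
}

#: aggregate event totals, intervention vs control arm (shared decision
#: making reported no event counts, only denominators)
AGGREGATE_COUNTS = {
    "delayed_prescribing": ((255, 817), (790, 847)),
    "procalcitonin": ((117, 507), (320, 501)),
    "crp": ((631, 1685), (785, 1599)),
}


def published_effects() -> list[EffectEstimate]:
    """Pooled-RR estimates as published (k unknown, hence None)."""
    return [
        EffectEstimate(intervention_id=iv, pooled_rr=rr, ci=ci)
        for iv, (rr, ci) in PUBLISHED_RR.items()
    ]


def aggregate_trial_fixtures() -> list[TrialOutcome]:
    """The aggregate 2x2 totals wrapped as single-trial fixtures."""
    return [
        TrialOutcome(
            trial_id=f"{iv}_totals", intervention_id=iv,
            treated=ArmCount(*t), control=ArmCount(*c),
        )
        for iv, (t, c) in AGGREGATE_COUNTS.items()
    ]


def delayed_prescribing_cascade() -> RecruitmentCascade:
    """22/61 practices participated; within them, 48/92 clinicians recruited."""
    return RecruitmentCascade(
        trial_id="delayed_rct", intervention_id="delayed_prescribing",
        levels=(RecruitmentLevel("practice", 22, 61), RecruitmentLevel("gp", 48, 92)),
    )


def procalcitonin_cascade() -> RecruitmentCascade:
    """53 of 345 eligible primary-care physicians participated."""
    return RecruitmentCascade(
        trial_id="procalcitonin_rct", intervention_id="procalcitonin",
        levels=(RecruitmentLevel("gp", 53, 345),),
    )


def crp_cascade() -> RecruitmentCascade:
    """35 of 125 single-handed-practice clinicians participated."""
    return RecruitmentCascade(
        trial_id="crp_rct", intervention_id="crp",
        levels=(RecruitmentLevel("gp", 35, 125),),
    )


def sdm_cascades_reported() -> list[RecruitmentCascade]:
    """The three shared-decision-making trials' recruitment as reported."""
    iv = "shared_decision_making"
    return [
        RecruitmentCascade("sdm_rct1", iv, (RecruitmentLevel("gp", 45, 345),)),
        RecruitmentCascade("sdm_rct2", iv, (RecruitmentLevel("gp", 101, 2036),)),
        RecruitmentCascade(
            "sdm_rct3", iv,
            (RecruitmentLevel("fmg", 4, 24), RecruitmentLevel("fp", 33, 42)),
        ),
    ]


def sdm_cascades_reconstructed() -> list[RecruitmentCascade]:
    """SYNTHETIC reconstruction of the third trial's counts (135/1008) so the
    three trials sum to the published 281/3389 totals; see module docstring."""
    iv = "shared_decision_making"
    return [
        RecruitmentCascade("sdm_rct1", iv, (RecruitmentLevel("gp", 45, 345),)),
        RecruitmentCascade("sdm_rct2", iv, (RecruitmentLevel("gp", 101, 2036),)),
        RecruitmentCascade("sdm_rct3_reconstructed", iv,
                           (RecruitmentLevel("gp", 135, 1008),)),
    ]


def single_trial_cascades() -> list[RecruitmentCascade]:
    return [delayed_prescribing_cascade(), procalcitonin_cascade(), crp_cascade()]
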