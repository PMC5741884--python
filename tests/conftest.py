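import pytest

from popimpact import (
    ArmCount,
    RecruitmentCascade,
    RecruitmentLevel,
    TrialOutcome,
)


@pytest.fixture
def delayed_cascade() -> RecruitmentCascade:
    """Two-level cascade: 22/61 practices, then 48/92 clinicians."""
    return RecruitmentCascade(
        trial_id="delayed_rct",
        intervention_id="delayed_prescribing",
        levels=(RecruitmentLevel("practice", 22, 61), RecruitmentLevel("gp", 48, 92)),
    )


@pytest.fixture
def delayed_totals_trial() -> TrialOutcome:
    """Aggregate 2x2 totals for delayed prescribing used as a one-trial fixture."""
    return TrialOutcome(
        trial_id="dp1",
        intervention_id="delayed_prescribing",
        treated=ArmCount(255, 817),
        control=ArmCount(790, 847),
    )


def make_cascade(trial_id: str, x: int, n: int,
                 intervention_id: str = "iv", population_based: bool = True
                 ) -> RecruitmentCascade:
    return RecruitmentCascade(
        trial_id=trial_id,
        intervention_id=intervention_id,
        levels=(RecruitmentLevel("clinician", x, n),),
        population_based=population_based,
    )
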