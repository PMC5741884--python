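"""Data model and I/O for trial outcome tables, recruitment cascades and run
configuration.

The two tabular inputs of the analysis are plain CSV files:

``trials.csv``
    one row per randomised trial with two-arm event counts::

        trial_id,intervention_id,events_t,n_t,events_c,n_c

``recruitment.csv``
    one row per recruitment level (outermost level — e.g. practice — has
    ``level_order`` 1, the innermost — clinician — the highest order)::

        trial_id,intervention_id,level_order,unit_label,participated,approached[,population_based]

All validation errors name the offending ``trial_id`` and field so that a bad
row in a large table can be located immediately.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger("popimpact")

TRIAL_COLUMNS = ["trial_id", "intervention_id", "events_t", "n_t", "events_c", "n_c"]
RECRUITMENT_COLUMNS = [
    "trial_id",
    "intervention_id",
    "level_order",
    "unit_label",
    "participated",
    "approached",
]


class SchemaError(ValueError):
    """A required column is missing or a file is structurally malformed."""


class ValidationError(ValueError):
    """A row violates a domain invariant; the message names trial_id and field."""


@dataclass(frozen=True)
class ArmCount:
    """Event count out of the randomised total for one trial arm."""

    events: int
    total: int

    def __post_init__(self) -> None:
        if self.total < 1:
            raise ValidationError(f"arm total must be >= 1, got {self.total}")
        if not 0 <= self.events <= self.total:
            raise ValidationError(
                f"events must satisfy 0 <= events <= total, got {self.events}/{self.total}"
            )

    @property
    def risk(self) -> float:
        return self.events / self.total


@dataclass(frozen=True)
class TrialOutcome:
    """One trial's two-arm 2x2 outcome table — the meta-analysis unit."""

    trial_id: str
    intervention_id: str
    treated: ArmCount
    control: ArmCount

    def __post_init__(self) -> None:
        if not self.trial_id:
            raise ValidationError("trial_id must be nonempty")


@dataclass(frozen=True)
class RecruitmentLevel:
    """Participation counts at one nesting level (practice, clinician, ...)."""

    unit_label: str
    participated: int
    approached: int

    def __post_init__(self) -> None:
        if self.approached < 1:
            raise ValidationError(
                f"approached must be >= 1 for level '{self.unit_label}', got {self.approached}"
            )
        if not 0 <= self.participated <= self.approached:
            raise ValidationError(
                f"level '{self.unit_label}': participated must satisfy "
                f"0 <= participated <= approached, got {self.participated}/{self.approached}"
            )


@dataclass(frozen=True)
class RecruitmentCascade:
    """Ordered recruitment levels for one trial, outermost first.

    ``population_based`` marks trials whose clinicians were recruited from a
    defined population (the only ones usable for uptake pooling); trials that
    e.g. only invited academic practices attached to a university carry False
    and are excluded from pooled uptake estimation.
    """

    trial_id: str
    intervention_id: str
    levels: tuple[RecruitmentLevel, ...]
    population_based: bool = True

    def __post_init__(self) -> None:
        if not self.trial_id:
            raise ValidationError("trial_id must be nonempty")
        if len(self.levels) < 1:
            raise ValidationError(f"trial '{self.trial_id}': cascade needs >= 1 level")
        object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def usable(self) -> bool:
        """True when every outer (non-innermost) level has participants, so the
        effective-denominator scaling is defined."""
        return all(lv.participated > 0 for lv in self.levels[:-1])


@dataclass(frozen=True)
class RunConfig:
    """Run-level choices: CI method and level, Monte-Carlo draws, seed, rounding."""

    ci_method: str = "clopper_pearson"
    ci_level: float = 0.95
    mc_draws: int = 100_000
    seed: int = 0
    uptake_decimals: int = 0  # uptake reported to whole percent
    impact_decimals: int = 1  # impact reported to one decimal percent

    _CI_METHODS = ("clopper_pearson", "wilson", "wald")

    def __post_init__(self) -> None:
        if self.ci_method not in self._CI_METHODS:
            raise ValidationError(
                f"ci_method must be one of {self._CI_METHODS}, got '{self.ci_method}'"
            )
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.mc_draws < 1000:
            raise ValidationError(f"mc_draws must be >= 1000, got {self.mc_draws}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        fields = ("ci_method", "ci_level", "mc_draws", "seed",
                  "uptake_decimals", "impact_decimals")
        with open(path, "w") as fh:
            json.dump({k: getattr(self, k) for k in fields}, fh, indent=2)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_trials(path: str | Path, format: str = "csv") -> list[TrialOutcome]:
    """Read a trial-outcome table into validated :class:`TrialOutcome` records."""
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "json":
        df = pd.read_json(path)
    else:
        raise SchemaError(f"unsupported format '{format}' (csv or json)")
    if df.empty and not set(TRIAL_COLUMNS) <= set(df.columns):
        # pandas drops header typing on some empty frames; still enforce schema
        _require_columns(df, TRIAL_COLUMNS, path)
    _require_columns(df, TRIAL_COLUMNS, path)

    out: list[TrialOutcome] = []
    for _, row in df.iterrows():
        tid = str(row["trial_id"])
        try:
            out.append(
                TrialOutcome(
                    trial_id=tid,
                    intervention_id=str(row["intervention_id"]),
                    treated=ArmCount(int(row["events_t"]), int(row["n_t"])),
                    control=ArmCount(int(row["events_c"]), int(row["n_c"])),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"trial '{tid}': {err}") from err
    logger.info("read %d trial outcome rows from %s", len(out), path)
    return out


def write_trials(trials: Iterable[TrialOutcome], path: str | Path) -> None:
    rows = [
        dict(
            trial_id=t.trial_id,
            intervention_id=t.intervention_id,
            events_t=t.treated.events,
            n_t=t.treated.total,
            events_c=t.control.events,
            n_c=t.control.total,
        )
        for t in trials
    ]
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def read_recruitment(path: str | Path) -> list[RecruitmentCascade]:
    """Read a recruitment table and group rows into per-trial cascades.

    Levels are sorted by ``level_order`` ascending (outermost = 1).  A missing
    ``population_based`` column defaults to True with a logged warning, since
    single-trial worked examples typically omit it.
    """
    df = pd.read_csv(path)
    _require_columns(df, RECRUITMENT_COLUMNS, path)
    if "population_based" not in df.columns:
        logger.warning(
            "%s: no population_based column; assuming all trials are population based",
            path,
        )
        df = df.assign(population_based=True)

    dup = df.duplicated(subset=["trial_id", "level_order"])
    if dup.any():
        bad = df.loc[dup, ["trial_id", "level_order"]].iloc[0]
        raise ValidationError(
            f"trial '{bad['trial_id']}': duplicate level_order {int(bad['level_order'])}"
        )

    cascades: list[RecruitmentCascade] = []
    for tid, grp in df.groupby("trial_id", sort=False):
        grp = grp.sort_values("level_order")
        try:
            levels = tuple(
                RecruitmentLevel(
                    unit_label=str(r["unit_label"]),
                    participated=int(r["participated"]),
                    approached=int(r["approached"]),
                )
                for _, r in grp.iterrows()
            )
        except ValidationError as err:
            raise ValidationError(f"trial '{tid}': {err}") from err
        pb = bool(grp["population_based"].iloc[0])
        cascades.append(
            RecruitmentCascade(
                trial_id=str(tid),
                intervention_id=str(grp["intervention_id"].iloc[0]),
                levels=levels,
                population_based=pb,
            )
        )
    logger.info("read %d recruitment rows (%d cascades) from %s", len(df), len(cascades), path)
    return cascades


def write_recruitment(cascades: Iterable[RecruitmentCascade], path: str | Path) -> None:
    rows = []
    for c in cascades:
        for order, lv in enumerate(c.levels, start=1):
            rows.append(
                dict(
                    trial_id=c.trial_id,
                    intervention_id=c.intervention_id,
                    level_order=order,
                    unit_label=lv.unit_label,
                    participated=lv.participated,
                    approached=lv.approached,
                    population_based=c.population_based,
                )
            )
    cols = RECRUITMENT_COLUMNS + ["population_based"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
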