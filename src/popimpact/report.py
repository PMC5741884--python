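"""Summary-table and decomposition rendering.

Rendering is pure formatting of the unrounded estimates: uptake to whole
percent, impact to one decimal percent (configurable through
:class:`~popimpact.trial_io.RunConfig`), so re-rendering is idempotent and
nothing downstream ever consumes a rounded number.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .effectiveness import EffectEstimate
from .impact import ImpactEstimate
from .trial_io import RunConfig
from .uptake import UptakeEstimate

SUMMARY_COLUMNS = [
    "intervention_id", "rr", "rr_ci", "rrr_pct",
    "participating", "potential", "uptake_pct", "uptake_ci_pct",
    "impact_pct", "rank",
]


def _pct(x: float, decimals: int) -> float:
    return round(100.0 * x, decimals) if decimals > 0 else int(round(100.0 * x))


def render_summary_table(
    effects: Sequence[EffectEstimate],
    uptakes: Sequence[UptakeEstimate],
    impacts: Sequence[ImpactEstimate],
    config: Optional[RunConfig] = None,
) -> tuple[pd.DataFrame, list[str]]:
    """One row per intervention with effectiveness, uptake and impact columns,
    plus footnotes recording CI methods, denominator scaling and floored bounds.
    """
    config = config or RunConfig()
    e_by = {e.intervention_id: e for e in effects}
    u_by = {u.intervention_id: u for u in uptakes}
    i_by = {i.intervention_id: i for i in impacts}
    unmatched = (set(e_by) | set(u_by) | set(i_by)) - (set(e_by) & set(u_by) & set(i_by))
    if unmatched:
        raise ValueError(f"intervention ids not present in all inputs: {sorted(unmatched)}")

    ud, idec = config.uptake_decimals, config.impact_decimals
    rows, footnotes = [], []
    order = sorted(i_by.values(), key=lambda i: (i.rank if i.rank is not None else 0))
    for imp in order:
        e, u = e_by[imp.intervention_id], u_by[imp.intervention_id]
        rows.append(
            dict(
                intervention_id=imp.intervention_id,
                rr=round(e.pooled_rr, 2),
                rr_ci=f"({e.ci[0]:.2f}-{e.ci[1]:.2f})",
                rrr_pct=_pct(e.rrr, 0),
                participating=u.numerator,
                potential=u.effective_denominator,
                uptake_pct=_pct(u.proportion, ud),
                uptake_ci_pct=f"({_pct(u.ci[0], ud)}-{_pct(u.ci[1], ud)})",
                impact_pct=_pct(imp.impact, idec),
                rank=imp.rank,
            )
        )
        if u.ci[0] == 0.0:
            footnotes.append(f"{imp.intervention_id}: lower CI set as >=0")
        if u.method == "pooled_glmm":
            footnotes.append(
                f"{imp.intervention_id}: totals across trials, combined in a "
                "logistic regression model with random intercepts"
            )
        nested = u.method == "single_trial" and u.effective_denominator != u.numerator \
            and u.ci_method in ("clopper_pearson", "wilson", "wald")
        if nested:
            footnotes.append(
                f"{imp.intervention_id}: CI method {u.ci_method} on "
                f"{u.numerator}/{u.effective_denominator}"
            )
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return df, footnotes


def render_decomposition(impacts: Sequence[ImpactEstimate]) -> pd.DataFrame:
    """Long-format encounter decomposition: three rows per intervention whose
    fractions sum to 1 (averted / uptake_no_effect / no_uptake)."""
    rows = []
    for imp in impacts:
        for stratum, frac in zip(("averted", "uptake_no_effect", "no_uptake"), imp.strata):
            rows.append(dict(intervention_id=imp.intervention_id,
                             stratum=stratum, fraction=frac))
    return pd.DataFrame(rows, columns=["intervention_id", "stratum", "fraction"])


def to_tsv(df: pd.DataFrame, footnotes: Sequence[str] = ()) -> str:
    text = df.to_csv(sep="\t", index=False)
    if footnotes:
        text += "".join(f"# {f}\n" for f in footnotes)
    return text


def to_markdown(df: pd.DataFrame, footnotes: Sequence[str] = ()) -> str:
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        lines.append("| " + " | ".join(str(row[c]) for c in cols) + " |")
    text = "\n".join(lines)
    if footnotes:
        text += "\n\n" + "\n".join(f"*{f}*" for f in footnotes)
    return text + "\n"
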