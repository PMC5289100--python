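"""Summary statistics: group means, binocular summation ratios, mixed ANOVA.

Acuity is carried in logMAR throughout; ratio-scale quantities are derived by
exponentiation.  The binocular summation ratio is monocular MAR divided by
binocular MAR, i.e. 10^(monocular logMAR - binocular logMAR); values above 1
mean binocular viewing improved acuity.  Because the ratio is a nonlinear
(exponential) function of the logMAR difference, the group mean of
per-participant ratios generally differs from the ratio implied by the group
mean logMARs; both aggregations are provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = [
    "SummationResult",
    "GroupSummary",
    "AnovaResult",
    "summation_ratio",
    "group_fold_difference",
    "summarize_groups",
    "summation_table",
    "mixed_anova",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SummationResult:
    participant_id: str
    stimulus_type: str
    monocular_logmar: float
    binocular_logmar: float
    ratio: float


@dataclass(frozen=True)
class GroupSummary:
    group: str
    condition: tuple
    mean: float
    se: float
    n: int


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_between: int
    df_within: int
    p: float


def summation_ratio(monocular_logmar: float, binocular_logmar: float) -> float:
    """Binocular summation ratio = monocular MAR / binocular MAR."""
    return 10.0 ** (monocular_logmar - binocular_logmar)


def group_fold_difference(logmar_a: float, logmar_b: float) -> tuple[float, float]:
    """Fold-difference 10^(a-b) between two acuities, plus the raw logMAR difference."""
    diff = logmar_a - logmar_b
    return 10.0 ** diff, diff


def summarize_groups(cohort_result: pd.DataFrame) -> pd.DataFrame:
    """Per group x stimulus-type x viewing cell: mean, SE (sd/sqrt(n)) and n.

    Every combination of the groups, stimulus types and viewing conditions
    present in the data must be populated with at least two participants.
    """
    cols = ["group", "stimulus_type", "viewing"]
    expected = [
        (g, s, v)
        for g in cohort_result["group"].unique()
        for s in cohort_result["stimulus_type"].unique()
        for v in cohort_result["viewing"].unique()
    ]
    grouped = cohort_result.groupby(cols)["threshold_logmar"]
    rows = []
    for cell in expected:
        if cell not in grouped.groups:
            raise ValueError(f"empty cell {cell} in cohort result")
        vals = grouped.get_group(cell).to_numpy(float)
        if vals.size < 2:
            raise ValueError(f"cell {cell} has {vals.size} value(s); need >= 2 for an SE")
        rows.append(
            {
                "group": cell[0],
                "stimulus_type": cell[1],
                "viewing": cell[2],
                "mean_logmar": float(vals.mean()),
                "se_logmar": float(vals.std(ddof=1) / np.sqrt(vals.size)),
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def summation_table(cohort_result: pd.DataFrame) -> pd.DataFrame:
    """Binocular summation ratios, aggregated mean +/- SE per group x stimulus type.

    Ratios are computed per participant first (10^(mono - bino)) and then
    averaged — the aggregation a per-participant table implies — so the group
    mean ratio is a mean of ratios, not the ratio of group mean MARs.
    """
    wide = cohort_result.pivot_table(
        index=["participant_id", "group", "stimulus_type"],
        columns="viewing",
        values="threshold_logmar",
    ).reset_index()
    if "monocular" not in wide or "binocular" not in wide or wide[["monocular", "binocular"]].isna().any().any():
        raise ValueError("summation table needs both monocular and binocular thresholds per participant")
    wide["ratio"] = 10.0 ** (wide["monocular"] - wide["binocular"])
    out = (
        wide.groupby(["group", "stimulus_type"])["ratio"]
        .agg(
            mean_ratio="mean",
            se_ratio=lambda x: x.std(ddof=1) / np.sqrt(len(x)),
            n="size",
        )
        .reset_index()
    )
    return out


def paired_nd_test(nd_control: pd.DataFrame) -> pd.DataFrame:
    """Paired t-test of with- vs without-filter thresholds, per condition.

    Expects the stacked output of a neutral-density re-test (both
    ``nd_filter`` values present for the same participants); returns the
    mean paired difference (with - without, logMAR), t and p per
    stimulus-type x viewing cell.
    """
    from scipy import stats

    wide = nd_control.pivot_table(
        index=["participant_id", "stimulus_type", "viewing"],
        columns="nd_filter",
        values="threshold_logmar",
    ).reset_index()
    if True not in wide.columns or False not in wide.columns:
        raise ValueError("nd control table needs both filtered and unfiltered thresholds")
    rows = []
    for (stim, view), cell in wide.groupby(["stimulus_type", "viewing"]):
        diff = cell[True].to_numpy(float) - cell[False].to_numpy(float)
        t, p = stats.ttest_rel(cell[True], cell[False])
        rows.append(
            {
                "stimulus_type": stim,
                "viewing": view,
                "mean_diff_logmar": float(diff.mean()),
                "t": float(t),
                "p": float(p),
                "n": int(len(diff)),
            }
        )
    return pd.DataFrame(rows)


def mixed_anova(
    table: pd.DataFrame,
    within_factor: str,
    between_factor: str,
    dv: str = "threshold_logmar",
    subject: str = "participant_id",
) -> list[AnovaResult]:
    """Two-way mixed-design ANOVA (one between-subject, one within-subject factor).

    Requires a balanced design: exactly one value per subject x within-level
    and the same number of subjects in every between-group.  Returns the
    between main effect, the within main effect and their interaction.
    """
    import pingouin as pg

    counts = table.groupby([subject, within_factor], observed=True)[dv].count()
    if (counts != 1).any():
        bad = counts[counts != 1].index[0]
        raise ValueError(f"unbalanced design: subject x within cell {bad} has {counts.max()} values")
    per_group = table.groupby(between_factor, observed=True)[subject].nunique()
    if per_group.nunique() != 1:
        raise ValueError(f"unbalanced design: group sizes {per_group.to_dict()}")

    aov = pg.mixed_anova(
        data=table, dv=dv, within=within_factor, between=between_factor, subject=subject
    )
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    results = []
    for _, row in aov.iterrows():
        results.append(
            AnovaResult(
                effect=str(row["Source"]),
                F=float(row["F"]),
                df_between=int(row["DF1"]),
                df_within=int(row["DF2"]),
                p=float(row[p_col]),
            )
        )
    return results
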