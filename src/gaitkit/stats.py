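"""Statistical decision pipeline for gait parameter tables.

The procedure mirrors common practice for longitudinal walkway studies:

1. per (parameter, paw), a two-way mixed-design ANOVA (within = week,
   between = treatment group) with a Mauchly sphericity check and
   Greenhouse-Geisser correction of the within and interaction terms
   when sphericity fails (p <= 0.05);
2. when the week x group interaction is significant, per-week pairwise
   group comparisons, choosing an unequal-variance procedure
   (Games-Howell, the Welch-type analogue of the Dunnett T3 family)
   when Levene's test rejects homogeneity and Tukey's HSD otherwise;
   when the interaction is not significant, only the treatment main
   effect is reported;
3. diagonal vs. diagonal phase-dispersion comparisons by paired t-test
   within each group at each week, preceded by Pearson correlations of
   each dispersion variable with average body speed;
4. Pearson correlations of TH+ neuron counts with the week-6 means of
   27 gait parameters, labeled strong / moderate / none by |r|.

Significance is 0.05 two-sided throughout, with no multiple-testing
correction across parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .errors import InsufficientDataError, UndefinedCorrelationError
from .reference import TH_CORRELATION_PARAMETERS

__all__ = [
    "AnovaResult",
    "CorrelationResult",
    "rm_anova",
    "posthoc",
    "phase_dispersion_paired_test",
    "pd_speed_correlations",
    "th_correlations",
    "strength_classifier",
    "ALPHA",
]

ALPHA = 0.05


@dataclass(frozen=True)
class AnovaResult:
    """Mixed-design ANOVA summary for one parameter/paw."""

    parameter: str
    paw: str
    F: float                # interaction F
    df_num: float           # possibly epsilon-scaled, hence non-integer
    df_den: float
    p_interaction: float
    p_treatment_main: float
    F_treatment: float
    gg_applied: bool
    epsilon: Optional[float] = None


@dataclass(frozen=True)
class CorrelationResult:
    parameter: str
    paw: str
    r: float
    p: float
    strength: str  # 'strong' | 'moderate' | 'none'
    n: int = 0


def _complete_cases(table: pd.DataFrame) -> pd.DataFrame:
    """Drop animals that miss any week (listwise deletion)."""
    weeks = set(table["week"].unique())
    counts = table.groupby("animal_id")["week"].agg(lambda w: set(w) == weeks)
    keep = counts[counts].index
    return table[table["animal_id"].isin(keep)]


def rm_anova(
    table: pd.DataFrame, parameter: str = "", paw: str = "all"
) -> AnovaResult:
    """Two-way mixed ANOVA (within = week, between = group).

    ``table`` needs columns animal_id, group, week, value.  Animals with
    missing weeks are dropped listwise.  Sphericity of the within factor
    is tested with Mauchly's W; on violation (p <= 0.05) the
    Greenhouse-Geisser epsilon rescales the within and interaction
    degrees of freedom and p-values.
    """
    df = _complete_cases(table)
    groups = df["group"].unique()
    weeks = df["week"].unique()
    if len(groups) < 2 or len(weeks) < 2:
        raise InsufficientDataError("need >= 2 groups and >= 2 weeks")
    per_group = df.groupby("group")["animal_id"].nunique()
    if (per_group < 2).any():
        raise InsufficientDataError("need >= 2 complete animals per group")
    aov = pg.mixed_anova(
        data=df,
        dv="value",
        within="week",
        subject="animal_id",
        between="group",
        correction=True,
    ).set_index("Source")
    inter = aov.loc["Interaction"]
    week_row = aov.loc["week"]
    group_row = aov.loc["group"]
    spher_ok = bool(week_row.get("sphericity", True))
    eps = week_row.get("eps", np.nan)
    gg_applied = (not spher_ok) and np.isfinite(eps)
    df1, df2 = float(inter["DF1"]), float(inter["DF2"])
    f_inter = float(inter["F"])
    if gg_applied:
        df1, df2 = df1 * eps, df2 * eps
        p_inter = float(sps.f.sf(f_inter, df1, df2))
    else:
        p_inter = float(inter["p_unc"])
    return AnovaResult(
        parameter=parameter,
        paw=paw,
        F=f_inter,
        df_num=df1,
        df_den=df2,
        p_interaction=p_inter,
        p_treatment_main=float(group_row["p_unc"]),
        F_treatment=float(group_row["F"]),
        gg_applied=gg_applied,
        epsilon=float(eps) if np.isfinite(eps) else None,
    )


def posthoc(table: pd.DataFrame, anova: AnovaResult) -> pd.DataFrame:
    """Levene-gated pairwise comparisons, or the main effect alone.

    Significant interaction (p <= 0.05): per-week pairwise group
    comparisons, Games-Howell under heteroscedasticity (Levene p <=
    0.05), Tukey HSD otherwise.  Non-significant interaction: a single
    main-effect row, no per-week table.
    """
    df = _complete_cases(table)
    if anova.p_interaction > ALPHA:
        return pd.DataFrame(
            [
                dict(
                    week=-1,  # sentinel: pooled over weeks
                    A="treatment",
                    B="main-effect",
                    test="main_effect",
                    levene_p=math.nan,
                    pval=anova.p_treatment_main,
                    significant=anova.p_treatment_main <= ALPHA,
                )
            ]
        )
    rows = []
    for week, sub in df.groupby("week"):
        samples = [g["value"].to_numpy() for _, g in sub.groupby("group")]
        levene_p = float(sps.levene(*samples, center="mean").pvalue)
        if levene_p <= ALPHA:
            pc = pg.pairwise_gameshowell(data=sub, dv="value", between="group")
            pcol, test = "pval", "games_howell"
        else:
            pc = pg.pairwise_tukey(data=sub, dv="value", between="group")
            pcol, test = "p_tukey", "tukey"
        for _, r in pc.iterrows():
            rows.append(
                dict(
                    week=week,
                    A=r["A"],
                    B=r["B"],
                    test=test,
                    levene_p=levene_p,
                    pval=float(r[pcol]),
                    significant=float(r[pcol]) <= ALPHA,
                )
            )
    return pd.DataFrame(rows)


def phase_dispersion_paired_test(
    values_a: Sequence[float], values_b: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided paired t-test between two phase-dispersion axes.

    ``values_a``/``values_b`` are per-animal means, paired by animal,
    within one group at one week.  Identical vectors return (0, 1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if len(a) < 3:
        raise InsufficientDataError("paired t-test needs n >= 3")
    diffs = a - b
    if np.all(diffs == 0):
        return 0.0, 1.0
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def pd_speed_correlations(
    pd_table: pd.DataFrame, speed_col: str = "average_speed"
) -> pd.DataFrame:
    """Pearson correlation of each phase-dispersion variable with speed.

    The preliminary check run before the paired comparisons: columns of
    ``pd_table`` other than ``speed_col`` are correlated against it.
    """
    rows = []
    speed = pd_table[speed_col].to_numpy(dtype=float)
    for col in pd_table.columns:
        if col == speed_col:
            continue
        vals = pd_table[col].to_numpy(dtype=float)
        mask = np.isfinite(vals) & np.isfinite(speed)
        if mask.sum() < 3 or np.std(vals[mask]) == 0 or np.std(speed[mask]) == 0:
            r, p = math.nan, math.nan
        else:
            res = sps.pearsonr(vals[mask], speed[mask])
            r, p = float(res.statistic), float(res.pvalue)
        rows.append(dict(variable=col, r=r, p=p, n=int(mask.sum())))
    return pd.DataFrame(rows)


def strength_classifier(
    r: float, p: Optional[float] = None, strong: float = 0.60, moderate: float = 0.40
) -> str:
    """Label a correlation by |r|: >=0.60 strong, >=0.40 moderate, else none.

    The thresholds are configuration constants; the defaults reproduce
    the published strong/none partition of the reference correlation
    table.  The p-value is carried along but does not enter the label.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation coefficient outside [-1, 1]: {r}")
    if abs(r) >= strong:
        return "strong"
    if abs(r) >= moderate:
        return "moderate"
    return "none"


def th_correlations(
    th_counts: Mapping[str, float],
    week6_means: pd.DataFrame,
    parameters: Iterable[Tuple[str, str]] = TH_CORRELATION_PARAMETERS,
) -> List[CorrelationResult]:
    """Correlate TH+ neuron counts with week-6 gait parameter means.

    ``week6_means`` needs columns animal_id, parameter, paw, value (one
    row per animal and parameter).  Animals appear in the correlation
    only when both the count and the parameter mean are present; fewer
    than 4 pairs or a zero-variance vector is an error.
    """
    results = []
    for parameter, paw in parameters:
        sub = week6_means[
            (week6_means["parameter"] == parameter) & (week6_means["paw"] == paw)
        ]
        pairs = [
            (th_counts[a], v)
            for a, v in zip(sub["animal_id"], sub["value"])
            if a in th_counts and np.isfinite(v)
        ]
        if len(pairs) < 4:
            raise InsufficientDataError(
                f"{parameter}/{paw}: need >= 4 paired observations, got {len(pairs)}"
            )
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if np.std(x) == 0 or np.std(y) == 0:
            raise UndefinedCorrelationError(
                f"{parameter}/{paw}: zero variance in a correlated vector"
            )
        res = sps.pearsonr(x, y)
        r, p = float(res.statistic), float(res.pvalue)
        results.append(
            CorrelationResult(
                parameter=parameter,
                paw=paw,
                r=r,
                p=p,
                strength=strength_classifier(r, p),
                n=len(pairs),
            )
        )
    return results
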