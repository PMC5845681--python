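"""Study-level orchestration: runs -> parameter table -> analysis report.

Glues the per-run parameter engine to the QC/normalization rules and the
statistical pipeline:

1. run-level QC (interruptions, minimum step cycles);
2. per-run parameter extraction, then per-animal session means;
3. animal-week speed classification; animals walking below 20 cm/s at a
   week drop out of that week entirely;
4. per-week speed normalization of the six speed-associated parameters;
5. mixed-design ANOVA + gated post-hocs per parameter/paw, paired
   diagonal phase-dispersion tests, and TH-count correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .core import ParameterRecord, Run
from .errors import InsufficientDataError
from .params import summarize_run
from .qc import (
    NormalizationContext,
    RejectedRun,
    SpeedClass,
    apply_speed_normalization,
    classify_speed,
    proportion_slow,
    qc_filter_runs,
    remove_outliers,
)
from . import stats as gstats

__all__ = ["compute_parameter_table", "analyze_study", "AnalysisReport", "records_to_frame"]

log = logging.getLogger(__name__)


def records_to_frame(records: Iterable[ParameterRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                animal_id=r.animal_id,
                group=r.group,
                week=r.week,
                run_id=r.run_id,
                parameter=r.parameter,
                paw=r.paw,
                value=r.value,
                normalized=r.normalized,
            )
            for r in records
        ]
    )


def compute_parameter_table(
    runs: Iterable[Run],
    normalization: str = "corrective",
    min_cycles: int = 3,
    parameters: Optional[set] = None,
    pd_wrap: bool = False,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Runs in, per-animal-week parameter table out.

    Returns ``(table, qc_log)``.  The table holds animal-week means
    (run_id = "animal-mean") with speed normalization applied per week
    (``normalization`` in {'corrective', 'verbatim', 'off'}); the QC log
    lists every rejected run and every animal-week dropped for slow
    walking, with reason codes.
    """
    accepted, rejected = qc_filter_runs(runs, min_cycles=min_cycles)
    qc_rows = [
        dict(
            animal_id=rr.run.animal_id,
            week=rr.run.week,
            run_id=rr.run.run_id,
            reason=rr.reason,
        )
        for rr in rejected
    ]
    if not accepted:
        return pd.DataFrame(), pd.DataFrame(qc_rows)

    per_run = records_to_frame(
        rec for run in accepted for rec in summarize_run(run, parameters, pd_wrap)
    )
    # session means across a week's accepted runs
    means = (
        per_run.groupby(
            ["animal_id", "group", "week", "parameter", "paw"], as_index=False
        )["value"]
        .mean()
        .assign(run_id="animal-mean", normalized=False)
    )

    # animal-week speed classification; <20 cm/s drops the whole session
    speeds = (
        means[means["parameter"] == "average_speed"]
        .set_index(["animal_id", "week"])["value"]
        .to_dict()
    )
    excluded = {
        key for key, v in speeds.items() if classify_speed(v) is SpeedClass.EXCLUDED_LT20
    }
    for animal_id, week in sorted(excluded):
        qc_rows.append(
            dict(animal_id=animal_id, week=week, run_id="animal-mean", reason="slow_animal")
        )
    if excluded:
        mask = [
            (a, w) not in excluded for a, w in zip(means["animal_id"], means["week"])
        ]
        means = means[mask]

    # per-week normalization over all included animals (groups pooled)
    out_frames = []
    for week, sub in means.groupby("week"):
        week_speeds = {
            a: v for (a, w), v in speeds.items() if w == week and (a, w) not in excluded
        }
        recs = [
            ParameterRecord(
                animal_id=r.animal_id,
                group=r.group,
                week=int(r.week),
                run_id=r.run_id,
                parameter=r.parameter,
                paw=r.paw,
                value=r.value,
            )
            for r in sub.itertuples()
        ]
        if normalization != "off":
            ctx = NormalizationContext.from_speeds(int(week), week_speeds)
            recs = apply_speed_normalization(recs, ctx, direction=normalization)
        out_frames.append(records_to_frame(recs))
    table = pd.concat(out_frames, ignore_index=True)
    return table, pd.DataFrame(qc_rows)


@dataclass
class AnalysisReport:
    """Per-parameter statistical results for one study."""

    anova: pd.DataFrame
    posthoc: pd.DataFrame
    phase_dispersion_tests: pd.DataFrame
    pd_speed_correlations: pd.DataFrame
    correlations: pd.DataFrame
    slow_proportions: pd.DataFrame


_ANOVA_PARAMS = [
    ("average_speed", "all"),
    ("cadence", "all"),
    ("run_duration", "all"),
    *[(p, paw) for p in ("step_cycle", "stand", "swing", "stride_length",
                          "initial_dual_stance", "stand_index", "print_length",
                          "print_area") for paw in ("LF", "RF", "LH", "RH")],
    ("print_position", "LF"),
    ("print_position", "RF"),
]


def analyze_study(
    table: pd.DataFrame,
    th_counts: Optional[Mapping[str, float]] = None,
    outlier_sd: Optional[float] = 2.0,
    correlation_groups: Tuple[str, ...] = ("mfb", "sham_mfb"),
    correlation_table: Optional[pd.DataFrame] = None,
) -> AnalysisReport:
    """Run the full statistical pipeline on an animal-week parameter table.

    Outliers beyond ``outlier_sd`` sample SDs are removed within each
    (group, week, parameter, paw) cell of animal means before testing
    (pass ``None`` to skip).  TH correlations use week-6 means of the
    named cohorts when counts are supplied; ``correlation_table`` lets
    the caller supply a separate (typically raw, un-normalized) table
    for that step — the published sign pattern (slower, longer cycles
    and larger dual stance with fewer surviving TH+ neurons) refers to
    the raw time scales, which per-week speed normalization distorts.
    """
    df = table.copy()
    if outlier_sd is not None:
        kept = []
        for _, cell in df.groupby(["group", "week", "parameter", "paw"]):
            vals = cell["value"].tolist()
            if len(vals) >= 3:
                retained = set()
                good = remove_outliers(vals, n_sd=outlier_sd)
                counts: Dict[float, int] = {}
                for v in good:
                    counts[v] = counts.get(v, 0) + 1
                rows = []
                for idx, v in zip(cell.index, vals):
                    if counts.get(v, 0) > 0:
                        counts[v] -= 1
                        rows.append(idx)
                kept.extend(rows)
            else:
                kept.extend(cell.index)
        df = df.loc[sorted(kept)]

    anova_rows, posthoc_frames = [], []
    for parameter, paw in _ANOVA_PARAMS:
        sub = df[(df["parameter"] == parameter) & (df["paw"] == paw)]
        if sub.empty:
            continue
        try:
            res = gstats.rm_anova(sub, parameter=parameter, paw=paw)
        except InsufficientDataError as exc:
            log.warning("ANOVA skipped for %s/%s: %s", parameter, paw, exc)
            continue
        anova_rows.append(
            dict(
                parameter=parameter,
                paw=paw,
                F=res.F,
                df_num=res.df_num,
                df_den=res.df_den,
                p_interaction=res.p_interaction,
                p_treatment_main=res.p_treatment_main,
                F_treatment=res.F_treatment,
                gg_applied=res.gg_applied,
                epsilon=res.epsilon,
            )
        )
        ph = gstats.posthoc(sub, res)
        ph.insert(0, "parameter", parameter)
        ph.insert(1, "paw", paw)
        posthoc_frames.append(ph)

    # paired diagonal phase-dispersion comparison per group x week
    diag_a, diag_b = "phase_dispersion_diag_LF_RH", "phase_dispersion_diag_RF_LH"
    pd_rows = []
    pivot = df[df["parameter"].isin([diag_a, diag_b])].pivot_table(
        index=["group", "week", "animal_id"], columns="parameter", values="value"
    )
    for (group, week), sub in pivot.groupby(level=["group", "week"]):
        sub = sub.dropna()
        if len(sub) < 3:
            continue
        t, p = gstats.phase_dispersion_paired_test(sub[diag_a], sub[diag_b])
        pd_rows.append(
            dict(
                group=group,
                week=week,
                n=len(sub),
                mean_LF_RH=float(sub[diag_a].mean()),
                mean_RF_LH=float(sub[diag_b].mean()),
                t=t,
                p=p,
                significant=p <= gstats.ALPHA,
            )
        )

    # preliminary check: dispersion variables vs average body speed
    pd_cols = [c for c in df["parameter"].unique() if c.startswith("phase_dispersion")]
    speed_pivot = df[df["parameter"].isin(pd_cols + ["average_speed"])].pivot_table(
        index="animal_id", columns="parameter", values="value"
    )
    if "average_speed" in speed_pivot:
        pd_speed = gstats.pd_speed_correlations(speed_pivot, "average_speed")
    else:
        pd_speed = pd.DataFrame()

    # TH correlations at week 6
    corr_rows = []
    if th_counts is not None:
        corr_src = correlation_table if correlation_table is not None else df
        wk6 = corr_src[
            (corr_src["week"] == 6) & (corr_src["group"].isin(correlation_groups))
        ]
        present = {
            (p, w)
            for p, w in gstats.TH_CORRELATION_PARAMETERS
            if not wk6[(wk6["parameter"] == p) & (wk6["paw"] == w)].empty
        }
        for res in gstats.th_correlations(
            th_counts, wk6, parameters=[pp for pp in gstats.TH_CORRELATION_PARAMETERS if pp in present]
        ):
            corr_rows.append(
                dict(
                    parameter=res.parameter,
                    paw=res.paw,
                    r=res.r,
                    p=res.p,
                    strength=res.strength,
                    n=res.n,
                )
            )

    # proportion of slow walkers per group and week
    slow_rows = []
    speeds = df[df["parameter"] == "average_speed"]
    for (group, week), sub in speeds.groupby(["group", "week"]):
        classes = [classify_speed(v) for v in sub["value"]]
        slow_rows.append(
            dict(group=group, week=week, pct_slow=proportion_slow(classes), n=len(classes))
        )

    return AnalysisReport(
        anova=pd.DataFrame(anova_rows),
        posthoc=pd.concat(posthoc_frames, ignore_index=True)
        if posthoc_frames
        else pd.DataFrame(),
        phase_dispersion_tests=pd.DataFrame(pd_rows),
        pd_speed_correlations=pd_speed,
        correlations=pd.DataFrame(corr_rows),
        slow_proportions=pd.DataFrame(slow_rows),
    )
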