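"""Run inclusion rules, speed classification, speed normalization, outliers.

Inclusion follows standard walkway practice: interrupted crossings are
discarded, leading/trailing partial prints are trimmed, and a run must
carry at least three complete step cycles on every paw.  Animals whose
session-mean speed falls below 20 cm/s are excluded from speed and all
speed-associated statistics (such slow crossings reflect explorative
behavior rather than walking); 20-50 cm/s counts as slow walking and
above 50 cm/s as normal.

Six parameters known to co-vary with speed (step cycle, stand, swing,
stride length, print position, cadence) are normalized per timepoint
with the factor ``F_n = V_n / averageV`` (individual session speed over
the cohort mean).  Two directions are offered:

* ``"verbatim"`` multiplies all six by ``F_n``, the single-factor rule
  as conventionally stated;
* ``"corrective"`` (default) multiplies the speed-inverse parameters
  (step cycle, stand, swing) by ``F_n`` but the speed-proportional ones
  (stride length, print position, cadence) by ``1 / F_n`` — the
  direction that actually removes the speed confound from each side.

The verbatim rule de-confounds only the speed-inverse parameters and
amplifies the speed of the others; both behaviors are kept because the
single-factor rule is what published walkway analyses apply.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, List, Mapping, Sequence, Tuple

from .core import ParameterRecord, PawLabel, Run  # noqa: F401 - Run in annotations
from .errors import ValidationError
from .params import segment_step_cycles

__all__ = [
    "SpeedClass",
    "NormalizationContext",
    "SPEED_NORMALIZED_PARAMETERS",
    "SPEED_INVERSE_PARAMETERS",
    "qc_filter_runs",
    "RejectedRun",
    "classify_speed",
    "proportion_slow",
    "apply_speed_normalization",
    "remove_outliers",
]

log = logging.getLogger(__name__)

#: The six speed-associated parameters that get normalized.
SPEED_NORMALIZED_PARAMETERS = frozenset(
    {"step_cycle", "stand", "swing", "stride_length", "print_position", "cadence"}
)
#: Of those, the ones inversely related to speed (longer when slower).
SPEED_INVERSE_PARAMETERS = frozenset({"step_cycle", "stand", "swing"})


class SpeedClass(str, enum.Enum):
    EXCLUDED_LT20 = "excluded_lt20"
    SLOW_20_50 = "slow_20_50"
    NORMAL_GT50 = "normal_gt50"


def classify_speed(animal_mean_speed: float) -> SpeedClass:
    """Classify a session-mean speed: <20 excluded, 20-50 slow, >50 normal."""
    if animal_mean_speed < 0:
        raise ValidationError("speed must be non-negative")
    if animal_mean_speed < 20.0:
        return SpeedClass.EXCLUDED_LT20
    if animal_mean_speed <= 50.0:
        return SpeedClass.SLOW_20_50
    return SpeedClass.NORMAL_GT50


def proportion_slow(classes: Iterable[SpeedClass]) -> float:
    """Percentage of slow walkers among classified (non-excluded) animals.

    Excluded animals leave both numerator and denominator.  Returns NaN
    when no animal remains classifiable.
    """
    classes = list(classes)
    slow = sum(c is SpeedClass.SLOW_20_50 for c in classes)
    normal = sum(c is SpeedClass.NORMAL_GT50 for c in classes)
    if slow + normal == 0:
        log.warning("proportion_slow: no classifiable animals; reporting missing")
        return math.nan
    return 100.0 * slow / (slow + normal)


@dataclass(frozen=True)
class RejectedRun:
    run: Run
    reason: str  # machine-readable: 'interrupted' | 'too_few_cycles' | 'slow_animal'


def _trim_edge_prints(run: Run, edge_trim_cm: float) -> Run:
    """Drop prints within ``edge_trim_cm`` of either walkway end.

    Stands in for the removal of partial prints at run boundaries: a
    print cut by the recording window sits at the very edge of the
    walkway.  With the default margin of 0 nothing is trimmed.
    """
    if edge_trim_cm <= 0:
        return run
    kept = [
        c
        for c in run.contacts
        if edge_trim_cm <= c.x <= run.walkway_length - edge_trim_cm
    ]
    return replace(run, contacts=kept)


def qc_filter_runs(
    runs: Iterable[Run], min_cycles: int = 3, edge_trim_cm: float = 0.0
) -> Tuple[List[Run], List[RejectedRun]]:
    """Apply run-level inclusion rules.

    Rejects interrupted runs and runs with fewer than ``min_cycles``
    complete step cycles on any paw (after edge trimming).  Every
    rejection carries a machine-readable reason code.
    """
    accepted, rejected = [], []
    for run in runs:
        if run.interrupted:
            rejected.append(RejectedRun(run, "interrupted"))
            continue
        trimmed = _trim_edge_prints(run, edge_trim_cm)
        n_cycles = min(len(segment_step_cycles(trimmed, paw)) for paw in PawLabel)
        if n_cycles < min_cycles:
            rejected.append(RejectedRun(run, "too_few_cycles"))
            continue
        accepted.append(trimmed)
    return accepted, rejected


@dataclass(frozen=True)
class NormalizationContext:
    """Per-timepoint speed normalization factors.

    ``speeds`` maps animal -> session-mean speed ``V_n`` over accepted
    runs; ``average_v`` is the mean of ``V_n`` over all included animals
    at this week (sham and lesion pooled); ``factors`` holds
    ``F_n = V_n / average_v``, which average to 1 by construction.
    """

    week: int
    speeds: Mapping[str, float]
    average_v: float
    factors: Mapping[str, float]

    @classmethod
    def from_speeds(cls, week: int, speeds: Mapping[str, float]) -> "NormalizationContext":
        if not speeds:
            raise ValidationError("cannot build normalization context without animals")
        average_v = sum(speeds.values()) / len(speeds)
        if average_v <= 0:
            raise ValidationError("average speed must be positive")
        factors = {a: v / average_v for a, v in speeds.items()}
        return cls(week=week, speeds=dict(speeds), average_v=average_v, factors=factors)


def apply_speed_normalization(
    records: Iterable[ParameterRecord],
    context: NormalizationContext,
    direction: str = "corrective",
) -> List[ParameterRecord]:
    """Normalize the six speed-associated parameters of one timepoint.

    Parameters outside the six pass through unchanged.  An animal with a
    speed-associated record but no factor in the context is an error.
    """
    if direction not in ("corrective", "verbatim"):
        raise ValidationError(f"unknown normalization direction: {direction!r}")
    out = []
    for rec in records:
        if rec.parameter not in SPEED_NORMALIZED_PARAMETERS:
            out.append(rec)
            continue
        if rec.animal_id not in context.factors:
            raise ValidationError(
                f"animal {rec.animal_id} missing from week-{context.week} "
                "normalization context"
            )
        f = context.factors[rec.animal_id]
        if direction == "verbatim" or rec.parameter in SPEED_INVERSE_PARAMETERS:
            value = rec.value * f
        else:
            value = rec.value / f
        out.append(replace(rec, value=value, normalized=True))
    return out


def remove_outliers(values: Sequence[float], n_sd: float = 2.0) -> List[float]:
    """Single-pass removal of values beyond ``n_sd`` sample SDs of the mean.

    Applied within a (group, week, parameter, paw) cell of animal-level
    means.  Cells with fewer than 3 values pass through unchanged with a
    warning; the mean/SD are computed once and not re-iterated.
    """
    values = list(values)
    if len(values) < 3:
        warnings.warn("outlier removal skipped: fewer than 3 values", stacklevel=2)
        return values
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    if sd == 0:
        return values
    return [v for v in values if abs(v - mean) <= n_sd * sd]
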