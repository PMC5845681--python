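"""Gait parameter computation from a single walkway crossing.

Implements the classical CatWalk-style parameter set for quadruped gait:

* temporal: run duration, average speed, cadence, step cycle and its
  stand/swing decomposition, initial dual stance;
* spatial: stride length, print position, print length/area;
* coordination: inter-limb phase dispersion (target-paw initial contact
  expressed as a percentage of the anchor paw's step cycle; the anchor
  is always a front paw);
* stand index: the rate at which a paw releases contact at swing
  initiation, measured as the least-squares slope of the normalized
  contact-area decay (units 1/s; larger = faster lift-off).

All operations take a validated :class:`~gaitkit.core.Run` and are pure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

import numpy as np

from .core import ParameterRecord, PawContact, PawLabel, Run, StepCycle
from .errors import InsufficientDataError, UnsupportedMeasurementError, ValidationError

__all__ = [
    "run_duration",
    "average_speed",
    "segment_step_cycles",
    "cadence",
    "stride_lengths",
    "print_position",
    "initial_dual_stance",
    "stand_index",
    "phase_dispersion",
    "PhaseDispersionRecord",
    "print_geometry_means",
    "summarize_run",
    "PHASE_DISPERSION_PAIRS",
]

log = logging.getLogger(__name__)

#: Reported phase-dispersion pairs: two diagonal and two ipsilateral,
#: each anchored on a front paw.
PHASE_DISPERSION_PAIRS = {
    "phase_dispersion_diag_RF_LH": (PawLabel.RF, PawLabel.LH),
    "phase_dispersion_diag_LF_RH": (PawLabel.LF, PawLabel.RH),
    "phase_dispersion_ipsi_RF_RH": (PawLabel.RF, PawLabel.RH),
    "phase_dispersion_ipsi_LF_LH": (PawLabel.LF, PawLabel.LH),
}


def run_duration(run: Run) -> float:
    """Total crossing time in seconds (exit minus enter)."""
    return run.t_exit - run.t_enter


def average_speed(run: Run) -> float:
    """Mean body speed (cm/s): print span along the travel axis over duration."""
    if len(run.contacts) < 2:
        raise InsufficientDataError("average_speed needs at least 2 contacts")
    xs = [c.x for c in run.contacts]
    return (max(xs) - min(xs)) / (run.t_exit - run.t_enter)


def segment_step_cycles(run: Run, paw: PawLabel) -> List[StepCycle]:
    """Split a paw's prints into step cycles (consecutive IC to IC).

    The final print of the run has no successor and therefore yields no
    cycle, mirroring the removal of partial cycles at run boundaries.
    Fewer than two prints gives an empty list, not an error.
    """
    prints = run.contacts_of(paw)
    cycles = []
    for a, b in zip(prints, prints[1:]):
        if a.t_liftoff > b.t_contact:
            raise ValidationError(
                f"overlapping prints of paw {paw.value}: lift-off {a.t_liftoff} "
                f"after next initial contact {b.t_contact}"
            )
        stand = a.t_liftoff - a.t_contact
        duration = b.t_contact - a.t_contact
        cycles.append(
            StepCycle(
                paw=paw,
                t_start=a.t_contact,
                t_end=b.t_contact,
                stand=stand,
                swing=duration - stand,  # residual: stand + swing == duration exactly
            )
        )
    return cycles


def cadence(run: Run) -> float:
    """Steps per minute, counting initial contacts of all four paws."""
    duration = run_duration(run)
    return len(run.contacts) / duration * 60.0


def stride_lengths(run: Run, paw: PawLabel) -> List[float]:
    """Euclidean distances between consecutive print centroids of a paw."""
    prints = run.contacts_of(paw)
    return [
        math.hypot(b.x - a.x, b.y - a.y) for a, b in zip(prints, prints[1:])
    ]


def print_position(run: Run, side: str) -> List[float]:
    """Signed front-to-hind print distances (cm) for one body side.

    For each front print with step cycle ``[t0, t1)``, the first
    ipsilateral hind initial contact within the cycle is paired with it;
    the value is ``x_front - x_hind``, so positive means the hind paw
    landed behind the front paw and negative means overreach.  Front
    cycles without a hind contact in the window are skipped.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    front = PawLabel.LF if side == "left" else PawLabel.RF
    hind = front.ipsilateral_hind
    hind_prints = run.contacts_of(hind)
    values = []
    for front_print, cyc in zip(run.contacts_of(front), segment_step_cycles(run, front)):
        match = next(
            (h for h in hind_prints if cyc.t_start <= h.t_contact < cyc.t_end), None
        )
        if match is not None:
            values.append(front_print.x - match.x)
    return values


def initial_dual_stance(run: Run, paw: PawLabel) -> List[float]:
    """Per-cycle duration (s) of girdle-contralateral support at cycle start.

    At the initial contact opening a cycle of ``paw``, if the
    contralateral paw of the same girdle is on the glass, the value is
    the remaining contralateral stance time, clipped to this paw's own
    stand phase; otherwise 0.
    """
    partner_prints = run.contacts_of(paw.contralateral)
    values = []
    for cyc in segment_step_cycles(run, paw):
        t0 = cyc.t_start
        on_glass = next(
            (p for p in partner_prints if p.t_contact <= t0 < p.t_liftoff), None
        )
        values.append(min(on_glass.t_liftoff - t0, cyc.stand) if on_glass else 0.0)
    return values


def stand_index(contact: PawContact) -> float:
    """Release rate (1/s) of a print at swing initiation.

    The contact-area series is normalized to its maximum; a least-squares
    line is fit from the last time the area is maximal to lift-off, and
    the negated slope is returned.  Positive values mean faster release.
    """
    if contact.area_series is None:
        raise UnsupportedMeasurementError(
            "stand_index requires the contact-area time series"
        )
    series = contact.area_series
    if len(series) < 3:
        raise UnsupportedMeasurementError("area_series needs at least 3 samples")
    t = np.array([p[0] for p in series])
    a = np.array([p[1] for p in series])
    amax = a.max()
    peak_idx = int(np.nonzero(a >= amax * (1.0 - 1e-12))[0][-1])
    t_rel, a_rel = t[peak_idx:], a[peak_idx:] / amax
    if len(t_rel) < 2 or t_rel[-1] <= t_rel[0]:
        raise UnsupportedMeasurementError("zero-length release interval")
    slope = np.polyfit(t_rel - t_rel[0], a_rel, 1)[0]
    return -float(slope)


@dataclass(frozen=True)
class PhaseDispersionRecord:
    """Per-cycle phase dispersion values for one anchor/target pair."""

    anchor: PawLabel
    target: PawLabel
    values: Tuple[float, ...]
    pair_class: str  # 'diagonal', 'ipsilateral' or 'other'


def phase_dispersion(
    run: Run, anchor: PawLabel, target: PawLabel, wrap: bool = False
) -> PhaseDispersionRecord:
    """Target-paw initial contact as a percentage of the anchor step cycle.

    For each anchor cycle ``[t0, t1)`` containing a target initial
    contact, the first such contact gives
    ``(IC_target - t0) / (t1 - t0) * 100`` in ``[0, 100)``.  The anchor
    must be a front paw.  With ``wrap=True`` values are folded circularly
    into ``[-25, 75)`` (the conventional near-synchrony display window);
    the default reports the raw percentage.
    """
    if not anchor.is_front:
        raise ValueError("phase dispersion anchor must be a front paw")
    if target is anchor.diagonal:
        pair_class = "diagonal"
    elif target.is_left == anchor.is_left:
        pair_class = "ipsilateral"
    else:
        pair_class = "other"
    target_ics = [c.t_contact for c in run.contacts_of(target)]
    values = []
    for cyc in segment_step_cycles(run, anchor):
        ic = next((t for t in target_ics if cyc.t_start <= t < cyc.t_end), None)
        if ic is None:
            continue
        pd = (ic - cyc.t_start) / (cyc.t_end - cyc.t_start) * 100.0
        if wrap:
            pd = (pd + 25.0) % 100.0 - 25.0
        values.append(pd)
    return PhaseDispersionRecord(anchor, target, tuple(values), pair_class)


def print_geometry_means(run: Run, paw: PawLabel) -> Tuple[float, float]:
    """Mean (print_length cm, print_area cm^2) over a paw's prints."""
    prints = run.contacts_of(paw)
    if not prints:
        raise InsufficientDataError(f"no prints of paw {paw.value}")
    n = len(prints)
    return (
        sum(p.print_length for p in prints) / n,
        sum(p.print_area for p in prints) / n,
    )


def _mean(values: Iterable[float]) -> Optional[float]:
    values = list(values)
    return sum(values) / len(values) if values else None


def summarize_run(
    run: Run, parameters: Optional[set] = None, pd_wrap: bool = False
) -> List[ParameterRecord]:
    """Compute every (requested) gait parameter of one run as records.

    Emits per-run values (paw = ``"all"``) for run duration, average
    speed and cadence; per-paw means for the cyclic and static
    parameters; per-side print position (recorded under the side's front
    paw); and the per-pair mean phase dispersions.  ``parameters``
    restricts computation to a subset of names.  Runs without
    contact-area series simply omit stand_index (with a logged warning)
    rather than failing.
    """

    def wanted(name: str) -> bool:
        return parameters is None or name in parameters

    recs: List[ParameterRecord] = []

    def add(parameter: str, paw: str, value: Optional[float]):
        if value is not None:
            recs.append(
                ParameterRecord(
                    animal_id=run.animal_id,
                    group=run.group,
                    week=run.week,
                    run_id=run.run_id,
                    parameter=parameter,
                    paw=paw,
                    value=float(value),
                )
            )

    if wanted("run_duration"):
        add("run_duration", "all", run_duration(run))
    if wanted("average_speed"):
        add("average_speed", "all", average_speed(run))
    if wanted("cadence"):
        add("cadence", "all", cadence(run))

    for paw in PawLabel:
        cycles = segment_step_cycles(run, paw)
        if cycles:
            if wanted("step_cycle"):
                add("step_cycle", paw.value, _mean(c.duration for c in cycles))
            if wanted("stand"):
                add("stand", paw.value, _mean(c.stand for c in cycles))
            if wanted("swing"):
                add("swing", paw.value, _mean(c.swing for c in cycles))
        if wanted("stride_length"):
            add("stride_length", paw.value, _mean(stride_lengths(run, paw)))
        if wanted("initial_dual_stance"):
            add("initial_dual_stance", paw.value, _mean(initial_dual_stance(run, paw)))
        if wanted("stand_index"):
            with_series = [c for c in run.contacts_of(paw) if c.area_series is not None]
            if with_series:
                add("stand_index", paw.value, _mean(stand_index(c) for c in with_series))
            elif run.contacts_of(paw):
                log.warning(
                    "run %s: no area series for paw %s; stand_index omitted",
                    run.run_id,
                    paw.value,
                )
        if run.contacts_of(paw):
            if wanted("print_length") or wanted("print_area"):
                mean_len, mean_area = print_geometry_means(run, paw)
                if wanted("print_length"):
                    add("print_length", paw.value, mean_len)
                if wanted("print_area"):
                    add("print_area", paw.value, mean_area)

    if wanted("print_position"):
        for side, front in (("left", PawLabel.LF), ("right", PawLabel.RF)):
            add("print_position", front.value, _mean(print_position(run, side)))

    for name, (anchor, target) in PHASE_DISPERSION_PAIRS.items():
        if wanted(name):
            rec = phase_dispersion(run, anchor, target, wrap=pd_wrap)
            add(name, "all", _mean(rec.values))

    return recs
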