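"""Domain types and CSV I/O for quadruped footfall event data.

Conventions
-----------
* Time is in seconds, real-valued, with t = 0 at run start (``t_enter``);
  no absolute clock is kept because all processing is per run.
* The travel axis ``x`` (cm) increases in the direction of travel.  Runs
  recorded in the opposite direction are reflected by the loader
  (``x <- walkway_length - x``) so that downstream sign conventions, in
  particular the print-position sign, are uniform.
* ``y`` (cm) is the lateral coordinate; its origin is arbitrary because
  only distances enter any computation.

The footfall CSV dialect (UTF-8, comma separated, header required)::

    animal_id,group,week,run_id,walkway_length_cm,t_enter_s,t_exit_s,
    interrupted,paw,t_contact_s,t_liftoff_s,x_cm,y_cm,print_length_cm,
    print_area_cm2,area_series

with one row per paw print and ``area_series`` a ``t:area`` list joined
by ``;`` (or empty).  Times are serialized with 6 decimals, lengths and
areas with 3.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .errors import FormatError, ValidationError

__all__ = [
    "PawLabel",
    "PawContact",
    "Run",
    "StepCycle",
    "ParameterRecord",
    "PARAMETER_VOCABULARY",
    "GROUPS",
    "read_footfall_csv",
    "write_footfall_csv",
    "write_parameter_table",
    "read_parameter_table",
]

#: Treatment groups: sham surgeries and the two 6-OHDA lesion placements
#: (medial forebrain bundle = near-complete lesion, striatal = partial).
GROUPS = ("sham_mfb", "sham_striatal", "mfb", "striatal")

#: Closed vocabulary of parameter names a ParameterRecord may carry.
PARAMETER_VOCABULARY = frozenset(
    {
        "run_duration",
        "average_speed",
        "cadence",
        "step_cycle",
        "stand",
        "swing",
        "stand_index",
        "stride_length",
        "print_position",
        "initial_dual_stance",
        "phase_dispersion_diag_RF_LH",
        "phase_dispersion_diag_LF_RH",
        "phase_dispersion_ipsi_RF_RH",
        "phase_dispersion_ipsi_LF_LH",
        "print_length",
        "print_area",
        "slow_class",
    }
)


class PawLabel(str, enum.Enum):
    """One of the four paws: left/right front/hind."""

    LF = "LF"
    RF = "RF"
    LH = "LH"
    RH = "RH"

    @property
    def is_front(self) -> bool:
        return self in (PawLabel.LF, PawLabel.RF)

    @property
    def is_hind(self) -> bool:
        return not self.is_front

    @property
    def is_left(self) -> bool:
        return self in (PawLabel.LF, PawLabel.LH)

    @property
    def contralateral(self) -> "PawLabel":
        """Mirror paw within the same girdle (LF<->RF, LH<->RH)."""
        return _CONTRA[self]

    @property
    def ipsilateral_hind(self) -> "PawLabel":
        """Hind paw on the same body side; only defined for front paws."""
        if not self.is_front:
            raise ValueError(f"{self.value} is not a front paw")
        return PawLabel.LH if self is PawLabel.LF else PawLabel.RH

    @property
    def diagonal(self) -> "PawLabel":
        """Diagonal partner (LF<->RH, RF<->LH)."""
        return _DIAG[self]


_CONTRA = {
    PawLabel.LF: PawLabel.RF,
    PawLabel.RF: PawLabel.LF,
    PawLabel.LH: PawLabel.RH,
    PawLabel.RH: PawLabel.LH,
}
_DIAG = {
    PawLabel.LF: PawLabel.RH,
    PawLabel.RH: PawLabel.LF,
    PawLabel.RF: PawLabel.LH,
    PawLabel.LH: PawLabel.RF,
}


@dataclass(frozen=True)
class PawContact:
    """A single paw print.

    ``area_series`` is the optional contact-area time series sampled on
    ``[t_contact, t_liftoff]`` as a tuple of ``(t, area)`` pairs.  It is
    required only for the stand-index computation, which errors when the
    series is absent rather than silently approximating.
    """

    paw: PawLabel
    t_contact: float
    t_liftoff: float
    x: float
    y: float
    print_length: float
    print_area: float
    area_series: Optional[tuple] = None

    def __post_init__(self):
        if not isinstance(self.paw, PawLabel):
            raise ValidationError(f"unknown paw label: {self.paw!r}")
        if not self.t_liftoff > self.t_contact:
            raise ValidationError(
                f"t_liftoff ({self.t_liftoff}) must exceed t_contact "
                f"({self.t_contact}) for paw {self.paw.value}"
            )
        if self.print_length < 0 or self.print_area < 0:
            raise ValidationError("print geometry must be non-negative")
        if self.area_series is not None:
            series = tuple((float(t), float(a)) for t, a in self.area_series)
            object.__setattr__(self, "area_series", series)
            times = [t for t, _ in series]
            areas = [a for _, a in series]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValidationError("area_series times must be strictly increasing")
            if times[0] != self.t_contact or times[-1] != self.t_liftoff:
                raise ValidationError(
                    "area_series must span [t_contact, t_liftoff] exactly"
                )
            if any(a < 0 for a in areas) or max(areas) <= 0:
                raise ValidationError("area_series areas must be >= 0 with max > 0")

    @property
    def stand(self) -> float:
        """Contact duration (s) of this print."""
        return self.t_liftoff - self.t_contact


@dataclass
class Run:
    """One walkway crossing: ordered paw prints plus run metadata."""

    animal_id: str
    group: str
    week: int
    run_id: str
    walkway_length: float
    t_enter: float
    t_exit: float
    contacts: list
    interrupted: bool = False

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group: {self.group!r}")
        if not 0 <= int(self.week) <= 6:
            raise ValidationError(f"week must be in 0..6, got {self.week}")
        if not self.t_exit > self.t_enter:
            raise ValidationError("t_exit must exceed t_enter")
        self.contacts = sorted(self.contacts, key=lambda c: c.t_contact)
        for c in self.contacts:
            if not (self.t_enter <= c.t_contact and c.t_liftoff <= self.t_exit):
                raise ValidationError(
                    f"contact at t={c.t_contact} outside [t_enter, t_exit]"
                )
            if not -1e-9 <= c.x <= self.walkway_length + 1e-9:
                raise ValidationError(
                    f"contact x={c.x} outside walkway [0, {self.walkway_length}]"
                )

    def contacts_of(self, paw: PawLabel) -> list:
        return [c for c in self.contacts if c.paw is paw]


@dataclass(frozen=True)
class StepCycle:
    """Interval between two consecutive initial contacts of the same paw.

    ``swing`` is stored as the residual ``(t_end - t_start) - stand`` so
    that stand + swing equals the cycle duration exactly, bit for bit.
    """

    paw: PawLabel
    t_start: float
    t_end: float
    stand: float
    swing: float

    def __post_init__(self):
        if not self.t_end > self.t_start:
            raise ValidationError("cycle must have positive duration")
        if self.stand <= 0 or self.swing < 0:
            raise ValidationError("stand must be > 0 and swing >= 0")
        if self.stand + self.swing != self.t_end - self.t_start:
            raise ValidationError("stand + swing must equal cycle duration exactly")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class ParameterRecord:
    """One (animal, week, run, parameter, paw) value.

    ``run_id`` is ``"animal-mean"`` for values averaged over a session's
    accepted runs.  ``paw`` is a :class:`PawLabel` value or ``"all"``.
    """

    animal_id: str
    group: str
    week: int
    run_id: str
    parameter: str
    paw: str
    value: float
    normalized: bool = False

    def __post_init__(self):
        if self.parameter not in PARAMETER_VOCABULARY:
            raise ValidationError(f"unknown parameter name: {self.parameter!r}")


# ---------------------------------------------------------------------------
# Footfall CSV I/O

_FOOTFALL_COLUMNS = [
    "animal_id",
    "group",
    "week",
    "run_id",
    "walkway_length_cm",
    "t_enter_s",
    "t_exit_s",
    "interrupted",
    "paw",
    "t_contact_s",
    "t_liftoff_s",
    "x_cm",
    "y_cm",
    "print_length_cm",
    "print_area_cm2",
    "area_series",
]


def _fmt_t(v: float) -> str:
    return f"{v:.6f}"


def _fmt_cm(v: float) -> str:
    return f"{v:.3f}"


def _format_area_series(series) -> str:
    if series is None:
        return ""
    return ";".join(f"{_fmt_t(t)}:{_fmt_cm(a)}" for t, a in series)


def _parse_area_series(text: str, row: int):
    text = text.strip()
    if not text:
        return None
    pairs = []
    for token in text.split(";"):
        try:
            t, a = token.split(":")
            pairs.append((float(t), float(a)))
        except ValueError as exc:
            raise ValidationError(f"row {row}: malformed area_series token {token!r}") from exc
    return tuple(pairs)


def write_footfall_csv(runs: Iterable[Run], path) -> None:
    """Write runs in the footfall dialect with deterministic row order."""
    rows = []
    for run in runs:
        for c in run.contacts:
            rows.append(
                (
                    run.animal_id,
                    run.group,
                    run.week,
                    run.run_id,
                    _fmt_cm(run.walkway_length),
                    _fmt_t(run.t_enter),
                    _fmt_t(run.t_exit),
                    "true" if run.interrupted else "false",
                    c.paw.value,
                    _fmt_t(c.t_contact),
                    _fmt_t(c.t_liftoff),
                    _fmt_cm(c.x),
                    _fmt_cm(c.y),
                    _fmt_cm(c.print_length),
                    _fmt_cm(c.print_area),
                    _format_area_series(c.area_series),
                )
            )
    rows.sort(key=lambda r: (r[0], int(r[2]), r[3], float(r[9])))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_FOOTFALL_COLUMNS)
        writer.writerows(rows)


def _travel_is_reversed(contacts: Sequence[PawContact]) -> bool:
    """True when prints drift toward smaller x over time."""
    if len(contacts) < 2:
        return False
    ordered = sorted(contacts, key=lambda c: c.t_contact)
    return ordered[-1].x < ordered[0].x


def read_footfall_csv(path) -> list:
    """Parse a footfall CSV into a list of :class:`Run`.

    Runs are grouped by (animal_id, week, run_id); contacts come back
    sorted by initial-contact time.  Runs recorded against the travel
    axis are reflected so x always increases in the direction of travel.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError("empty file: header row required")
        missing = [c for c in _FOOTFALL_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"missing column(s): {', '.join(missing)}")
        groups: dict = {}
        meta: dict = {}
        for i, row in enumerate(reader, start=2):  # header is line 1
            key = (row["animal_id"], int(row["week"]), row["run_id"])
            try:
                paw = PawLabel(row["paw"])
            except ValueError:
                raise ValidationError(f"row {i}: unknown paw label {row['paw']!r}")
            t_contact = float(row["t_contact_s"])
            t_liftoff = float(row["t_liftoff_s"])
            if t_liftoff <= t_contact:
                raise ValidationError(
                    f"row {i}: t_liftoff ({t_liftoff}) <= t_contact ({t_contact})"
                )
            contact = PawContact(
                paw=paw,
                t_contact=t_contact,
                t_liftoff=t_liftoff,
                x=float(row["x_cm"]),
                y=float(row["y_cm"]),
                print_length=float(row["print_length_cm"]),
                print_area=float(row["print_area_cm2"]),
                area_series=_parse_area_series(row["area_series"], i),
            )
            groups.setdefault(key, []).append(contact)
            meta[key] = (
                row["group"],
                float(row["walkway_length_cm"]),
                float(row["t_enter_s"]),
                float(row["t_exit_s"]),
                row["interrupted"].strip().lower() in ("true", "1", "yes"),
            )
    runs = []
    for key in sorted(groups, key=lambda k: (k[0], k[1], k[2])):
        animal_id, week, run_id = key
        group, walkway, t_enter, t_exit, interrupted = meta[key]
        contacts = groups[key]
        if _travel_is_reversed(contacts):
            contacts = [replace(c, x=walkway - c.x) for c in contacts]
        runs.append(
            Run(
                animal_id=animal_id,
                group=group,
                week=week,
                run_id=run_id,
                walkway_length=walkway,
                t_enter=t_enter,
                t_exit=t_exit,
                contacts=contacts,
                interrupted=interrupted,
            )
        )
    return runs


# ---------------------------------------------------------------------------
# Parameter table I/O

_PARAM_COLUMNS = [
    "animal_id",
    "group",
    "week",
    "run_id",
    "parameter",
    "paw",
    "value",
    "normalized",
]


def write_parameter_table(records: Iterable[ParameterRecord], path) -> None:
    """Write a long-format parameter table (one row per record)."""
    records = list(records)
    seen = set()
    for r in records:
        if r.parameter not in PARAMETER_VOCABULARY:
            raise ValidationError(f"unknown parameter name: {r.parameter!r}")
        key = (r.animal_id, r.week, r.run_id, r.parameter, r.paw, r.normalized)
        if key in seen:
            raise ValidationError(f"duplicate parameter record key: {key}")
        seen.add(key)
    records.sort(
        key=lambda r: (r.animal_id, r.week, r.run_id, r.parameter, r.paw, r.normalized)
    )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PARAM_COLUMNS)
        for r in records:
            writer.writerow(
                (
                    r.animal_id,
                    r.group,
                    r.week,
                    r.run_id,
                    r.parameter,
                    r.paw,
                    repr(r.value),
                    "true" if r.normalized else "false",
                )
            )


def read_parameter_table(path) -> list:
    """Inverse of :func:`write_parameter_table`."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError("empty file: header row required")
        missing = [c for c in _PARAM_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"missing column(s): {', '.join(missing)}")
        return [
            ParameterRecord(
                animal_id=row["animal_id"],
                group=row["group"],
                week=int(row["week"]),
                run_id=row["run_id"],
                parameter=row["parameter"],
                paw=row["paw"],
                value=float(row["value"]),
                normalized=row["normalized"].strip().lower() in ("true", "1"),
            )
            for row in reader
        ]
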