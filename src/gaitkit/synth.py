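"""Synthetic footfall generator with known ground truth.

Emulates a unilateral 6-OHDA lesion study: four cohorts (two shams, a
medial-forebrain-bundle "full" lesion and a striatal "partial" lesion),
seven weekly sessions (week 0 = pre-lesion baseline) of at least three
crossings of a 70 cm walkway, plus the ancillary measurements that link
histology to behavior (nigral TH+ neuron counts, apomorphine-induced
rotations, cylinder-test touches).

The model is a constant-speed kinematic gait: each run has a body speed
``v``, stride ``L`` (so cycle period ``T = L / v``), duty factor ``d``
and per-paw phase offsets realizing the alternating "Ab" footfall
sequence LF -> RH -> RF -> LH.  A latent lesion severity ``s in [0, 1]``
drawn once per animal (shams fixed at 0) drives every phenotypic effect
from week 1 onward:

* the weekly habituation speed-up seen in shams stays flat at baseline
  (``mfb_speed_flat``, scaled by ``a_speed``);
* stride shortens intrinsically (``a_stride``) on top of its natural
  sub-linear scaling with speed;
* duty factor rises (``a_duty``), lengthening relative stance and, with
  girdle phases half a cycle apart, raising initial dual stance;
* the paw-release portion of the contact-area triangle shrinks
  (``a_standindex``), so the stand index rises;
* the right hind print grows (``a_printRH``), the compensatory
  loaded-limb effect on the non-impaired side;
* the right hind phase offset shifts by ``s * delta_diag`` of a cycle,
  de-synchronizing the LF-RH diagonal from the RF-LH diagonal.

Kinematic effects engage only above a severity threshold (motor signs
require substantial nigral loss), whereas the diagonal phase asymmetry
scales with raw severity — the partial lesion therefore shows the
coordination deficit and little else.  Noise is multiplicative
log-normal per run on ``v`` and ``L``, Gaussian on print geometry and on
phase offsets; this keeps all positive quantities positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import GROUPS, PawContact, PawLabel, Run
from .errors import ConfigurationError

__all__ = [
    "PhenotypeParams",
    "RunKinematics",
    "effective_severity",
    "apply_severity",
    "generate_run",
    "draw_cohort",
    "DEFAULT_GROUP_SIZES",
]

#: Cohort sizes of the emulated study (47 animals in total).
DEFAULT_GROUP_SIZES = {"sham_mfb": 9, "sham_striatal": 6, "mfb": 15, "striatal": 17}

#: Default phase offsets (fraction of cycle) realizing the Ab sequence
#: LF -> RH -> RF -> LH, with near-synchronous diagonal pairs.
DEFAULT_PHASES = {"RF": 0.0, "LH": 0.05, "LF": 0.5, "RH": 0.55}


@dataclass
class PhenotypeParams:
    """Generator coefficients mapping latent lesion severity to gait effects.

    Severity means mirror the nigral TH losses of the full (~89%) and
    partial (~40%) lesion models; the weekly sham speed trajectory rises
    through the 20-50 cm/s "slow walking" band so the proportion of slow
    animals decays to zero by week 6.  Effect coefficients are
    calibration choices: the study that motivates them reports effect
    directions, not sizes.
    """

    severity_mean: Dict[str, float] = field(
        default_factory=lambda: {
            "sham_mfb": 0.0,
            "sham_striatal": 0.0,
            "mfb": 0.89,
            "striatal": 0.40,
        }
    )
    severity_sd: Dict[str, float] = field(
        default_factory=lambda: {
            "sham_mfb": 0.0,
            "sham_striatal": 0.0,
            "mfb": 0.04,
            "striatal": 0.10,
        }
    )
    #: Sham mean speed (cm/s) per week 0..6; weekly habituation speed-up.
    baseline_speed_by_week: Tuple[float, ...] = (40.0, 43.0, 46.0, 49.0, 52.0, 55.0, 58.0)
    #: Severity below which kinematic effects stay silent (coordination
    #: asymmetry is exempt and scales with raw severity).
    severity_threshold: float = 0.5
    a_speed: float = 1.0
    a_stride: float = 0.10
    a_duty: float = 0.10
    a_standindex: float = 0.60
    a_printRH: float = 0.30
    #: Phase-offset shift (fraction of cycle) added to the right hind
    #: paw, scaled by raw severity; negative values pull the LF-RH
    #: diagonal dispersion below the RF-LH one.
    delta_diag: float = -0.03
    mfb_speed_flat: bool = True
    noise_cv: float = 0.08
    phase_jitter_sd: float = 0.008
    th_baseline_mean: float = 19800.0
    th_baseline_sd: float = 2000.0
    rotation_gain: float = 9.0
    cylinder_gain: float = 35.0
    # Kinematic reference values
    stride_ref_cm: float = 13.0
    speed_ref_cms: float = 35.0
    stride_speed_exp: float = 0.25
    duty0: float = 0.55
    body_offset_cm: float = 8.0
    walkway_length_cm: float = 70.0
    rise_fraction: float = 0.6
    phases: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PHASES))
    print_length_front_cm: float = 2.2
    print_length_hind_cm: float = 2.4
    print_area_front_cm2: float = 1.8
    print_area_hind_cm2: float = 2.6
    geom_noise_sd_cm: float = 0.08
    geom_noise_sd_cm2: float = 0.10

    def __post_init__(self):
        for g, m in self.severity_mean.items():
            if not 0.0 <= m <= 1.0:
                raise ConfigurationError(f"severity_mean[{g}] outside [0, 1]")
        if any(v <= 20.0 for v in self.baseline_speed_by_week):
            raise ConfigurationError("baseline speeds must exceed 20 cm/s")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        if not 0 < self.duty0 < 1:
            raise ConfigurationError("duty0 must be in (0, 1)")


def effective_severity(params: PhenotypeParams, s: float) -> float:
    """Thresholded severity driving the kinematic (non-phase) effects."""
    th = params.severity_threshold
    return 0.0 if s <= th else (s - th) / (1.0 - th)


@dataclass(frozen=True)
class RunKinematics:
    """Deterministic per-run ground truth before noise."""

    v: float  # body speed, cm/s
    L: float  # stride length, cm
    d: float  # duty factor
    phases: Dict[str, float]  # per-paw phase offsets, fraction of cycle
    release_fraction: float  # area-decay portion of the stand phase
    print_geometry: Dict[str, Tuple[float, float]]  # paw -> (length, area)

    @property
    def T(self) -> float:
        return self.L / self.v


def apply_severity(
    params: PhenotypeParams, week: int, s: float, group: str = "mfb"
) -> RunKinematics:
    """Map (week, severity) to the noiseless kinematics of one run.

    Week 0 is the pre-lesion baseline: severity has no effect there.
    """
    lesioned = week >= 1 and group in ("mfb", "striatal")
    e = effective_severity(params, s) if lesioned else 0.0
    base = params.baseline_speed_by_week
    v = base[week]
    if lesioned and params.mfb_speed_flat:
        v = base[week] - params.a_speed * e * (base[week] - base[0])
    L = (
        params.stride_ref_cm
        * (v / params.speed_ref_cms) ** params.stride_speed_exp
        * (1.0 - params.a_stride * e)
    )
    d = params.duty0 * (1.0 + params.a_duty * e)
    if not 0.0 < d < 1.0:
        raise ConfigurationError(f"duty factor {d:.3f} outside (0, 1)")
    phases = dict(params.phases)
    if lesioned:
        phases["RH"] = (phases["RH"] + s * params.delta_diag) % 1.0
    release = (1.0 - params.rise_fraction) * (1.0 - params.a_standindex * e)
    geometry = {}
    for paw in PawLabel:
        length = (
            params.print_length_front_cm if paw.is_front else params.print_length_hind_cm
        )
        area = params.print_area_front_cm2 if paw.is_front else params.print_area_hind_cm2
        if paw is PawLabel.RH and lesioned:
            scale = 1.0 + params.a_printRH * e
            length, area = length * scale, area * scale
        geometry[paw.value] = (length, area)
    return RunKinematics(
        v=v, L=L, d=d, phases=phases, release_fraction=release, print_geometry=geometry
    )


def _area_series(
    t_contact: float, t_liftoff: float, area: float, release_fraction: float
) -> tuple:
    """Triangular contact-area profile: linear rise then linear fall to 0."""
    stand = t_liftoff - t_contact
    release = release_fraction * stand
    t_peak = t_liftoff - release
    rise_mid = t_contact + 0.5 * (t_peak - t_contact)
    fall_mid = t_peak + 0.5 * release
    return (
        (t_contact, 0.0),
        (rise_mid, 0.5 * area),
        (t_peak, area),
        (fall_mid, 0.5 * area),
        (t_liftoff, 0.0),
    )


def generate_run(
    v: float,
    L: float,
    d: float,
    phases: Optional[Dict[str, float]] = None,
    walkway_length: float = 70.0,
    body_offset: float = 8.0,
    print_geometry: Optional[Dict[str, Tuple[float, float]]] = None,
    release_fraction: float = 0.4,
    animal_id: str = "a00",
    group: str = "sham_mfb",
    week: int = 0,
    run_id: str = "r0",
) -> Tuple[Run, dict]:
    """Lay one deterministic crossing and return (run, ground truth).

    Paw ``p`` makes initial contact at times ``(k + phi_p) * T`` with
    ``T = L / v`` and lifts off ``d * T`` later; positions advance by
    ``L`` per cycle, with front paws a body offset ahead of the hinds.
    Prints are kept while they lie on the walkway and finish before the
    body reaches the exit.  Enter/exit times are chosen so that the
    measured speed (print span over duration) reproduces ``v`` whenever
    edge truncation allows.
    """
    if v <= 0 or L <= 0 or walkway_length <= 0:
        raise ConfigurationError("v, L and walkway_length must be positive")
    if not 0.0 < d < 1.0:
        raise ConfigurationError("duty factor must be in (0, 1)")
    if walkway_length < L:
        raise ConfigurationError(
            f"walkway ({walkway_length} cm) shorter than one stride ({L} cm)"
        )
    phases = dict(DEFAULT_PHASES if phases is None else phases)
    if print_geometry is None:
        print_geometry = {
            p.value: (2.2, 1.8) if p.is_front else (2.4, 2.6) for p in PawLabel
        }
    T = L / v
    t_body_exit = walkway_length / v
    contacts = []
    for paw in PawLabel:
        phi = phases[paw.value]
        offset = body_offset if paw.is_front else 0.0
        length, area = print_geometry[paw.value]
        k = math.floor(-phi - offset / L)  # first index that could land at x >= 0
        while True:
            t_ic = (k + phi) * T
            x = v * t_ic + offset
            if x > walkway_length + 1e-9:
                break
            # skip prints landing before the body is on the walkway (a
            # small negative allowance admits jittered offsets near 0)
            if x < -1e-9 or t_ic < -0.05 * T:
                k += 1
                continue
            t_lift = t_ic + d * T
            if t_lift <= t_body_exit + 1e-9:
                contacts.append(
                    PawContact(
                        paw=paw,
                        t_contact=t_ic,
                        t_liftoff=t_lift,
                        x=min(x, walkway_length),
                        y=1.5 if paw.is_left else -1.5,
                        print_length=length,
                        print_area=area,
                        area_series=_area_series(t_ic, t_lift, area, release_fraction),
                    )
                )
            k += 1
    if not contacts:
        raise ConfigurationError("no prints fit on the walkway")
    # The recording window covers the print span at body speed v: it opens
    # at the first initial contact and closes span/v later.  Prints still on
    # the glass at window close are cut short (partial prints at the run
    # end, recognizable by their missing area series); the measured average
    # speed (span over duration) therefore recovers v.
    t_first = min(c.t_contact for c in contacts)
    span = max(c.x for c in contacts) - min(c.x for c in contacts)
    if span <= 0:
        t_exit = max(c.t_liftoff for c in contacts)
    else:
        t_exit = t_first + span / v
        kept = []
        for c in contacts:
            if c.t_contact >= t_exit - 1e-9:
                continue
            if c.t_liftoff > t_exit:
                c = PawContact(
                    paw=c.paw,
                    t_contact=c.t_contact,
                    t_liftoff=t_exit,
                    x=c.x,
                    y=c.y,
                    print_length=c.print_length,
                    print_area=c.print_area,
                    area_series=None,
                )
            kept.append(c)
        contacts = kept
    if t_first != 0.0:  # time origin at run start
        contacts = [
            PawContact(
                paw=c.paw,
                t_contact=c.t_contact - t_first,
                t_liftoff=c.t_liftoff - t_first,
                x=c.x,
                y=c.y,
                print_length=c.print_length,
                print_area=c.print_area,
                area_series=None
                if c.area_series is None
                else tuple((t - t_first, a) for t, a in c.area_series),
            )
            for c in contacts
        ]
        t_exit -= t_first
    t_enter = 0.0
    run = Run(
        animal_id=animal_id,
        group=group,
        week=week,
        run_id=run_id,
        walkway_length=walkway_length,
        t_enter=t_enter,
        t_exit=t_exit,
        contacts=contacts,
        interrupted=False,
    )
    truth = {
        "animal_id": animal_id,
        "group": group,
        "week": week,
        "run_id": run_id,
        "v": v,
        "L": L,
        "T": T,
        "d": d,
        "release_fraction": release_fraction,
        **{f"phi_{p}": phases[p] for p in ("LF", "RF", "LH", "RH")},
        **{
            f"print_length_{p.value}": print_geometry[p.value][0] for p in PawLabel
        },
        **{f"print_area_{p.value}": print_geometry[p.value][1] for p in PawLabel},
    }
    return run, truth


def _animal_rng(seed: int, group_idx: int, animal_idx: int) -> np.random.Generator:
    return np.random.default_rng([seed, group_idx, animal_idx])


def _run_rng(seed, gi, ai, week, run) -> np.random.Generator:
    return np.random.default_rng([seed, gi, ai, week, run])


def draw_cohort(
    params: Optional[PhenotypeParams] = None,
    n_per_group: Optional[Dict[str, int]] = None,
    weeks: Tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6),
    runs_per_animal: int = 3,
    seed: int = 0,
    parameters_only: bool = False,
) -> Tuple[List[Run], pd.DataFrame, Dict[str, pd.DataFrame]]:
    """Simulate a full study: runs, ground truth and ancillary tables.

    Random streams are keyed per animal and per (animal, week, run) from
    the master seed, so changing one group's size never reshuffles
    another group's data.  Returns ``(runs, ground_truth, ancillary)``
    where ``ancillary`` holds the ``th_counts``, ``rotations`` and
    ``cylinder`` tables.  Deterministic and byte-identical for a fixed
    seed.
    """
    params = params or PhenotypeParams()
    n_per_group = dict(DEFAULT_GROUP_SIZES if n_per_group is None else n_per_group)
    for g, n in n_per_group.items():
        if n < 0:
            raise ConfigurationError(f"group size must be >= 0, got {n} for {g}")
    runs: List[Run] = []
    truth_rows: List[dict] = []
    th_rows, rot_rows, cyl_rows = [], [], []
    cv = params.noise_cv
    for gi, group in enumerate(GROUPS):
        n = n_per_group.get(group, 0)
        for ai in range(n):
            animal_id = f"{group}_{ai:02d}"
            arng = _animal_rng(seed, gi, ai)
            if group in ("mfb", "striatal"):
                s = float(
                    np.clip(
                        arng.normal(params.severity_mean[group], params.severity_sd[group]),
                        0.0,
                        1.0,
                    )
                )
            else:
                s = 0.0
            # --- histology: TH+ neuron count scales with surviving fraction
            th = max(
                50.0, float(arng.normal(params.th_baseline_mean, params.th_baseline_sd)) * (1.0 - s)
            )
            th_rows.append(
                dict(animal_id=animal_id, group=group, th_count=th, severity=s)
            )
            # --- apomorphine rotations (single post-lesion session)
            net_true = params.rotation_gain * s + float(arng.normal(0.08, 0.15))
            ipsi = int(arng.poisson(6))
            contra = max(0, int(round(net_true * 60.0)) + ipsi)
            rot_rows.append(
                dict(
                    animal_id=animal_id,
                    group=group,
                    contra_turns=contra,
                    ipsi_turns=ipsi,
                    session_minutes=60.0,
                )
            )
            # --- cylinder test at baseline and weeks 4 and 6
            for cw in (0, 4, 6):
                drop = params.cylinder_gain * s if cw >= 4 else 0.0
                pct = float(np.clip(50.0 - drop + arng.normal(0.0, 3.0), 1.0, 99.0))
                total = max(6, int(arng.poisson(22)))
                both = int(arng.binomial(total, 0.15))
                single = total - both
                # movements: both count once per side
                contra_single = int(
                    np.clip(round(pct / 100.0 * (single + 2 * both) - both), 0, single)
                )
                cyl_rows.append(
                    dict(
                        animal_id=animal_id,
                        group=group,
                        week=cw,
                        left=contra_single,  # right-hemisphere lesion: contralateral = left
                        right=single - contra_single,
                        both=both,
                    )
                )
            if parameters_only:
                continue
            for week in weeks:
                kin = apply_severity(params, week, s, group)
                for rj in range(runs_per_animal):
                    rrng = _run_rng(seed, gi, ai, week, rj)
                    v = kin.v * math.exp(rrng.normal(0.0, cv))
                    L = kin.L * math.exp(rrng.normal(0.0, cv))
                    # jitter is additive and unwrapped: offsets near 0 must
                    # not jump to ~1, which would shift a paw a whole cycle
                    phases = {
                        p: phi + rrng.normal(0.0, params.phase_jitter_sd)
                        for p, phi in kin.phases.items()
                    }
                    geometry = {}
                    for p in PawLabel:
                        gl, ga = kin.print_geometry[p.value]
                        geometry[p.value] = (
                            max(0.2, gl + rrng.normal(0.0, params.geom_noise_sd_cm)),
                            max(0.2, ga + rrng.normal(0.0, params.geom_noise_sd_cm2)),
                        )
                    run, truth = generate_run(
                        v=v,
                        L=L,
                        d=kin.d,
                        phases=phases,
                        walkway_length=params.walkway_length_cm,
                        body_offset=params.body_offset_cm,
                        print_geometry=geometry,
                        release_fraction=kin.release_fraction,
                        animal_id=animal_id,
                        group=group,
                        week=week,
                        run_id=f"r{rj}",
                    )
                    truth["severity"] = s
                    runs.append(run)
                    truth_rows.append(truth)
    ancillary = {
        "th_counts": pd.DataFrame(th_rows),
        "rotations": pd.DataFrame(rot_rows),
        "cylinder": pd.DataFrame(cyl_rows),
    }
    return runs, pd.DataFrame(truth_rows), ancillary
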