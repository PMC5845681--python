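"""Ancillary behavioral scores and histology quantification.

Rotation test: net contralateral rotations per minute after a dopamine
agonist challenge; the conventional success cut-off for a full
(medial-forebrain-bundle) lesion is >= 5 net rotations/min.

Cylinder test: forelimb-use asymmetry during rearing; simultaneous use
of both paws scores one movement for each side, and the result is the
percentage of contralateral touch-movements.

TH loss: percentage reduction of TH-positive neuron counts (or striatal
TH+ fiber volume) relative to a sham baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

from .errors import ValidationError

__all__ = [
    "RotationResult",
    "CylinderResult",
    "net_rotations",
    "cylinder_asymmetry",
    "percent_th_loss",
    "ROTATION_SUCCESS_CUTOFF",
]

#: Net rotations/min at or above which a full lesion counts as successful.
ROTATION_SUCCESS_CUTOFF = 5.0


@dataclass(frozen=True)
class RotationResult:
    animal_id: str
    contra_turns: int
    ipsi_turns: int
    session_minutes: float
    net_per_min: float
    lesion_success: bool


@dataclass(frozen=True)
class CylinderResult:
    animal_id: str
    left_touches: int
    right_touches: int
    both_touches: int
    pct_contralateral: float


def net_rotations(
    contra: int, ipsi: int, minutes: float = 60.0
) -> Tuple[float, bool]:
    """Net contralateral rotations per minute and the success flag.

    ``(contra - ipsi) / minutes``; success when the net rate reaches the
    full-lesion cut-off of 5/min.
    """
    if contra < 0 or ipsi < 0:
        raise ValidationError("turn counts must be non-negative")
    if minutes <= 0:
        raise ValidationError("session duration must be positive")
    net = (contra - ipsi) / minutes
    return net, net >= ROTATION_SUCCESS_CUTOFF


def cylinder_asymmetry(
    left: int, right: int, both: int, lesion_side: str = "right"
) -> float:
    """Percentage of contralateral forelimb touch-movements.

    Both-paw touches contribute one movement to each side, so the
    denominator is ``left + right + 2 * both``.  For a right-hemisphere
    lesion the contralateral paw is the left one.  Returns NaN when no
    touches occurred (undefined, reported missing).
    """
    if left < 0 or right < 0 or both < 0:
        raise ValidationError("touch counts must be non-negative")
    if lesion_side not in ("left", "right"):
        raise ValidationError("lesion_side must be 'left' or 'right'")
    total = left + right + 2 * both
    if total == 0:
        return math.nan
    contra = left if lesion_side == "right" else right
    return 100.0 * (contra + both) / total


def percent_th_loss(lesion_mean: float, sham_mean: float) -> float:
    """Percent loss of TH+ cells (or volume) relative to a sham baseline.

    ``100 * (1 - lesion / sham)``; scale-invariant in the common units.
    """
    if sham_mean <= 0:
        raise ValidationError("sham baseline must be positive")
    return 100.0 * (1.0 - lesion_mean / sham_mean)
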