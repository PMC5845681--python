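"""Published reference values used as fixed inputs.

``TH_CORRELATION_TABLE`` is the printed table of Pearson correlations
between the residual number of TH-positive nigral neurons and 27 gait
parameters (full-lesion cohort plus its sham, week 6).  It is data, not
a computed result: the strength classifier is checked against it and
the synthetic generator's severity-gait coupling reproduces its sign
pattern.
"""

from __future__ import annotations

__all__ = ["TH_CORRELATION_TABLE", "TH_CORRELATION_PARAMETERS"]

#: (parameter, paw, r, p) — 27 rows.
TH_CORRELATION_TABLE = (
    ("run_duration", "all", -0.529, 0.008),
    ("average_speed", "all", 0.635, 0.001),
    ("cadence", "all", 0.608, 0.002),
    ("step_cycle", "RF", -0.552, 0.006),
    ("step_cycle", "RH", -0.525, 0.012),
    ("step_cycle", "LF", -0.592, 0.004),
    ("step_cycle", "LH", -0.590, 0.008),
    ("stand", "RF", -0.489, 0.021),
    ("stand", "RH", -0.528, 0.014),
    ("stand", "LF", -0.555, 0.007),
    ("stand", "LH", -0.420, 0.065),
    ("swing", "RF", -0.442, 0.035),
    ("swing", "RH", -0.556, 0.006),
    ("swing", "LF", -0.593, 0.004),
    ("swing", "LH", -0.665, 0.001),
    ("initial_dual_stance", "RF", -0.456, 0.013),
    ("initial_dual_stance", "RH", -0.291, 0.133),
    ("initial_dual_stance", "LF", -0.290, 0.127),
    ("initial_dual_stance", "LH", -0.305, 0.115),
    ("print_length", "RF", 0.176, 0.421),
    ("print_length", "RH", -0.407, 0.054),
    ("print_length", "LF", 0.149, 0.498),
    ("print_length", "LH", 0.152, 0.510),
    ("stride_length", "RF", 0.602, 0.002),
    ("stride_length", "RH", 0.577, 0.004),
    ("stride_length", "LF", 0.557, 0.006),
    ("stride_length", "LH", 0.505, 0.016),
)

#: The (parameter, paw) combinations entering the histology correlation.
TH_CORRELATION_PARAMETERS = tuple((p, w) for p, w, _, _ in TH_CORRELATION_TABLE)
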