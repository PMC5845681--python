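# Methods

## Scope and model

`gaitkit` analyzes footfall event tables from walkway (CatWalk-style)
recordings of freely crossing rats, aimed at unilateral 6-OHDA lesion
studies: a medial-forebrain-bundle (MFB, "full") lesion cohort, a
striatal ("partial") lesion cohort, and their shams, followed weekly
from a pre-lesion baseline (week 0) through week 6.  The package has
three layers: a per-run parameter engine, a QC/normalization layer, and
a statistical decision pipeline; a synthetic footfall generator with
known ground truth validates all of them.

## Gait parameters

All parameters derive from per-print events (initial contact IC,
lift-off, centroid position, print geometry, optional contact-area time
series):

- **step cycle** — time between consecutive ICs of the same paw; its
  **stand** phase is the first print's contact duration and **swing**
  is stored as the residual `cycle − stand`, so the decomposition is
  exact in floating point, not just to a tolerance.  The final print of
  a run opens no cycle (partial cycles at run boundaries are excluded).
- **cadence** — ICs of all four paws per minute.  Whether cadence
  counts one paw or four is a convention; all-paw counting is used and
  affects only the constant factor.
- **average speed** — print span along the travel axis divided by run
  duration (`t_exit − t_enter`).
- **stride length** — Euclidean distance between consecutive centroids
  of the same paw (not the x-projection; identical for straight runs).
- **print position** — `x_front − x_hind` for the first ipsilateral
  hind IC inside the front paw's step cycle; positive = hind behind
  front.  The loader reflects runs recorded against the travel axis so
  the sign convention is uniform.
- **initial dual stance** — at the IC opening a paw's cycle, the
  remaining stance time of the girdle-contralateral paw (clipped to the
  paw's own stand), else 0.
- **stand index** — rate of contact release at swing initiation: the
  negated least-squares slope of the max-normalized area series from
  its last maximum to lift-off (units 1/s).  The commercial quantity of
  the same name has an unpublished formula; this definition preserves
  its ordering (faster lift-off ⇒ larger index) but not its arbitrary
  units.  It requires the area series and errors rather than
  approximating when the series is absent.
- **phase dispersion** — target-paw IC as a percentage of the anchor
  (always front) paw's step cycle, `(IC_t − IC_a)/cycle_a × 100` in
  [0, 100).  A `pd_wrap` option folds values circularly into [−25, 75).
  The pipeline analyzes dispersions wrapped: diagonal pairs are nearly
  synchronous (offsets of a few percent of a cycle), so unwrapped
  values jitter between ~0.1 and ~99.9 and their means are meaningless.

## Speed normalization

Six parameters co-vary with crossing speed (step cycle, stand, swing,
stride length, print position, cadence).  Per week, each animal's
session speed `V_n` and the cohort mean `averageV` (all included
animals pooled) give `F_n = V_n / averageV`; factors average to 1 by
construction.  Two directions are implemented:

- `verbatim`: all six values multiplied by `F_n` — the single-factor
  rule as conventionally printed in walkway studies;
- `corrective` (library default): `F_n` applied to the speed-inverse
  parameters (step cycle, stand, swing) and `1/F_n` to the
  speed-proportional ones (stride, print position, cadence).

The single-factor rule only de-confounds the speed-inverse side; it
*amplifies* speed differences in the proportional parameters.  This is
not a detail: under the corrective direction the product of normalized
cadence and normalized stride is proportional to `averageV²/v`, which
rises when an animal slows down — so a slowed cohort can never show the
jointly reduced cadence *and* stride that the verbatim rule produces.
Published lesion signatures of that joint form are artifacts of the
verbatim direction, and reproducing them (as the direction-recovery
check does) requires running with `normalization="verbatim"`.

Animals with a session-mean speed below 20 cm/s are excluded from that
week entirely (sub-20 crossings reflect explorative behavior);
20–50 cm/s is classed slow walking, above 50 normal.

## QC

Interrupted runs are rejected; a run must have at least three complete
step cycles on every paw.  Prints cut by the recording window carry no
area series and are handled as partial prints.  Outlier removal is a
single pass within (group × week × parameter × paw) cells of animal
means: values beyond ±2 sample SD are dropped; cells under 3 values
pass through with a warning.

## Statistics

Per parameter/paw: a two-way mixed ANOVA (within = week, between =
group; pingouin) with Mauchly's test; when sphericity fails (p ≤ 0.05)
the Greenhouse–Geisser ε rescales the within and interaction degrees of
freedom (pingouin corrects only the within row; the interaction p is
recomputed from the ε-scaled F distribution).  A significant
interaction triggers per-week pairwise comparisons — Games-Howell (the
Welch-type unequal-variance family that "Dunnett T3" belongs to) when
Levene's test rejects homogeneity, Tukey HSD otherwise; a
non-significant interaction reports the treatment main effect only.
Diagonal-vs-diagonal phase dispersion is compared by paired t-test per
group and week (identical vectors return t = 0, p = 1), preceded by
Pearson correlations of each dispersion variable with speed.  α = 0.05
two-sided throughout, no multiple-testing correction across parameters
— matching the source analysis style, not best modern practice.

TH-count correlations (27 parameter/paw combinations) use **raw**
week-6 means, not normalized ones: the published sign pattern (slower,
longer cycles, larger dual stance with fewer surviving neurons;
print-length sign flipped only in the loaded right hind) arises on the
raw time scales and is inverted for some parameters by per-week
normalization.  Strength labels are |r| ≥ 0.60 strong, ≥ 0.40 moderate,
else none; these thresholds reproduce the published 4 strong / 6 none
partition of the reference table (which then yields 17 moderate — the
reference text's count of 18 is internally inconsistent with its own
27-row table and is not patched).

## Synthetic generator

Each run is a constant-speed kinematic gait: body speed `v`, stride
`L`, period `T = L/v`, duty factor `d`, and per-paw phase offsets
(RF 0, LH 0.05, LF 0.5, RH 0.55) realizing the alternating "Ab"
sequence LF→RH→RF→LH.  Paw `p` touches down at `(k + φ_p)T`, lifts off
`dT` later, and prints advance by `L` per cycle with front paws a body
offset (8 cm) ahead.  The recording window opens at the first IC and
closes span/v later; prints still down at close are truncated (partial
prints), which makes measured average speed equal `v` exactly.  Each
print carries a triangular area series (rise over 60% of stance, then
linear release), so the stand index has the closed form
`1/(release fraction × stand)`.

A latent severity `s ∈ [0,1]`, drawn once per animal (means 0.89 full /
0.40 partial, mirroring ~89%/40% TH loss; shams 0), drives the
phenotype from week 1: the sham weekly speed-up (40→58 cm/s) stays flat
at baseline; stride shortens intrinsically (10% at full effect) on top
of its `v^0.25` speed scaling; duty rises 10%; the area-release phase
shrinks 60%; the right hind print grows 30%; and the RH phase shifts by
`−0.03·s` cycles, pulling LF-RH dispersion below RF-LH.  Kinematic
effects engage only above severity 0.5 — motor signs require
substantial nigral loss — while the phase asymmetry scales with raw
severity, so the partial-lesion cohort shows the coordination deficit
and essentially nothing else, as in the study design being emulated.
Noise: per-run log-normal on `v` and `L` (CV 0.08), Gaussian phase
jitter (0.008 cycles), additive Gaussian print-geometry noise.  Random
streams are keyed per animal and per (animal, week, run) from the
master seed, so resizing one group never reshuffles another.

Ancillary tables: TH count = baseline × (1 − s) + noise; net
apomorphine rotations ≈ 9·s /min (full lesion ≈ 8/min, shams ≈ 0.05);
cylinder contralateral use drops by 35·s percentage points at weeks
≥ 4.

What the generator does *not* emulate: acceleration within runs,
gait-phase variability beyond stationary jitter, explorative stops,
paw-placement lateralization of the lesioned side beyond the modeled
parameters, or ramping lesion development (severity is constant from
week 1; full degeneration takes 3–4 weeks in vivo).  Passing tests
therefore demonstrate correctness of the measurement and decision
pipeline under a known stationary gait model, not biological realism.

## Numerical choices and problem sizes

Stride defaults (13 cm at 35 cm/s) keep generated strides below
~16.5 cm, where a 70 cm walkway stops fitting four prints per paw and
the 3-cycle rule starts rejecting runs.  Direction recovery is checked
on 20 seeded replicates of the full 47-animal study; null calibration
of the interaction and paired tests uses 500 Gaussian
compound-symmetric replicates; stride-detection power uses 100
two-group replicates.  The acceptance script uses 5/300/60 replicates
for the same quantities to stay fast.  Oracle closures are asserted at
1e-9; the stand+swing decomposition and the normalization-factor mean
are exact (bitwise / 1e-12).

## Known limitations

Mauchly's test is unreliable at very small n (it may not compute; the
code then skips the correction).  Games-Howell is a close relative,
not an exact reimplementation, of SPSS's Dunnett T3.  The per-animal
session means feeding the ANOVA ignore within-session run counts
(unweighted means).  Print position assumes straight crossings; the
Euclidean stride ignores body curvature for the same reason.
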