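# Methods

This note documents the models, conventions, parameter choices and
numerical details behind `mostrip`, and what the simulator-based tests
do and do not demonstrate about recorded data.

## Coordinate and timing conventions

* Axis 0 (x) is anterior–posterior (AP), positive in the direction of
  progression; axis 1 mediolateral (positive left); axis 2 vertical.
  The treadmill belt surface therefore has *negative* AP velocity
  during forward walking, and the signed belt channel stores that
  negative value.  With this convention `(v_CoM − v_treadmill)` is
  positive in steady forward walking and the unperturbed MoS is
  positive.
* Frames are 0-based; `time = frame / sampling_rate`; all internal
  units are SI (m, s, kg); MoS is converted to mm only at reporting.
* A *step* is the interval between consecutive heel strikes of opposite
  feet, indexed by its terminating heel strike, where the MoS is
  evaluated.

## Margin of stability

At each step's heel-strike frame:

* CoM velocity is the central difference of the (preprocessed) CoM AP
  series — a deliberate, documented convention; the simulator defines
  its ground truth with the same convention so noise-free
  self-consistency is exact rather than limited by the O(h²)
  discretisation error (~0.02 mm at 100 Hz).
* Belt speed is read from the speed channel at that frame
  (`belt_mode="instantaneous"`); a nominal mode uses the channel
  median.
* Effective leg length is recomputed at every heel strike as the 3-D
  CoM-to-heel distance.
* The anterior BoS boundary is the leading (newly contacting) limb's
  toe marker (`boundary="leading_toe"`); `max_toe` takes the more
  anterior of the two toes.
* g = 9.81 m/s², configurable.

Fall events are maximal runs of harness load strictly above 30% body
weight (strict inequality: "more than 30%").

## Gap filling and smoothing

Gaps of up to 20 frames bounded by at least two observed frames on each
side are filled per coordinate by a not-a-knot cubic interpolating
spline through all observed frames; this restores any cubic polynomial
exactly.  Gaps touching either recording end are never extrapolated,
and longer gaps propagate as missing (model-based reconstruction is out
of scope); both are reported.

Smoothing is a quintic smoothing spline penalising the integrated
squared third derivative — the filter Woltring introduced for
kinematic data — built on a degree-5 B-spline basis with simple
interior knots at the data sites.  Its penalty null space is the
quadratics; the quadratic trend is projected out before the penalized
solve and added back, so null-space reproduction holds to rounding at
any smoothing parameter (otherwise float leakage in the penalty matrix,
whose entries scale like `1/h⁵`, is amplified by large λ).  The
smoothing parameter is chosen by generalized cross-validation (GCV);
the GCV trace is estimated with 4 fixed Rademacher probes through
banded Cholesky solves — deterministic, ~1% accurate, and ample for
locating the flat GCV minimum (λ search: 9-point log grid plus 8
golden-section refinements).  A predicted-MSE mode (the Vicon-style
setting) selects λ by bisection so the residual mean square matches a
supplied value.  Segments shorter than 12 frames are returned
unsmoothed with a warning.

## Event detection and labeling

Heel strike is a local maximum of (heel AP − pelvis AP) and toe-off a
local minimum of (toe AP − pelvis AP) — the standard coordinate-based
choice for treadmill data without force plates.  Candidate extrema must
be at least 0.4 × the median stride period apart (the stride period is
estimated from a first pass with a 0.3-s floor) and exceed a prominence
of 5% of the robust (2nd–98th percentile) signal span; the robust span
keeps lead-in/lead-out transients from inflating the floor and dropping
shortened perturbed steps.  Manual overrides replace an automatic event
of the same kind and side within 10 frames, otherwise insert.

Each perturbation onset frame is assigned to the step whose swing phase
contains it; that step is `perturbed`, its predecessor
`preperturbation`, its three successors `recovery1..3`.  Steps of an
unperturbed bout are `baseline`, everything else `other`.  Overlapping
label windows raise an error naming the colliding perturbations; the
simulator's ≥5-step spacing guarantees disjoint windows.

## The simulator

The generator is kinematic, not dynamic: no forces are modelled, which
keeps every quantity closed-form computable.

* The CoM oscillates sinusoidally in AP, phase-locked to the step
  sequence so that it is furthest forward — with zero AP velocity — at
  each heel strike; this also pins the relative-coordinate extrema to
  the event frames.  Amplitude 0.02 m; ML sway at stride frequency;
  vertical bounce 0.012 m about a 0.95-m CoM height.
* Stance feet translate backwards at belt speed; swing feet follow
  quintic Hermite arcs with small positive lab-frame velocities at
  swing onset (0.20 m/s) and landing (0.15 m/s), so toe-off minima and
  heel-strike maxima fall exactly on the event frames.
* **Landings are solved, not emergent**: each step's heel position is
  chosen (fixed-point iteration on the leg length) so the MoS at that
  heel strike equals a drawn per-step target.  Ground truth is
  therefore exact by construction, on the sampled trajectories and with
  the central-difference velocity convention.
* Per-step MoS targets: label means (baseline 119, preperturbation 114,
  perturbed −106, recovery 74/88/109 mm — representative values for
  slow perturbed treadmill walking in fit older adults) plus a risk
  effect plus N(0, 30 mm) step noise.  The perturbed-step mean scales
  with belt speed (the belt term in the extrapolated CoM grows with
  `v_b`, and faster conditions destabilise more).
* A blocking perturbation: the tether engages a quarter into swing,
  holds the foot's AP position for `block_duration` (0.25 s; shortened
  automatically when a timing draw leaves too little swing, releasing
  no later than 5 frames before landing), then releases into a
  shortened catch-up step.  If a drawn target would put the landing
  behind toe-off (possible at the slowest belts), the landing is
  clamped 8 cm ahead of toe-off and the *realized* MoS recorded as
  ground truth.
* Risk scores come from a truncated normal **moment-matched so the
  truncated distribution's mean equals the nominal 23.6%** on the range
  20.4–33.3%.  On this strongly asymmetric range no truncated normal
  attains mean 23.6 and SD 4.17 simultaneously (pinning the mean caps
  the SD near 3); the fit weights the mean 10×, because the mean is the
  anchor of the risk→MoS effect.  Belt speeds use the same helper on
  0.3–0.9 m/s.
* The risk→MoS slope defaults to +10 mm per risk-%-point — higher-risk
  walkers show *larger* margins, with the magnitude set once from the
  ~70-mm spread across tertile means (≈7 points apart) that motivates
  the default; the sign is configurable.  Between-participant MoS
  spread beyond the risk effect (`participant_mos_sd`) defaults to 0 so
  that pooled-step AUC admits the closed-form check
  AUC → Φ(δ/(σ√2)); real cohorts have participant-level heterogeneity,
  which clustering would add back.
* Harness-load peaks are injected only as explicit configuration
  (frame, %BW, duration) so the fall-event counter has exact ground
  truth.
* Schedules: the `random` scheme draws the fixed 4-right + 3-left mix;
  `series_right`/`series_left` place all 7 perturbations on the named
  side (the protocol's wording does not fix the sides of the series
  conditions; all-one-side is the reading that distinguishes them from
  `random`).  Ordinals keep ≥5 unperturbed steps between perturbations
  and honour foot parity; one schedule per condition is shared by all
  participants.

What the simulator does **not** emulate: anthropometric variation, foot
pitch/roll (toe = heel + 0.18 m AP rigidly), double-support force
transfer, fatigue or adaptation across trials, marker occlusion
patterns of real labs (gaps must be injected explicitly), and any
correlation between risk score and gait timing.  Passing tests
demonstrate the *pipeline's* correctness on data whose generative
structure is known — not that the effect sizes encoded in the defaults
hold in any real cohort.

## Statistics

* Quartiles use linear interpolation between order statistics; CIs are
  t-based.
* The paired Wilcoxon signed-rank test drops zero differences
  (Wilcoxon's original rule), uses average ranks for tied |d|, and
  enumerates the exact tie-aware null by dynamic programming over
  doubled ranks for up to 25 non-zero pairs (two-sided
  p = P(|W − μ| ≥ |w − μ|), which equals twice the smaller tail for
  this symmetric null); beyond that, a normal approximation with tie
  correction (σ² = Σr²/4).  The pairing unit is one pair per
  perturbation window, pooled across participants; a
  participant-median mode exists.
* AUC is the Mann–Whitney pairwise statistic (ties ½), computed by
  average ranks, with the higher-risk group positive and MoS the score,
  unflipped; values below 0.5 are reported as-is.  ROC observations are
  pooled step-level MoS by default (`pooled`); `participant_mean`
  reduces each participant to their mean first.  The unperturbed-bout
  AUC pools all baseline steps.
* The exploratory regression is OLS of MoS on tertile indicators (low
  reference) per condition × step label; a continuous risk-score mode
  exists.  No multiple-testing correction is applied, and repeated
  measures are not modelled — these tables are descriptive.

## Problem sizes and determinism

The default cohort is 19 participants × 8 conditions × 60 steps at
100 Hz (~36 s per trial); the full pipeline runs in about 1.5 minutes
on one CPU.  The closed-form AUC check pools 2 200 baseline steps per
group from 220-step unperturbed bouts.  All randomness flows from a
single integer seed through `numpy` `SeedSequence` spawning; reruns are
bit-identical.

## Known limitations

* Coordinate-based event detection can misplace events on extremely
  shortened steps at the slowest belts (~0.3 m/s), where mid-swing
  pelvis sway rivals the step's AP excursion — the situation the
  manual-override path exists for (observed rate ≲0.2% of events at the
  belt-speed floor, zero at default speeds).
* C3D input is not supported; the canonical interchange is TSV with SI
  units.
* Mediolateral MoS, whole-BoS polygons, and model-based large-gap
  reconstruction are out of scope.
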