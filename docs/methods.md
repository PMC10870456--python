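# Methods

## Model

A single rigid segment rotates about the ankle:
`J_B θ̈ = m g L_COM sin θ + τ_total`, with θ the lean angle from vertical
along the task direction.  Anthropometry is derived from stature and mass:
`L_COM = 0.5527 · height` (a standard COM-height fraction for standing
adults) and the point-mass inertia `J_B = m L_COM²`; both are overridable.
Intrinsic ankle impedance defaults to 15% (stiffness) and 5% (damping) of
the gravity stiffness `m g L_COM` per radian.  These fractions are
assumptions — the literature values they stand in for are not published in
a usable form — chosen so that passive stance is distinctly sub-critical
(unstable without active control), which the code enforces as an invariant.

Controller gains are expressed per degree, as identified gain tables are;
all internal dynamics are in radians, and the conversion lives only at the
module boundaries.

The COP output is the linearized single-pendulum ZMP relation
`COP = L_COM θ − (J_B/(m g)) θ̈` (reported in cm).  This choice is forced
by two requirements: static consistency (COP = COM ground projection when
θ̈ = 0) and the existence of the anticipatory undershoot (accelerating the
body toward the target must move the COP the opposite way).  A pure
COM-projection output `L_COM θ` satisfies the first but can never produce
an undershoot under this controller, so it was rejected.

### A consequence worth stating plainly

Because the COP carries the acceleration term, **any** controller that
moves the pendulum from upright produces a finite opposite-direction COP
excursion at movement onset — of order `(L²/g)·max θ̈ ≈ 0.2–0.5 cm` for the
movement amplitudes and durations in the cohort tables — even with the
feedforward path removed (`K_FF = 0`).  The anticipatory excursion
therefore has a feedback-induced floor; the feedforward gain scales it far
beyond that floor (≈ 0.6 cm at `K_FF = 0` versus ≈ 2.2 cm at healthy-scale
`K_FF ≈ 15` for the healthy-mean subject), but it cannot be made to vanish.
One acceptance-style expectation ("no feedforward ⇒ no measurable APA") is
unattainable under this output model and the corresponding test is left
failing by design rather than weakened.

## Motor planning

The reference is the classic minimum-jerk polynomial, written with
coefficients `A1=15, A2=6, A3=10` applied to `(θ_0 − θ_f)`; this is the
unique 3rd–5th-order choice that reaches the target with zero endpoint
velocity and acceleration, giving the bell-shaped velocity profile.  The
return phase is modelled as the mirrored profile over the return time
`t_b` — the return trajectory itself is not part of the identification, so
this only needs to produce a plausible settle-back for segmentation.
Diagonal targets are treated as a 1-DOF lean along the straight line to the
target (the Euclidean distance sets `θ_f = atan(d / H_CoM)`); whether the
original protocol composed independent AP/ML controllers instead is
unknowable from the published material, and the 1-DOF reading matches the
one-dimensional controller structure.

Target geometry: `d = 0.3 · H_CoM · tan(θ_limit)` per direction, with the
published limit angles (AP: 6.25° T1; 4.5° T2,T3; 1.7° T4,T5; 4.4° T6–T8 —
the printed list contains an obvious target-numbering typo, resolved as the
backward group; ML: 0° T1,T8; 6° T2,T3,T6,T7; 8° T4,T5).  Mirrored pairs
(2,3), (4,5), (6,7) carry opposite ML signs; targets 1–5 lean forward,
6–8 backward.

## Control blending

During the APA window the feedforward and feedback channels are cross-faded
with `α = (t − t_r)/t_APA`.  The published equation puts α on the
feedforward channel (pure feedback at window start, pure feedforward at
window end, then an instantaneous hand-back to feedback); the surrounding
text describes the opposite: a smooth shift *from* feedforward *to*
feedback.  Both are implemented (`blend_direction = "printed" |
"narrative"`).  The default is `"narrative"`, for a mechanical reason: the
planned trajectory starts from rest, so `τ_FF` vanishes at the window
start, making the narrative blend continuous at **both** window edges,
whereas the printed blend is discontinuous at the window end.  That
discontinuity injects a single-sample COP spike proportional to `K_FF`
(≈ +7 cm at healthy-scale gains) which dwarfs the genuine APA and aliases
the feature surfaces; the narrative blend reproduces the reported feature
scales (healthy APA ≈ 1.5–2.2 cm, Lean_max ≈ 5 cm).  Before target onset
the same feedback law regulates about `θ_0` (the publication is silent on
the preparation phase; regulating about upright is the only choice that
holds the unstable plant there).

## Simulation

Fixed-step RK4 at `dt = 1/1600 s` (0.625 ms), chosen finer than 1 ms and
exactly commensurate with the 80 Hz force-plate output grid (20 steps per
sample); the reference and blend weights are evaluated analytically on a
half-step grid so the RK4 substages see exact mid-step values.  Halving dt
changes the final lean angle by far less than 1e−6 deg.  The inner loop is
numba-compiled.  Trials comprise a 5 s quiet-stance preparation, the
movement, and a 2 s settling tail.  No process noise is modelled — the
closed loop is deterministic — and optional white measurement noise
(configurable SD in cm, explicit seed) is added to the *emitted* COP
channels only.  Divergence (|θ| > 45°) raises an error naming the gains.

## Segmentation

The planar COP is centered on its pre-onset baseline mean and projected on
the unit vector toward the target.  APA onset is the first post-onset
excursion opposite the target exceeding `max(2·SD_baseline, 1e−4 cm)`,
sustained ≥ 50 ms.  The 2·SD rule is the classic threshold algorithm; the
50 ms persistence suppresses single-sample noise crossings, and the
absolute floor handles the noiseless limit where the baseline SD is zero
(an arbitrarily small floor works because the model's COP leaves baseline
quadratically fast; 1e−4 cm is far below any instrument resolution).  APA
end is the first return of the centered signal to baseline; the crossing
time is linearly interpolated for `t_APA`, and the APA peak-to-peak is
clamped at the baseline crossing so the feature is independent of how far
past zero the next sample lands (without this, 80 Hz and full-rate analyses
of the same trial disagree by ~7%).  `Lean_max` is the global toward-target
maximum after APA end; `t_b` ends at the first local extremum after the
signal settles within ±10% of `Lean_max` around baseline (the published
"next small peak" endpoint, operationalized).  `t_total = t_r + t_f + t_b`
holds by construction.

No filtering is applied by default.  A zero-phase Butterworth low-pass is
available for real recordings, but it is off because filtfilt is
non-causal: a sharp APA leaks ~0.2 s backward in time, advancing the
detected onset by many samples and closing the APA window on filter
ripple.  The source recordings were analysed unfiltered as far as one can
tell.

Segmentation-time estimates are *not* unbiased estimators of the planner
parameters: the COP maximum trails/leads the end of the planned reach by
the inertial deceleration bump and the quasi-static overshoot
(`θ_ss/θ_f = K_P'/(K_P' + K_A' − m g L_COM) > 1`), so measured `t_f`
differs from planner `t_f` by ~0.2–0.3 s, and the measured APA duration is
shorter than the blend-window duration.  Reaction time is recovered within
one sample, and the spatial features agree with the simulator's internal
full-rate state to < 1%.

## Identification

Two unknowns `(K_P, K_FF)` are fitted so the model's `Lean_max` and APA
size match the measured pair simultaneously: bounded least squares on the
normalized residual vector, multi-start from a deterministic 7×7 gain grid,
scales defaulting to the target features.  Bounds default to
`K_P ∈ [5, 300] N·m/deg` (the lower bound is raised to 1.05× the static
stability limit per subject) and `K_FF ∈ [0, 30]`, enclosing all published
group means with margin.  Temporal parameters enter as given — they are
never optimized.

Two structural facts shape the solver.  First, the landscape has long flat
valleys in `K_P`, so refinement starts are organized per `K_FF` column
(best `K_P` plus the smallest competitive `K_P` in each qualifying column)
rather than globally.  Second, the APA-vs-`K_FF` curve is U-shaped at very
low `K_FF` (the feedback jolt late in the blend window makes its own APA),
so one feature pair can lie on two gain branches that match the features to
machine precision while differing in APA *duration* by a factor ~2.5.  When
the caller supplies the measured `t_APA`, near-tied optima are
disambiguated by APA-duration consistency; otherwise ties resolve to the
smallest `(K_P, K_FF)`.  With this, noiseless round trips over the
observed gain range recover both gains to better than 1e−10 relative, and
0.05 cm feature noise yields a median error of ~4%.

For synthetic data the identification should be run with the generating
temporal parameters (recorded in each trial's sidecar); feeding the biased
segmentation-time estimates into the planner changes the forward map and
biases the recovered gains by ~10% (this is what happens on real data,
where the true planner times are unknowable — the pipeline command does
exactly that, deliberately).

## Synthetic cohorts

The generator's defaults are the study conditions: two groups of 24
(healthy and PD), per-direction group means of the temporal parameters and
gains fixed to the published tables, demography per group (healthy
175.6 ± 8.8 cm, 77.28 ± 12.7 kg; patients 164.5 ± 8.4 cm, 68.5 ± 11.5 kg),
8 targets × 4 repetitions.  Between-subject spread is not published;
truncated normals with a 15% coefficient of variation are used, with
truncation at physiologic bounds (and at the per-subject stability limit
for `K_P`).  A subject-level factor with weight 0.7 correlates each gain
across directions; clinical scores exist for the patient group only
(UPDRS 26.14 ± 4.4, FRT 31.5 ± 10.2) and are generated through a Gaussian
copula on the subject factors with rank correlations +0.6 (K_P–UPDRS),
−0.6 (K_P–FRT), −0.6 (K_FF–UPDRS), 0 (K_FF–FRT) — signs chosen to match
the reported correlation pattern, magnitudes an assumption labelled as
such.  Direction-specific clinical correlations are not modelled (a single
scalar score cannot carry eight independent direction correlations through
one subject factor); the generated pattern is direction-uniform.

What passing tests on these cohorts do and do not show: they validate the
pipeline's statistical machinery and its sensitivity at the published
effect sizes, not the physiological claims — the generator draws gains
directly from the group-mean tables, so group separation is built into the
simulated world by construction.

## Statistics

Independent two-sample t-tests per direction and parameter (Welch default —
the groups plausibly differ in variance — Student's pooled variant
available), significance flags at 0.05 and 0.01, no multiple-testing
correction by default (a Holm option exists but is off, matching the
original analysis).  Spearman rank correlation with average-rank ties for
gain–clinical associations, patients only.  On null cohorts the empirical
type-I rate at α = 0.05 stays within binomial bounds over 1000 replicates.

## Problem sizes and numerical choices

Tests and the acceptance script run the simulator at the published
protocol scale (5 s preparation, 80 Hz output, 8 targets, n = 24 per
group) but keep the expensive loops modest by design: round-trip recovery
uses 20 gain pairs, surface checks a 10×10 grid over the observed gain
range, and the cohort significance check 50 seed replicates.  File values
are serialized with 9 significant digits; trial time axes are snapped back
to the exact uniform grid on read, making write→read→write byte-stable.
All randomness flows through explicit seeds; identical seeds give
bit-identical trials, cohorts and fitted gains.

## Known limitations

Single-segment dynamics only (no hip strategy), no sensory delays or
intermittent control, no muscle model; the return-phase trajectory is a
modelling convenience; measured-vs-planner time bias above; the low-K_FF
branch ambiguity is resolved heuristically via APA duration; synthetic
between-subject spread and gain–clinical correlation strengths are
assumptions, and outputs derived from them are labelled synthetic.
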