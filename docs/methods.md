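# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and sign conventions

Screen positions are Cartesian degrees of visual angle, origin at the
fixation cross, y up.  Angular positions on the object circle are *clock
angles*: arc degrees clockwise from 12 o'clock, `θ(x, y) = atan2(x, y)`
in `[0, 360)`.  Two sign conventions coexist deliberately:

* **target-relative endpoint angles** are clockwise-positive and wrapped
  into `(-180, 180]`.  An end point on the optimal aim point therefore has
  angle −45 to the intended object and 0 to the optimal point, and during
  learning the angle to the optimal point falls from +45 toward 0;
* **curvature** is counterclockwise-positive: a trajectory deviating to
  the left of its chord (counterclockwise around the scene centre for an
  outward saccade) has a positive signed area.

Both conventions are applied uniformly in the metrics, the generator and
the report, so the learning effect appears with the same sign everywhere.

## Scene and decoder

Defaults: 8 objects, object circle radius 7 deg, target areas to 9 deg,
half-width 180/n = 22.5 arc deg, clockwise distortion +45 arc deg,
feedback dot 1 deg.  The distortion is a field of the immutable scene
configuration, constant within a session.  Decoding assigns object *i*
when the clockwise angular distance from the object to the end point lies
in the half-open interval `[-22.5, +22.5)` and the radius does not exceed
9 deg (boundary inclusive).  The half-open rule is a package choice — the
area boundaries have measure zero for continuous end points — and it
guarantees that the target areas tile the disk exactly: every point with
r ≤ 9 is decoded to exactly one object, including the degenerate point at
the fixation cross (θ(0,0) := 0).  An end point beyond 9 deg decodes to
nothing and triggers the too-far message instead of feedback.

## Saccade detection

Speeds are two-point backward differences at 1 kHz with no smoothing by
default (an optional 5-sample moving average exists for noisy data); this
matches the causal online setting.  Two roles share the thresholds:

* *online* (what the simulated interface does): onset at the first sample
  with speed > 100 deg/s **and** ≥ 3 deg of travel from the fixation
  cross; offset at the first sample where the trailing 3-sample mean speed
  drops below 30 deg/s, the end point being that sample.  The travel
  criterion makes online onset fire mid-flight by design — it exists to
  reject fixational movement, not to timestamp the movement start.
* *offline* (trial parsing for analysis): the same 100 deg/s trigger, but
  the onset is walked back to the first sample of the surrounding run
  above 20 deg/s.  On the generator's noise-free streams this recovers
  the kinematic onset to within a few samples; the documented recovery
  tolerance (asserted over 1000 random saccades in the test suite) is
  6 ms for onset/offset and 0.3 deg for the end point.

The simulated feedback onset is the online-detected offset plus a
configurable detection-to-display delay (default 19 ms).

Validity filters are pure predicates: primary saccades need amplitude in
[3.5, 10.5] deg (inclusive), duration < 100 ms (strict) and latency
> 100 ms (strict); secondary saccades need amplitude < 5 deg (strict),
duration < 100 ms and latency in [100, 500] ms inclusive relative to the
primary offset.  Where inclusivity was a free choice it is fixed as just
stated and tested at the exact boundaries.

## Curvature index

Trajectories are translated to start at the origin, rotated so the end
point lies on +x (counterclockwise deviation maps to +y), linearly
resampled to 24 time steps over normalised time, and integrated by the
trapezoid rule.  The index is the signed net area (the reported values
carry sign; a total-absolute-area variant would lose the
toward/away-from-distractor distinction).  For a sinusoidal bow of peak
deviation *c* the index is 2c/π up to the ~0.15% trapezoid error at 24
steps, which is the closed-form anchor used by the tests.  The index is
invariant to rotation and translation of the trajectory.

## Session structure and phases

A session is 20 circle-off baseline trials, 200 feedback trials, 20
circle-off aftereffect trials.  Phases: *pre* = baseline block, *early* /
*late* = first/last 20 feedback trials (window length configurable), *mid*
= the remaining feedback trials, *post* = final block.  Circle-off trials
skip distortion, decoding, feedback and learning.

## Synthetic data generator

The generator's purpose is to produce data with the statistical structure
the analysis assumes, with every assumption exposed as configuration:

* **Kinematics** — minimum-jerk position profile along the start→landing
  chord; duration from the main sequence `2.2·A + 21` ms (generic
  oculomotor textbook values, not fitted to any dataset); optional
  perpendicular sinusoidal bow (ccw-positive) for curvature studies.
* **Noise** — isotropic Gaussian landing noise (default SD 0.5 deg) plus
  angular aim noise (default SD 5 arc deg).  At radius 7 the combined
  angular scatter is ≈ 6.5 arc deg, so a converged learner stays well
  inside the ±22.5 arc deg success window and late-phase decoding
  succeeds almost always, while an unadapted aim virtually always fails.
  Streams carry no per-sample position noise by default; detector
  robustness to sample noise is exercised via the smoothing option.
* **Timing** — fixation period uniform 500–1000 ms; primary latency
  lognormal with median 350 ms (log-SD 0.3) plus an early-learning
  increment (default +80 ms) so the latency-by-phase pattern can be
  exercised qualitatively; secondary saccades occur with probability 0.9,
  latency uniform 150–350 ms, aimed at the learner's *current* goal
  (the optimal point once learned) with 0.3 deg landing noise.
* **Learners** — `error_based`: `a ← a − η·(feedback angle to intended)`,
  η default 0.15, so the gap to −45 decays geometrically by (1−η) per
  trial; `reward_based`: on error add a N(0, σ_explore) step (σ default
  15 arc deg), on success keep the aim and shrink σ by 0.95.  By default
  the learner mode follows the feedback type (motor → error-based,
  action → reward-based), treating the two models as illustrative
  instruments, not claims about human mechanisms.
* **Onset delay** — per-participant number of feedback trials before
  updating begins, drawn uniformly from [20, 120] at cohort level.  This
  staggers convergence across a cohort: pooled first-session angles to
  the optimal point then have one mode near +45 (still aiming at the
  intended object) and one near 0 (converged), 45 arc deg apart, which is
  what makes the pooled distribution bimodal during first-session
  learning.
* **Savings** — session 2 starts at baseline aim (so pre-phase angles are
  centred on zero by construction); when feedback resumes the learner
  retrieves `savings × learned offset`, its learning rate is raised to
  `min(1, η(1+savings))`, and its onset delay shrinks by `(1−savings)`.
  With savings = 0 session 2 reproduces first-session learning conditions
  exactly; with savings = 1 relearning is immediate.
* **Cohorts** — default n = 22, feedback order counterbalanced (even
  participants motor-first).  A master seed fans out through
  `SeedSequence.spawn`, one child per participant, so cohorts are fully
  deterministic and participant streams are independent.

What the generator does **not** emulate: fixational eye movements,
blinks, pupil artefacts, per-sample tracker noise, head movement, screen
pixelation, latency-accuracy trade-offs, or any mechanistic commitment
about how humans mix error- and reward-based learning.  Tests passing on
this generator therefore validate the pipeline's arithmetic and the
statistics' calibration, not claims about real eyes.

## Statistics

* **Permutation t-test** — sign-flip permutation of differences
  (paired/one-sample) or group-label permutation with a Welch statistic
  (two-sample); add-one p-value `((#extreme)+1)/(n_perm+1)`, never zero,
  seed-reproducible.  Default 10 000 permutations.
* **Mixed ANOVA** — classical balanced one-between / one-or-two-within
  sums-of-squares decomposition (Type-III-equivalent under the enforced
  balance; unbalanced tables raise an explicit error, mirroring the
  practice of dropping participants to keep balance).  Permutation nulls:
  between effects permute participant group labels; within effects and
  all interactions involving a within factor permute the within-cell
  labels independently per participant.  Both the parametric F (with df)
  and the permutation p are reported, and the scheme is logged in the
  result object.  The implementation is validated in the tests against a
  saturated-OLS decomposition (statsmodels) and against pingouin's mixed
  ANOVA for the one-within case.
* **Hartigan's dip** — computed exactly from the definition: the minimal
  sup-distance between the empirical CDF and any unimodal CDF (convex
  then concave, an atom allowed at the mode), by enumerating mode
  positions and solving each side's greatest-convex-minorant /
  least-concave-majorant band-feasibility problem; O(m²) with a numba
  core.  Validated against an LP brute force over piecewise-linear
  unimodal CDFs for small n, the two-point-mass limit 0.25, the point
  mass 0 and the 1/(2n) lower bound.  P-values are Monte-Carlo against
  uniform(0,1) nulls of the same n (the classical reference null); the
  null can be precomputed once per sample size and reused.  Note the
  uniform null makes the test conservative for peaked unimodal data
  (e.g. Gaussian samples reject at well below the nominal rate) and
  exact for uniform data — the tests check both.
* **Holm correction** — statsmodels' step-down implementation behind the
  package surface, with the hand-computed example frozen as a test.
* **Learning trend** — the per-trial binary decoding-outcome table
  (centred trial number) is exported for any external mixed-model
  workflow; the package's own trend test fits a per-participant logistic
  slope by IRLS and tests the slopes against zero with a one-sample
  sign-flip permutation test (alternative: mean slope > 0).  Separated or
  degenerate outcome series (all successes/failures) fall back to a
  ridge-penalised fit (λ = 1) and are flagged in the slope table.  This
  is a deliberately simple participant-level trend test, not a trial-level
  autoregressive GLMM; the exported table is the interface for the
  latter.

When dip tests are applied to pooled cohort angles inside the analysis
stage, samples larger than 2000 are subsampled (seeded) before the dip —
at the modes' 45-arc-deg separation the test's power is unaffected and
the O(m²) cost stays bounded.

## Problem sizes used in the checks

The statistical-calibration checks run 2000 null simulations per test
(t-test and trend test, 199 permutations each, so the achievable p-grid
is exact at α = 0.05); dip power uses 200 mixture datasets of n = 500
against a shared 999-sample null; learner-rate recovery averages 25
motor-feedback sessions of 200 feedback trials; the cohort-level pattern
checks use 200 cohorts of n = 22 (bimodality on the first 40, with pooled
angles subsampled to 1000).  These sizes give Monte-Carlo error
comfortably inside the asserted bands while keeping the default test run
fast.

## Known limitations

* The reward-based learner's converged aim is wherever its random walk
  entered the success window, not exactly the optimal point, so action
  feedback leaves a small residual mean angle — an intentional echo of
  incomplete adjustment under success-only feedback.
* Post-phase behaviour keeps the learned aim (no extinction model), so
  aftereffect decay is not simulated.
* The online onset criterion (velocity + 3 deg travel) timestamps
  mid-flight by construction; only the offline parser is a movement-onset
  estimator.
* The dip's Monte-Carlo null assumes continuous data; heavy ties in
  user-supplied samples shift the null and the p-value should then be
  interpreted with care (the statistic itself handles ties exactly).
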