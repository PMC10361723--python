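# Methods

## Coordinate frame and kinematics

Tracks are planar (midplane imaging) sequences of positions in µm. All
kinematic quantities are computed in a polar frame about the LRO center
after rotating the image so the anterior axis points along +y; +x is the
embryo's right and angles are standard counterclockwise radians (theta =
π/2 at the anterior pole). The imaging literature never states the image
handedness, so this convention is a package choice; every derived quantity
is rotation-equivariant, which the test suite checks explicitly.

Per consecutive-frame step: the angle change is wrapped to (−π, π] (ties
at π resolve positive), angular velocity is `dtheta/dt` with `dt` = 0.2 s
per frame interval, and the displacement is projected on the outward
radial and counterclockwise tangential unit vectors *at the step's first
point*. Normalized `lr`/`pa` coordinates are Cartesian position divided by
the LRO radius, clipped to [−1, 1]. Steps with either endpoint inside half
the LRO radius are discarded (boundary inclusive: r = R/2 is kept), since
angular quantities degenerate near the rotation axis.

Sector summaries use equal-width angular sectors; sector 0 starts at the
anterior direction and proceeds counterclockwise (the origin is a
configurable parameter — published figures do not define theirs).
Directionality is the angle of a step's displacement measured from the
outward radial direction at its first point, in [0, 2π): π/2 is pure
counterclockwise-tangential motion, 0 is pure outward motion. Zero-length
displacements have undefined direction and are skipped.

The regression's unit of observation is the track (median angular
velocity, mean lr, mean pa), one row per track per stage; whether the
original analyses used per-step or per-track rows is not fully explicit,
and per-track is the conservative choice for the embryo-level hierarchy.

## Flow regression

Both experimental designs share the fixed structure
`1 + Group*LR + Group*PA + Group*Time` (12 coefficients with three
groups), with Sham as the treatment-coding reference and
`Time = stage − 6` (stage 6 is the first post-intervention observation;
the original time coding is unstated, so intercept values are comparable
only up to that choice). The random part is an unstructured covariance
over intercept and the two group dummies per embryo — 6 covariance
parameters plus the residual variance, matching the 7 covariance
parameters reported for the published fits. Estimation is REML via
statsmodels MixedLM with Wald confidence intervals and p-values.

When the data carry no between-embryo variance in the group response the
full random structure is singular; the fit is retried across optimizers
(bfgs first — on degenerate data lbfgs can report convergence at a
spurious point) and then downgraded to a random intercept with a logged
warning. This downgrade is the expected path for the synthetic generator,
whose random effects are intercept-only.

## AAV stage models

Sham: `AAV(t) = φ1 + φ2 (t − 5)` with φ1 = 0.356, φ2 = 0.0362 and a
normal random effect on φ1 (SD 0.0378). Post-extraction (anchored at
5 ss): `AAV(t) = φ1 [σ(0.9(t−5−φ2)) − σ(−0.9 φ2)] + φ3 σ(8(t−5.5))` with
φ1 = 0.778, φ2 = 0.969, φ3 = 0.126 and a random effect on φ3 only
(SD 0.169); the subtraction of `σ(−0.9 φ2)` anchors the curve at
essentially zero at the extraction stage (the printed source formula is
typographically mangled; this is the unique reading consistent with a
smooth increase from zero, and it reproduces the published behavior:
AAV(5) ≈ 0.0023, AAV(8) ≈ 0.567 rad/s).

Stages 3-5 scale with the motile-cilia fraction (5.57%, 42.9%, 62.1% at
3-5 ss against 76.3% at 6 ss), by linearity of Stokes flow:
`AAV(t) = fraction(t)/fraction(6) × AAV(6)`. This rescaling rule (not the
linear extrapolation) is used for sham stages 3-5. Interventions at other
stages reuse the 5 ss curve shifted in time; for 3/4 ss interventions the
shifted trajectory's stages ≤ 5 are rescaled off its own stage-6 value —
the exact analogue of the sham formula. A double intervention (5+7 ss)
re-anchors the same curve at the second extraction (AAV(7) ≈ 0). Negative
per-embryo draws are not truncated: the regression-based model lives on
the real line and locally negative (clockwise) flow is observed in real
vesicles.

`fit_aav_model` exploits that the recovery model is linear in its single
random effect: conditional on the fixed effects the marginal likelihood
is Gaussian with a rank-one-plus-diagonal covariance per embryo
(Woodbury), so the model is fitted by direct maximum likelihood with
Nelder-Mead multistart rather than a general NLME machine; standard
errors come from a central-difference Hessian. The sham model is an
ordinary linear mixed model.

## Symmetry-breaking model

Signal: `S = Σ_{t=3..8} AAV(t) W(t)`, weights non-negative in arbitrary
units relative to the threshold of 1. Outcome rule: normal situs with
probability 0.9 if `S > 1` (strict — S equal to the threshold counts as
not exceeded) and 0.5 otherwise, so the population defect probability
always lies in [0.10, 0.50]. The published text once calls the in-between
quantity the "abnormality rate"; the implementation follows the explicit
per-embryo rule (normal at 50%/90%).

Fitting maximizes a binomial log-likelihood over the observed
normal/abnormal counts of all experiment series simultaneously, with each
series' defect probability computed from a frozen cohort of 1000
simulated virtual organizers (common random numbers, so the likelihood is
deterministic in the weights). By default the cohort average of the exact
per-embryo defect probabilities is used rather than Bernoulli draws —
same estimand, lower variance; a flag restores literal draws. Predicted
probabilities are clipped to [1e-6, 1−1e-6].

Optimization is bounded multistart local search: the uniform guess
W(t) = 1 plus random starts in the box [0, 5]^6 (the published
description of the start box is typographically ambiguous; [0, 5]
comfortably brackets threshold-crossing signals and is configurable),
followed by a longer polish of the best few distinct incumbents. The
local solver is bounded Powell, because the cohort defect probability is
a step function of the weights and gradient-based solvers stall on its
flat segments. The default is 200 starts; the original 100 000-run
multistart is reachable through `n_starts`.

Two identifiability features matter. First, stage-3 flow is small and
nearly proportional across scenarios, so likelihood is almost invariant
to trading W(3) against mid-stage weights; among solutions within
`ridge_tol` = 0.5 log-likelihood units of the optimum (well inside the
one-degree-of-freedom 95% profile width) the minimum-total-weight one is
returned as the parsimonious representative of the maximum-likelihood
set. Second, which weights are identified at all depends on the scenario
set: only an intervention that ablates a stage's flow constrains that
stage's weight, so weight-recovery experiments use the stage-scan design
(single interventions at each of 3-8 ss) rather than the subset of series
with printed counts. Contribution per stage is
`W(t) × E[AAV_sham(t)]`, normalized to sum to one.

The default fitted series are those with printed counts (3 ss: 2/13,
4 ss: 7/26, 5 ss: 14/40, 6 ss: 4/27, 5+7 ss: 6/16) plus a sham series
whose counts are a synthetic stand-in (4/40, the model's 10% floor);
full series tables can be supplied as CSV.

## Synthetic data generator

Tracks are rigid rotations about the LRO center at a local angular
velocity `ω = ω0 + b_embryo + group offsets + grad_pa·PA + grad_lr·LR +
slope·(stage − 6)` plus i.i.d. Gaussian positional jitter — the minimal
process for which angular velocity is well defined and exactly
recoverable. ω is evaluated at the track's angular midpoint (three
fixed-point iterations) so the per-track mean position, the regressor
used downstream, matches the generative covariate to first order in the
arc length. Start angles are uniform on [0, 2π); start radii uniform on
[R/2, R] so all points survive core exclusion by default (`include_core`
samples the full disc to exercise the filter). Seeding uses one root seed
with per-embryo streams spawned deterministically.

Defaults are the fitted flow-field conditions: ω0 = 0.25 rad/s,
grad_pa = 0.16, grad_lr = 0.004, stage slope 0.021 rad/s per somite,
radius 25 µm, dt = 0.2 s, stages 6-8. No noise model is published for the
real tracking data, so the between-embryo SD (0.05 rad/s) and positional
jitter (0.2 µm) are fixture choices of plausible magnitude. The generator
emulates the statistical structure the downstream stages assume — it does
not emulate tracking artifacts (missed detections, identity switches,
out-of-plane motion) or any hydrodynamics, so passing recovery tests
demonstrates correctness of the estimators, not robustness to real
tracking error.

Outcome series draw per-embryo trajectories from the stage models,
integrate the signal against known true weights and draw situs by the
threshold rule. The recovery experiment's truth (0, 0.8, 1.6, 1.2, 0, 0
for stages 3-8) puts the unperturbed cohort above threshold, the regime
of the fitted published model (which predicts ~10% sham defects).

## Problem sizes and numerical choices

Weight fits use 200 multistarts over 1000-embryo cohorts (~10 s); the
regression-coverage experiment uses 100 replicates of 20 embryos × 3
stages × 30 tracks (~1 s per replicate via the vectorized kinematics
path); the AAV fit uses 8 Nelder-Mead starts. Mixed-model convergence
tolerance follows statsmodels defaults with maxiter 500. Fisher's exact
test uses the minimum-likelihood two-sided rule (the convention of the
statistical software named in the original analyses), degenerate margins
return p = 1, and zero-variance paired differences return p = 0 with a
warning. Empty kinematic sectors report missing values, never zero.

## Known limitations

- Planar kinematics only; no 3-D reconstruction or physical flow
  simulation (the viscosity manipulation is represented solely through
  its fitted regression effects).
- The stage-weight likelihood is flat in directions the scenario set does
  not probe; fitted weight values there are representative, not
  estimates. Restricted models and contribution shares are the robust
  summaries.
- The sham outcome series entering the default fit is a synthetic
  stand-in, and reproduction of the published per-track regression table
  requires the original source-data files, which are not distributed
  here.
- Intervention curves for stages other than 5 ss are time-shifted copies
  of the 5 ss fit (stated for 3/4 ss; extended to later stages by the
  same rule), not independently fitted curves.
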