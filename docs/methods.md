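# Methods

This package implements an end-to-end "ethomics" analysis for Duchenne
muscular dystrophy (DMD): behavioral fingerprints are extracted from
full-body kinematic recordings, combined by Gaussian-process (GP)
regression to predict clinical scales cross-sectionally and six months
ahead, and finally used to select a monotone disease-progression biomarker
by constrained Bayesian optimization. Because no patient data ship with the
package, every stage runs on a bundled synthetic-cohort simulator; this
note describes the models, the parameters that matter, and what the
synthetic results do and do not establish.

## Data model and preprocessing

A recording is one participant-visit: 22 joints × 3 Euler angle channels
(degrees; X = abduction/adduction, Y = internal/external rotation,
Z = flexion/extension) plus 23 segment positions × 3 axes (meters), sampled
at 60 Hz. Axes are x forward, y left, z up. Two text formats are read: a
CSV dialect (`time_s`, 66 angle columns, 69 position columns) and an
MVNX-subset XML dialect from which only the segment/joint declarations and
the per-frame `jointAngle`/`position` payloads are used.

Load-time gap repair linearly interpolates missing runs up to 0.5 s and
refuses longer gaps or gaps touching the stream boundary — interpolating
long stretches would bias duty-cycle and velocity statistics, and refusing
loudly is safer than guessing.

All channels are smoothed with a centered moving average of window 21
(0.35 s at 60 Hz) before feature extraction. The edge policy — a
symmetrically shrinking window, `min(21, 2k+1)` at distance `k` from an
edge — keeps the output length equal to the input length with no phase
shift. Velocities and accelerations are central finite differences
(one-sided at the two boundary frames).

## Fingerprint families

Nine families produce 87 named scalars per visit (3+3+8+9+17+8+15+15+9):

1. **Workspace volume** (cm³, full/upper/lower body). Segment positions are
   re-expressed relative to the pelvis, binned into half-open 2 cm voxels
   anchored at the pelvis-frame origin, and the volume is the non-empty
   voxel count × 8 cm³. Occupancy frequency is irrelevant — a voxel counts
   once.
2. **Hip orbit area** (cm²) on the sagittal (xz), coronal (yz) and
   transverse (xy) planes: the pelvis-relative hip trajectory binned into
   2×2 cm cells, count × 4 cm².
3. **Extremity velocity** (8): mean and variance of the per-frame Euclidean
   speed of each hand and foot. "Magnitude by root-mean-square" is read as
   the per-frame 3-vector norm; the alternative (norm/√3) differs only by a
   global constant per feature and cannot change any rank-based or
   regression result.
4. **Average joint velocity** (9): mean |angular velocity| of nine major
   sagittal channels.
5. **Autocorrelation FWHM** (17, s): the biased autocorrelation of each
   angular-velocity channel is evaluated to a 10 s lag; the full width at
   half maximum is twice the first (sub-sample interpolated) lag where
   r crosses 0.5. Channels that never cross within 10 s — including
   degenerate constant channels — return the 20 s cap.
6. **Logistic scale** (8, deg/s): maximum-likelihood scale σ of a logistic
   distribution fitted to each angular-velocity channel, initialized at the
   moment estimate √3·sd/π. Zero-variance channels return σ = 0 rather than
   erroring so batch extraction stays total.
7. **Joint-velocity correlations** (15): Pearson r over configured channel
   pairs (sagittal hip–knee and left–right couplings, coronal hip
   couplings, trunk–hip links). A degenerate constant channel contributes
   r = 0.
8. **Duty cycle** (15): a motion detector computes a 100-bin histogram of
   |angular velocity| over its range, then scans upward from the modal
   (rest) bin for the first bin with empirical probability < p_set
   (default 0.005); the left edge of that bin is the motion threshold. The
   three Euler-axis masks of a joint are OR-combined; the duty cycle is the
   true fraction. If no sparse bin exists after the mode (no detectable
   rest state) everything above the signal minimum counts as motion. The
   detector presumes a dominant rest mode; it is only meaningful when the
   joint rests for the majority of frames, which holds for everyday
   activity.
9. **Segment acceleration** (9): mean/variance of the per-frame
   acceleration magnitude of the hands, feet and pelvis.

The exact channel subsets behind the 9/17/8/15/15/9 dimensions are not
canonical; they are configurable (`FamilyConfig`) and the defaults cover
the major limb and trunk joints. The reference segment is the pelvis for
both workspace and hip orbit (the trunk-vs-pelvis distinction is below the
resolution of anything downstream).

**Group screening** uses the tie-corrected Kruskal–Wallis one-way ANOVA per
feature (two groups → df 1), p ≤ 0.05, with no multiplicity correction by
default (screening is descriptive here; Benjamini–Hochberg can be applied
downstream if inference is intended).

## Prediction protocol

Rows are subject-visits; the grouping key is the subject, always. The outer
loop is leave-one-subject-out (LOSO): all visits of one subject form one
fold. Per outer training fold, a floating wrapper selection (forward
addition with conditional backward elimination, improvement tolerance 1e-6,
subset cap 10, minimum 1) searches feature subsets scored by pooled
inner-LOSO RMSE of a GP regressor.

The GP is zero-mean with an isotropic squared-exponential kernel plus white
noise on z-scored features and target (scaling statistics always from the
training rows of the current fold). During subset search the
hyperparameters are fixed (length-scale 3·√d, relative noise 0.1) so that
candidate subsets are compared on equal footing; the fold's final model
re-tunes both hyperparameters on a 5×5 log-spaced grid by inner-LOSO RMSE.

Each held-out subject is predicted with the subset selected on its own
training fold. The modal ("most frequent") subset across folds is reported
as the deployable subset and as a robustness diagnostic, with ties broken
to the smaller, then lexicographically first subset. Refitting *every*
fold with the modal subset is available (`subset_policy="most_frequent"`)
but is not the default: the modal subset aggregates selections that saw
each fold's test subject, and on small cohorts this contaminates the
out-of-fold estimate measurably (permuted-target pooled R² up to ≈0.5,
versus ≤0.1 under the per-fold policy). Pooled out-of-fold predictions
yield the aggregate RMSE and R² (1 − SS_res/SS_tot; may be negative).

Cross-sectional targets: 6MWD and NSAA on ambulant visits only; PUL and
MyoGrip on all visits. Rows missing a target are dropped for that target
only; more than 20% missing aborts (no imputation). Longitudinal pairs join
each visit T to a later visit with gap within 6 ± 2 months; fingerprints
(or the baseline score) at T predict the score at T+6. The
fingerprints-vs-score comparison runs both arms under the modal-subset
refit: per-fold selection is too unstable for a many-feature model at this
cohort size, and the single-feature score-only arm is identical under
either policy, so the comparison stays like-for-like. Learning curves
evaluate min(C(n,k), 1000) seeded subject subsets per k and report the mean
and s.d. of the aggregate RMSE.

## Progression biomarker

The biomarker family is

    Y(age) = (tanh(X) − tanh(X_min)) / (tanh(X_max) − tanh(X_min)),
    X = α·age − β,  X_min = X(0),  X_max = X(25),

with α ∈ (0, 0.5] per year and β ∈ [0, 5]. Y is exactly 0 at age 0, exactly
1 at age 25, and non-decreasing for any valid parameters; α = 0 degenerates
the normalization, so the implemented lower bound is 1e-6. Clinical
feasibility requires Y(5) ∈ [0.01, 0.15] (closed) and Y(15) ∈ [0.5, 0.8].

The objective of the parameter search is the pooled LOSO RMSE of GP
regression of Y(age) on the fingerprints, with forward-only selection
(cap 10) inside — a cheaper selection than the full floating procedure,
acceptable because the objective only ranks parameter pairs. The target is
z-scored before regression, making the objective scale-free. This matters:
the raw RMSE of a curve with smaller spread over the observed ages is
smaller for trivial reasons, so an unnormalized objective would always
drift to the flattest curve the feasibility boxes allow, regardless of the
data. Feasibility depends on (α, β) analytically, so infeasible proposals
receive a fixed penalty (10.0) without touching the data.

Optimization is expected improvement (ξ = 0.01) under a GP surrogate
(scikit-learn, RBF + white kernel on box-scaled parameters): 10 feasible
uniform draws form the initial design (200 attempts per point before
aborting), then each iteration fits the surrogate to all evaluated points
and proposes the feasible candidate (of 2048 uniform draws) maximizing EI,
to a default budget of 100 evaluations. The optimizer returns the best
feasible parameters, the age-grid curve, and per-visit out-of-fold
predicted scores — the individual fingerprint-derived trajectories.

## Synthetic cohort

The generator is a study-shaped stand-in, not a biomechanical simulation.
A DMD subject carries a latent severity s(age) ∈ [0, 1] following the same
tanh family as the biomarker with generating truth (α*, β*) = (0.15, 1.8) —
chosen feasible (Y(5) ≈ 0.087, Y(15) ≈ 0.718) so that parameter recovery is
well-posed; controls have s ≡ 0. Default cohort: 15 DMD and 15 control
subjects, baseline ages 4–17, DMD visits at months 0/6/12, controls at
0/12, 120 s of kinematics per visit.

Movement is sum-of-sinusoid joint oscillation (0.3–1.5 Hz) gated by a
two-state rest/move bout process (≈2 s bouts, baseline on-fraction 0.40 —
low enough that the rest mode dominates the velocity histogram, which the
duty-cycle detector requires), plus additive logistic angle noise. Severity

* scales oscillation amplitude by (1 − 0.6 s) and frequency by (1 − 0.5 s),
* shifts hip/knee flexion baselines by +12 s and +8 s degrees,
* scales the bout on-fraction by (1 − 0.45 s),
* scales the logistic noise by (1 − 0.5 s),
* relaxes the hip–knee sagittal anticorrelation (0.8 → 0.8(1 − 0.8 s)) and
  strengthens the left–right coronal hip coupling (0.2 → 0.2 + 0.7 s,
  capped at 0.9) — the waddling-gait signature.

Non-ambulant subjects (s ≥ 0.55) have lower-body signal *and* noise
attenuated ×0.25 — not zeroed — so upper-body features stay informative.
Clinical scores decrease linearly in s with Gaussian noise at clinically
plausible test-retest magnitudes (6MWD sd 30 m, NSAA sd 2 of 34, PUL sd 2
of 42, MyoGrip sd 6%), integer grading and ceiling/floor clipping; 6MWD is
0 when non-ambulant. Each subject owns one RNG seed split into named
kinematics/scores substreams, so cohorts are bit-reproducible and effects
are independently modifiable.

Effect sizes were calibrated once to reproduce the *direction and
significance* of the group differences the analysis expects (slower
extremities, smaller workspace, lower duty cycle, smaller logistic scale,
wider autocorrelation FWHM, shifted hip angles, altered couplings) — never
any particular published value.

A second, fingerprint-level generator (`generate_feature_cohort`) skips the
kinematics entirely: informative features are affine in s with Gaussian
noise (sd 0.1 per unit-severity effect) plus pure-noise features, with the
same score model. It is the desk-scale instrument for protocol-level
experiments (leakage canaries, learning curves, biomarker recovery) where
the kinematic layer would only add runtime.

## What the synthetic results show — and what they do not

Passing tests establish that the pipeline recovers structure *its own
generator planted*: monotone severity effects, a recoverable progression
curve, fingerprints that out-predict a noisy baseline score. They say
nothing about real DMD kinematics — the generator's movement model is far
simpler than human behavior (no gait cycle, no activity repertoire, no
sensor drift), recordings are minutes rather than hours, and the
feature-noise and score-noise magnitudes, though chosen at plausible
levels, are assumptions. Absolute R²/RMSE values on synthetic cohorts are
properties of the generator settings, not estimates of clinical
performance. In particular, the walking scales (6MWD/NSAA) are evaluated on
the ambulant subcohort only, where desk-scale cohorts leave few subjects
and a restricted severity range; their synthetic cross-sectional R² is
correspondingly unstable, while full-cohort scales (PUL, MyoGrip) are the
stabler read-out at this scale.

## Numerical choices and degenerate inputs

* Problem sizes throughout the test-suite and the analysis drivers are
  desk-scale by design: 8–20 subjects, 30–120 s recordings, BO budget
  12–100 — chosen so a single CPU reproduces everything quickly.
* Kernel matrices get an escalating jitter (0 → 1e-2) before Cholesky
  failure is raised.
* Wrapper-selection ties resolve to the earliest feature in column order;
  the selection always returns at least one feature.
* The learning-curve subset sampler enumerates exhaustively when
  C(n,k) ≤ 1000 and otherwise samples distinct subsets uniformly, seeded.
* Zero-variance channels: logistic σ = 0, correlation r = 0, motion mask
  all-false, autocorrelation FWHM = cap.
* Constraint intervals of the biomarker are closed; bounds of (α, β) are
  closed except α > 0.

## Known limitations

* The MVNX reader handles the angle/position subset only — no sensor,
  orientation or center-of-mass payloads, and no BVH/C3D.
* The duty-cycle detector fails gracefully but uninformatively (duty → 1)
  on signals without a rest mode.
* The BO surrogate is fitted on as few as 10 points early on; with very
  small budgets (< ~15) results are close to random feasible search.
* `subset_policy="most_frequent"` reproduces the aggregate-subset protocol
  exactly but carries the selection optimism described above; compare both
  policies before quoting absolute numbers.
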