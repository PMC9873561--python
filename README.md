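# kinedmd

Ethomic fingerprinting and disease-progression modeling for full-body
kinematics in Duchenne muscular dystrophy (DMD).

Clinical trials in DMD lean on semiquantitative, motivation-dependent
endpoints (6-minute walk distance, North Star Ambulatory Assessment,
Performance of the Upper Limb, grip strength). This package implements an
alternative read-out built from wearable full-body motion capture of
everyday behavior: a 23-segment / 22-joint skeleton sampled at 60 Hz is
condensed into 87 named behavioral features ("ethomic fingerprints") in
nine families — workspace volume, hip orbit area, extremity velocities,
average joint velocities, autocorrelation width (FWHM), logistic velocity
scale, joint-velocity correlations, duty cycle, and segment accelerations.
The fingerprints are screened for group differences (Kruskal–Wallis),
combined by Gaussian-process regression under nested leave-one-subject-out
(LOSO) cross-validation with wrapper feature selection to predict the
clinical scales cross-sectionally and six months ahead, and finally used to
select a monotone progression biomarker

    Y(age) = (tanh(X) − tanh(X_min)) / (tanh(X_max) − tanh(X_min)),
    X = α·age − β,   X_min = X(0),  X_max = X(25),
    α ∈ (0, 0.5],  β ∈ [0, 5],

anchored at Y(0) = 0 and Y(25) = 1, with clinical feasibility boxes
Y(5) ∈ [0.01, 0.15] and Y(15) ∈ [0.5, 0.8]. The (α, β) pair is chosen by
expected-improvement Bayesian optimization of the LOSO error of regressing
the candidate curve on the fingerprints: the progression scale that
daily-life behavior can predict most consistently.

No patient data are included. A synthetic-cohort simulator (DMD and
control subjects with a latent tanh-shaped severity driving both the
kinematics and the clinical scores) makes every stage runnable and
testable end to end; see `docs/methods.md` for the model and its
limitations.

Audience: biostatisticians and movement scientists prototyping digital
biomarkers from wearable kinematics, and anyone who needs a tested
reference implementation of nested-LOSO GP prediction or constrained
sigmoid-biomarker search.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (14 DMD and 8 control subjects, 90 s of kinematics per visit,
seed 2026) and write their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py        # recordings + clinical scores
python analysis/02_extract_fingerprints.py   # 87 features per visit
python analysis/03_group_screen.py           # Kruskal–Wallis screening
python analysis/04_cross_sectional_prediction.py
python analysis/05_longitudinal_prediction.py
python analysis/06_fit_biomarker.py
```

Outputs from this configuration:

```
54 / 87 features differ between groups at p <= 0.05.

Cross-sectional performance (pooled out-of-fold):
  pul      RMSE   4.828  R^2  0.710  (42 visits)
  myogrip  RMSE  10.600  R^2  0.814  (42 visits)

Longitudinal (T -> T+6 months) aggregate RMSE:
  pul      score-only   3.733 vs fingerprints   2.311 -> fingerprints
  myogrip  score-only   9.496 vs fingerprints   4.815 -> fingerprints

Fitted biomarker: alpha = 0.2656 /year, beta = 3.5871
Y(5) = 0.010 (box 0.01-0.15), Y(15) = 0.690 (box 0.5-0.8), feasible = True
```

Reading this: more than half of the fingerprints separate the synthetic
DMD group from controls in the directions the generator plants (slower,
smaller, less active movement). The full-cohort scales (PUL, MyoGrip) are
predicted well cross-sectionally and are predicted *better* six months
ahead by the fingerprints than by the scale's own baseline value — the
headline property of a behavioral biomarker. The walking scales (6MWD,
NSAA) are restricted to the ambulant subcohort, which at this desk scale
leaves too few subjects for stable estimates (their R² fluctuates around
zero here; see `docs/methods.md`). The fitted progression curve satisfies
both clinical feasibility boxes; the generator's true severity curve was
(α*, β*) = (0.15, 1.8) with Y(5) = 0.087, Y(15) = 0.718.

The same stages are exposed as a CLI (`kinedmd simulate|fingerprint|
screen|predict-cross|predict-longitudinal|fit-biomarker|run-all`) with a
TOML configuration file, and as plain library calls:

```python
from kinedmd import (GeneratorConfig, generate_cohort, extract_fingerprints,
                     CohortDataset, cross_sectional_predict)

manifest, recordings = generate_cohort(GeneratorConfig(n_dmd=8, n_hc=8), seed=0)
features = {vid: extract_fingerprints(rec) for vid, rec in recordings.items()}
```

Note: generated cohorts are written as per-visit CSVs and can reach
hundreds of MB at the default recording length; they are reproducible from
the seed and safe to delete.

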