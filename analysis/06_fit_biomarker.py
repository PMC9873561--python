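"""Fit the tanh progression biomarker by constrained Bayesian optimization.

Searches (alpha, beta) with EI under a GP surrogate, subject to the
clinical feasibility boxes at ages 5 and 15; the objective is the LOSO
error of regressing the candidate curve on the fingerprints. Reads
results/features.csv, writes results/biomarker_curve.csv,
results/biomarker_visit_scores.csv and results/biomarker.json.
"""

import importlib
import logging

from kinedmd.pipeline import stage_fit_biomarker

CONFIG = importlib.import_module("00_config").CONFIG

logging.basicConfig(level=logging.INFO)
report = stage_fit_biomarker(CONFIG)
print(
    f"\nFitted biomarker: alpha = {report['alpha']:.4f} /year, "
    f"beta = {report['beta']:.4f}"
)
print(
    f"Y(5) = {report['Y_age5']:.3f} (box 0.01-0.15), "
    f"Y(15) = {report['Y_age15']:.3f} (box 0.5-0.8), feasible = {report['feasible']}"
)
print(f"Objective (LOSO RMSE of the z-scored curve): {report['objective_loso_rmse']:.4f}")
gen_alpha, gen_beta = 0.15, 1.8  # the generator's severity truth
print(f"Generator truth for comparison: alpha = {gen_alpha}, beta = {gen_beta}")
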