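"""Cross-sectional prediction of the clinical scales from fingerprints.

Nested leave-one-subject-out GP regression with wrapper feature selection,
on the DMD visits (ambulant visits only for 6MWD and NSAA). Reads
results/features.csv, writes results/cross_sectional.json plus pooled
predicted-vs-actual CSVs per scale, and prints aggregate RMSE and R^2.
"""

import importlib
import json
import logging
from pathlib import Path

from kinedmd.pipeline import stage_predict_cross

CONFIG = importlib.import_module("00_config").CONFIG

logging.basicConfig(level=logging.INFO)
report = stage_predict_cross(CONFIG)
print("\nCross-sectional performance (pooled out-of-fold):")
for target, res in report["targets"].items():
    print(
        f"  {target:8s} RMSE {res['rmse']:7.3f}  R^2 {res['r2']:6.3f}  "
        f"({res['n_rows']} visits; subset {res['final_subset']})"
    )
print(f"\nFull report: {Path(CONFIG.out_dir) / 'cross_sectional.json'}")
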