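"""Six-month-ahead prediction: fingerprints at T vs the scale itself at T.

For each clinical scale, visit pairs (T, T+6 months) are built per subject
and both predictor sets are evaluated with the identical nested LOSO
protocol. Reads results/features.csv, writes results/longitudinal.json and
prints which predictor wins per scale.
"""

import importlib
import logging

from kinedmd.pipeline import stage_predict_longitudinal

CONFIG = importlib.import_module("00_config").CONFIG

logging.basicConfig(level=logging.INFO)
report = stage_predict_longitudinal(CONFIG)
print("\nLongitudinal (T -> T+6 months) aggregate RMSE:")
for target, res in report["targets"].items():
    a = res["score_only"]["rmse"]
    b = res["fingerprints"]["rmse"]
    winner = "fingerprints" if res["fingerprints_beat_score_only"] else "score itself"
    print(f"  {target:8s} score-only {a:7.3f} vs fingerprints {b:7.3f} -> {winner}")
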