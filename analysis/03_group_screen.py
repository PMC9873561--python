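"""Kruskal-Wallis screening of every fingerprint between DMD and controls.

Reads results/features.csv, writes results/screen.csv / screen.json and
prints the strongest group discriminators.
"""

import importlib
import logging

from kinedmd.pipeline import stage_screen

CONFIG = importlib.import_module("00_config").CONFIG

logging.basicConfig(level=logging.INFO)
screen = stage_screen(CONFIG)
significant = screen[screen["p"] <= 0.05]
print(f"\n{len(significant)} / {len(screen)} features differ between groups at p <= 0.05.")
print("\nTop 10 discriminators:")
print(screen.nsmallest(10, "p")[["H", "p", "median_DMD", "median_HC"]].round(4).to_string())
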