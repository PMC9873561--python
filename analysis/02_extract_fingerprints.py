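"""Extract the 87 ethomic fingerprints for every visit recording.

Reads results/cohort/, writes results/features.csv (manifest columns plus
one named column per feature) and prints a per-family sanity summary.
"""

import importlib
import logging

from kinedmd.fingerprints import FAMILY_SIZES
from kinedmd.pipeline import stage_fingerprint

CONFIG = importlib.import_module("00_config").CONFIG

logging.basicConfig(level=logging.INFO)
table = stage_fingerprint(CONFIG)
print(f"\nExtracted {sum(FAMILY_SIZES.values())} features x {len(table)} visits.")
print("Family sizes:", dict(FAMILY_SIZES))
print("\nGroup medians of two headline features:")
print(
    table.groupby("group")[["workspace_volume_full_cm3", "speed_RightHand_mean"]]
    .median()
    .round(3)
    .to_string()
)
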