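"""Shared configuration for the numbered analysis drivers.

The cohort here is a desk-scale stand-in for a two-group observational
study: DMD boys seen at months 0/6/12 and controls at months 0/12, with
60 s of full-body kinematics per visit. Run the drivers in order; each
stage writes its outputs under results/ and later stages read them back.
"""

from kinedmd.pipeline import PipelineConfig

CONFIG = PipelineConfig(
    out_dir="results",
    seed=2026,
    targets=("6mwd", "nsaa", "pul", "myogrip"),
    budget=60,
    max_subset=5,
    generator={
        "n_dmd": 14,
        "n_hc": 8,
        "recording_duration_s": 90.0,
    },
)
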