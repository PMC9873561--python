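import numpy as np
import pytest

from kinedmd.recording import Recording
from kinedmd.skeleton import DEFAULT_SKELETON
from kinedmd.synthetic import DEFAULT_GENERATOR, SubjectProfile, generate_recording


def blank_recording(n_frames: int, sample_rate: float = 60.0) -> Recording:
    """All-zero recording scaffold for constructing exact test signals."""
    return Recording(
        subject_id="T",
        visit_id="T_v0",
        joint_angles=np.zeros((n_frames, 66)),
        segment_positions=np.zeros((n_frames, 69)),
        sample_rate=sample_rate,
    )


class FixedSeverityProfile(SubjectProfile):
    """Profile whose latent severity is a constant, independent of age."""

    def __init__(self, severity: float, rng_seed: int = 0):
        object.__setattr__(self, "subject_id", "FIX")
        object.__setattr__(self, "group", "DMD")
        object.__setattr__(self, "baseline_age", 8.0)
        object.__setattr__(self, "visit_months", (0.0,))
        object.__setattr__(self, "severity_params", (0.15, 1.8))
        object.__setattr__(self, "rng_seed", rng_seed)
        object.__setattr__(self, "_severity", severity)

    def severity(self, age: float) -> float:
        return self._severity


def severity_recording(severity: float, duration_s: float = 60.0, seed: int = 7):
    """Generated recording at a fixed severity with a reproducible stream."""
    rng = np.random.default_rng(seed)
    return generate_recording(
        FixedSeverityProfile(severity), 8.0, duration_s, DEFAULT_GENERATOR, rng=rng
    )


@pytest.fixture(scope="session")
def skeleton():
    return DEFAULT_SKELETON


@pytest.fixture(scope="session")
def healthy_recording():
    """One 60 s healthy-severity recording shared across feature tests."""
    return severity_recording(0.0, 60.0, seed=3)
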