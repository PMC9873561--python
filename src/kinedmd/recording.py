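"""Recording container plus preprocessing: gap repair, smoothing, derivatives.

A :class:`Recording` is one participant-visit of full-body kinematics sampled
at 60 Hz: 66 joint-angle channels (degrees) and 69 segment-position channels
(meters). Smoothing is a centered moving average of window 21 (the window
shrinks symmetrically at the edges so the output keeps the input length);
velocities and accelerations are central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .skeleton import DEFAULT_SKELETON, SkeletonModel

DEFAULT_SAMPLE_RATE = 60.0
#: longest gap (seconds) repaired by linear interpolation at load time
MAX_GAP_SECONDS = 0.5
DEFAULT_SMOOTH_WINDOW = 21


@dataclass
class Recording:
    """One participant-visit kinematic time series."""

    subject_id: str
    visit_id: str
    joint_angles: np.ndarray  # time x 66, degrees
    segment_positions: np.ndarray  # time x 69, meters
    sample_rate: float = DEFAULT_SAMPLE_RATE
    activity_labels: np.ndarray | None = None  # per-frame session tag
    skeleton: SkeletonModel = field(default_factory=lambda: DEFAULT_SKELETON)

    def __post_init__(self) -> None:
        self.joint_angles = np.asarray(self.joint_angles, dtype=float)
        self.segment_positions = np.asarray(self.segment_positions, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.joint_angles.ndim != 2 or self.joint_angles.shape[1] != 66:
            raise ValueError(
                f"joint_angles must be (time, 66), got {self.joint_angles.shape}"
            )
        if self.segment_positions.ndim != 2 or self.segment_positions.shape[1] != 69:
            raise ValueError(
                "segment_positions must be (time, 69), got "
                f"{self.segment_positions.shape}"
            )
        if len(self.joint_angles) != len(self.segment_positions):
            raise ValueError("angle and position streams disagree on frame count")
        if self.activity_labels is not None and len(self.activity_labels) != len(
            self.joint_angles
        ):
            raise ValueError("activity_labels length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.joint_angles)

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in seconds, t = frame / sample_rate."""
        return np.arange(self.n_frames) / self.sample_rate

    def positions_of(self, segment: str) -> np.ndarray:
        """(time, 3) position track of one segment."""
        return self.segment_positions[:, self.skeleton.segment_slice(segment)]

    def angle_channel(self, joint: str, axis: str) -> np.ndarray:
        return self.joint_angles[:, self.skeleton.joint_channel(joint, axis)]


@dataclass
class DerivedStreams:
    """Velocity/acceleration streams derived from one recording."""

    joint_angular_velocity: np.ndarray  # time x 66, deg/s
    segment_linear_velocity: np.ndarray  # time x 69, m/s
    segment_linear_acceleration: np.ndarray  # time x 69, m/s^2
    sample_rate: float
    skeleton: SkeletonModel

    @property
    def n_frames(self) -> int:
        return len(self.joint_angular_velocity)

    def velocity_of(self, segment: str) -> np.ndarray:
        return self.segment_linear_velocity[:, self.skeleton.segment_slice(segment)]

    def acceleration_of(self, segment: str) -> np.ndarray:
        return self.segment_linear_acceleration[
            :, self.skeleton.segment_slice(segment)
        ]

    def angular_velocity_channel(self, joint: str, axis: str) -> np.ndarray:
        return self.joint_angular_velocity[
            :, self.skeleton.joint_channel(joint, axis)
        ]


class GapError(ValueError):
    """A data gap is too long to repair by interpolation."""


def repair_gaps(
    values: np.ndarray, sample_rate: float, max_gap_s: float = MAX_GAP_SECONDS
) -> np.ndarray:
    """Linearly interpolate NaN runs no longer than ``max_gap_s`` seconds.

    Longer runs, and NaNs touching either end of the stream, raise
    :class:`GapError`: inventing long stretches (or extrapolating) would
    distort the downstream feature statistics.
    """
    values = np.array(values, dtype=float)
    if not np.isnan(values).any():
        return values
    max_frames = int(round(max_gap_s * sample_rate))
    for col in range(values.shape[1]):
        channel = values[:, col]
        isnan = np.isnan(channel)
        if not isnan.any():
            continue
        if isnan[0] or isnan[-1]:
            raise GapError(f"column {col}: gap at stream boundary cannot be repaired")
        # run-length encode the NaN mask
        edges = np.flatnonzero(np.diff(isnan.astype(int)))
        starts = edges[::2] + 1
        ends = edges[1::2] + 1  # exclusive
        for s, e in zip(starts, ends):
            if e - s > max_frames:
                raise GapError(
                    f"column {col}: gap of {e - s} frames exceeds "
                    f"{max_frames} ({max_gap_s} s at {sample_rate} Hz)"
                )
        good = ~isnan
        channel[isnan] = np.interp(
            np.flatnonzero(isnan), np.flatnonzero(good), channel[good]
        )
        values[:, col] = channel
    return values


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0 with shrinking symmetric edges.

    At distance ``k < window // 2`` from either edge the window shrinks to
    ``2k + 1`` frames, so the output has the input's length and no phase
    shift.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if window > n:
        raise ValueError(f"window {window} exceeds frame count {n}")
    half = window // 2
    csum = np.cumsum(values, axis=0)
    out = np.empty_like(values)
    # interior: full window via cumulative sums
    if n >= window:
        out[half : n - half] = (
            csum[window - 1 :]
            - np.concatenate([np.zeros((1,) + values.shape[1:]), csum[:-window]])
        ) / window
    for k in range(half):
        out[k] = values[: 2 * k + 1].mean(axis=0)
        out[n - 1 - k] = values[n - 1 - 2 * k :].mean(axis=0)
    return out


def smooth_recording(
    recording: Recording, window: int = DEFAULT_SMOOTH_WINDOW
) -> Recording:
    """Apply the centered moving average to every channel of a recording."""
    return replace(
        recording,
        joint_angles=moving_average(recording.joint_angles, window),
        segment_positions=moving_average(recording.segment_positions, window),
    )


def _gradient(values: np.ndarray, sample_rate: float) -> np.ndarray:
    # central differences inside, one-sided at the two boundary frames
    return np.gradient(values, axis=0) * sample_rate


def differentiate(recording: Recording) -> DerivedStreams:
    """Finite-difference velocities and accelerations of a recording."""
    if recording.n_frames < 3:
        raise ValueError("differentiation needs at least 3 frames")
    vel_ang = _gradient(recording.joint_angles, recording.sample_rate)
    vel_lin = _gradient(recording.segment_positions, recording.sample_rate)
    acc_lin = _gradient(vel_lin, recording.sample_rate)
    return DerivedStreams(
        joint_angular_velocity=vel_ang,
        segment_linear_velocity=vel_lin,
        segment_linear_acceleration=acc_lin,
        sample_rate=recording.sample_rate,
        skeleton=recording.skeleton,
    )
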