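"""Ethomic fingerprints: nine families of behavioral features per recording.

Each family condenses a full-body kinematic recording into named scalars:

======================  ====  ==========================================
family                  dim   quantity
======================  ====  ==========================================
workspace_volume        3     2 cm voxels visited by pelvis-relative
                              segment positions (full/upper/lower body), cm^3
hip_orbit_area          3     2 cm plane cells visited by the pelvis-relative
                              hip trajectory (sagittal/coronal/transverse), cm^2
extremity_velocity      8     mean and variance of hand/foot speed, m/s
avg_joint_velocity      9     mean absolute joint angular velocity, deg/s
autocorr_fwhm           17    full width at half maximum of the angular-
                              velocity autocorrelation, s
logistic_scale          8     ML scale sigma of a logistic fit to angular
                              velocity, deg/s
joint_correlations      15    Pearson r between angular-velocity channel
                              pairs
duty_cycle              15    fraction of time a joint is in motion
segment_acceleration    9     mean/variance of segment acceleration
                              magnitude, m/s^2
======================  ====  ==========================================

The default configuration yields 87 features (3+3+8+9+17+8+15+15+9). The
exact channel subsets behind the 9/17/8/15/15/9 dimensions are configurable;
the defaults cover the major limb and trunk joints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .recording import (
    DEFAULT_SMOOTH_WINDOW,
    DerivedStreams,
    Recording,
    differentiate,
    smooth_recording,
)
from .skeleton import EXTREMITY_SEGMENTS, LOWER_BODY_SEGMENTS, UPPER_BODY_SEGMENTS

FAMILY_SIZES = {
    "workspace_volume": 3,
    "hip_orbit_area": 3,
    "extremity_velocity": 8,
    "avg_joint_velocity": 9,
    "autocorr_fwhm": 17,
    "logistic_scale": 8,
    "joint_correlations": 15,
    "duty_cycle": 15,
    "segment_acceleration": 9,
}

Channel = tuple[str, str]  # (joint, Euler axis)

_AVG_VELOCITY_CHANNELS: tuple[Channel, ...] = (
    ("jRightHip", "Z"), ("jLeftHip", "Z"),
    ("jRightKnee", "Z"), ("jLeftKnee", "Z"),
    ("jRightShoulder", "Z"), ("jLeftShoulder", "Z"),
    ("jRightElbow", "Z"), ("jLeftElbow", "Z"),
    ("jL5S1", "Z"),
)

_FWHM_CHANNELS: tuple[Channel, ...] = (
    ("jRightHip", "Z"), ("jLeftHip", "Z"),
    ("jRightKnee", "Z"), ("jLeftKnee", "Z"),
    ("jRightAnkle", "Z"), ("jLeftAnkle", "Z"),
    ("jRightShoulder", "Z"), ("jLeftShoulder", "Z"),
    ("jRightElbow", "Z"), ("jLeftElbow", "Z"),
    ("jRightWrist", "Z"), ("jLeftWrist", "Z"),
    ("jRightHip", "X"), ("jLeftHip", "X"),
    ("jRightShoulder", "X"), ("jLeftShoulder", "X"),
    ("jL5S1", "Z"),
)

_LOGISTIC_CHANNELS: tuple[Channel, ...] = (
    ("jRightHip", "Z"), ("jLeftHip", "Z"),
    ("jRightKnee", "Z"), ("jLeftKnee", "Z"),
    ("jRightShoulder", "Z"), ("jLeftShoulder", "Z"),
    ("jRightElbow", "Z"), ("jLeftElbow", "Z"),
)

_CORRELATION_PAIRS: tuple[tuple[Channel, Channel], ...] = (
    (("jRightHip", "Z"), ("jRightKnee", "Z")),
    (("jLeftHip", "Z"), ("jLeftKnee", "Z")),
    (("jRightHip", "Z"), ("jLeftHip", "Z")),
    (("jRightKnee", "Z"), ("jLeftKnee", "Z")),
    (("jRightShoulder", "Z"), ("jRightElbow", "Z")),
    (("jLeftShoulder", "Z"), ("jLeftElbow", "Z")),
    (("jRightShoulder", "Z"), ("jLeftShoulder", "Z")),
    (("jRightHip", "X"), ("jLeftHip", "X")),
    (("jRightShoulder", "X"), ("jLeftShoulder", "X")),
    (("jRightHip", "X"), ("jRightShoulder", "X")),
    (("jRightHip", "Z"), ("jRightShoulder", "Z")),
    (("jLeftHip", "Z"), ("jLeftShoulder", "Z")),
    (("jRightKnee", "Z"), ("jRightAnkle", "Z")),
    (("jLeftKnee", "Z"), ("jLeftAnkle", "Z")),
    (("jL5S1", "Z"), ("jRightHip", "Z")),
)

_DUTYCYCLE_JOINTS: tuple[str, ...] = (
    "jL5S1", "jT9T8", "jC1Head",
    "jRightShoulder", "jRightElbow", "jRightWrist",
    "jLeftShoulder", "jLeftElbow", "jLeftWrist",
    "jRightHip", "jRightKnee", "jRightAnkle",
    "jLeftHip", "jLeftKnee", "jLeftAnkle",
)

_ACCEL_ENTRIES: tuple[tuple[str, str], ...] = (
    ("RightHand", "mean"), ("RightHand", "var"),
    ("LeftHand", "mean"), ("LeftHand", "var"),
    ("RightFoot", "mean"), ("RightFoot", "var"),
    ("LeftFoot", "mean"), ("LeftFoot", "var"),
    ("Pelvis", "mean"),
)


@dataclass(frozen=True)
class FamilyConfig:
    """Channel subsets and algorithm parameters for the nine families."""

    voxel_edge_m: float = 0.02
    plane_cell_edge_m: float = 0.02
    autocorr_max_lag_s: float = 10.0
    histogram_bins: int = 100
    motion_p_set: float = 0.005
    smooth_window: int = DEFAULT_SMOOTH_WINDOW
    reference_segment: str = "Pelvis"
    hip_segment: str = "RightUpperLeg"
    extremities: tuple[str, ...] = EXTREMITY_SEGMENTS
    avg_velocity_channels: tuple[Channel, ...] = _AVG_VELOCITY_CHANNELS
    fwhm_channels: tuple[Channel, ...] = _FWHM_CHANNELS
    logistic_channels: tuple[Channel, ...] = _LOGISTIC_CHANNELS
    correlation_pairs: tuple[tuple[Channel, Channel], ...] = _CORRELATION_PAIRS
    dutycycle_joints: tuple[str, ...] = _DUTYCYCLE_JOINTS
    accel_entries: tuple[tuple[str, str], ...] = _ACCEL_ENTRIES

    def __post_init__(self) -> None:
        for value in (
            self.voxel_edge_m, self.plane_cell_edge_m, self.autocorr_max_lag_s,
            self.histogram_bins, self.motion_p_set, self.smooth_window,
        ):
            if value <= 0:
                raise ValueError("all algorithm parameters must be positive")

    @property
    def fwhm_cap_s(self) -> float:
        # never-crossing channels report twice the maximum lag
        return 2.0 * self.autocorr_max_lag_s


DEFAULT_CONFIG = FamilyConfig()


def _relative_positions(recording: Recording, config: FamilyConfig) -> np.ndarray:
    """(time, 23, 3) positions re-expressed relative to the reference segment."""
    pos = recording.segment_positions.reshape(recording.n_frames, 23, 3)
    ref = recording.positions_of(config.reference_segment)
    return pos - ref[:, None, :]


def _voxel_count(points: np.ndarray, edge: float) -> int:
    """Number of distinct half-open grid cells visited by (n, d) points."""
    cells = np.floor(points / edge).astype(np.int64)
    return len(np.unique(cells, axis=0))


def compute_workspace_volume(
    recording: Recording, config: FamilyConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Full-, upper- and lower-body workspace volumes in cm^3.

    Positions are taken relative to the pelvis, binned into half-open
    ``voxel_edge_m`` cells anchored at the pelvis-frame origin; the volume is
    the non-empty voxel count times the single-voxel volume, regardless of
    occupancy frequency.
    """
    if recording.n_frames == 0:
        raise ValueError("empty recording")
    rel = _relative_positions(recording, config)
    names = recording.skeleton.segment_names
    ref = config.reference_segment
    voxel_cm3 = (config.voxel_edge_m * 100.0) ** 3

    def volume(segments: tuple[str, ...]) -> float:
        idx = [names.index(s) for s in segments]
        pts = rel[:, idx, :].reshape(-1, 3)
        return _voxel_count(pts, config.voxel_edge_m) * voxel_cm3

    full = tuple(s for s in names if s != ref)
    return np.array(
        [volume(full), volume(UPPER_BODY_SEGMENTS), volume(LOWER_BODY_SEGMENTS)]
    )


def compute_hip_orbit_area(
    recording: Recording, config: FamilyConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Hip-orbit areas (cm^2) on the sagittal (xz), coronal (yz) and
    transverse (xy) planes, with the pelvis fixed at the origin."""
    if recording.n_frames == 0:
        raise ValueError("empty recording")
    hip = recording.positions_of(config.hip_segment)
    pelvis = recording.positions_of(config.reference_segment)
    rel = hip - pelvis
    cell_cm2 = (config.plane_cell_edge_m * 100.0) ** 2
    planes = ((0, 2), (1, 2), (0, 1))  # x=forward, y=left, z=up
    return np.array(
        [
            _voxel_count(rel[:, list(axes)], config.plane_cell_edge_m) * cell_cm2
            for axes in planes
        ]
    )


def compute_extremity_velocity_stats(
    derived: DerivedStreams, config: FamilyConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Mean and variance of per-frame speed for each hand and foot (8 values).

    Speed is the Euclidean magnitude of the 3-D linear velocity per frame.
    """
    out = []
    for segment in config.extremities:
        speed = np.linalg.norm(derived.velocity_of(segment), axis=1)
        out.extend([speed.mean(), speed.var()])
    return np.array(out)


def compute_avg_joint_velocity(
    derived: DerivedStreams, config: FamilyConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Mean absolute angular velocity (deg/s) of the configured channels."""
    return np.array(
        [
            np.abs(derived.angular_velocity_channel(j, a)).mean()
            for j, a in config.avg_velocity_channels
        ]
    )


def autocorrelation(channel: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation of a demeaned 1-D series, r(0) = 1.

    Returns lags 0..max_lag; a zero-variance channel returns all NaN.
    """
    x = np.asarray(channel, dtype=float)
    x = x - x.mean()
    n = len(x)
    denom = np.dot(x, x)
    if denom == 0.0:
        return np.full(max_lag + 1, np.nan)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spectrum = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(spectrum * np.conj(spectrum), nfft)[: max_lag + 1]
    return acov / denom


def fwhm_of_autocorr(r: np.ndarray, sample_rate: float, cap_s: float) -> float:
    """FWHM (s) = twice the first lag where r crosses 0.5, interpolated.

    Channels whose autocorrelation never reaches 0.5 within the evaluated
    lags (including degenerate constant channels) return ``cap_s``.
    """
    if np.isnan(r).any():
        return cap_s
    below = np.flatnonzero(r < 0.5)
    if below.size == 0:
        return cap_s
    k = below[0]  # r[k-1] >= 0.5 > r[k]; k >= 1 because r[0] = 1
    frac = (r[k - 1] - 0.5) / (r[k - 1] - r[k])
    return 2.0 * (k - 1 + frac) / sample_rate


def compute_autocorr_fwhm(
    derived: DerivedStreams, config: FamilyConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Autocorrelation FWHM (s) of the configured angular-velocity channels."""
    max_lag = int(round(config.autocorr_max_lag_s * derived.sample_rate))
    if derived.n_frames < 2 * max_lag:
        raise ValueError(
            f"recording shorter than twice the {config.autocorr_max_lag_s} s "
            "maximum autocorrelation lag"
        )
    out = []
    for joint, axis in config.fwhm_channels:
        r = autocorrelation(derived.angular_velocity_channel(joint, axis), max_lag)
        out.append(fwhm_of_autocorr(r, derived.sample_rate, config.fwhm_cap_s))
    return np.array(out)


def fit_logistic_scale(samples: np.ndarray) -> float:
    """Maximum-likelihood logistic scale sigma of a sample.

    Initialized at the moment estimate sqrt(3)*sd/pi. A zero-variance sample
    returns 0 so that batch extraction stays total.
    """
    samples = np.asarray(samples, dtype=float)
    sd = samples.std()
    if sd == 0.0:
        return 0.0
    init_scale = np.sqrt(3.0) * sd / np.pi
    loc, scale = stats.logistic.fit(samples, loc=samples.mean(), scale=init_scale)
    return float(scale)


def compute_logistic_scale(
    derived: DerivedStreams, config: FamilyConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Logistic scale sigma (deg/s) per configured angular-velocity channel."""
    return np.array(
        [
            fit_logistic_scale(derived.angular_velocity_channel(j, a))
            for j, a in config.logistic_channels
        ]
    )


def compute_joint_correlations(
    derived: DerivedStreams, config: FamilyConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Pearson r between the configured angular-velocity channel pairs."""
    out = []
    for (j1, a1), (j2, a2) in config.correlation_pairs:
        x = derived.angular_velocity_channel(j1, a1)
        y = derived.angular_velocity_channel(j2, a2)
        if x.std() == 0.0 or y.std() == 0.0:
            out.append(0.0)  # degenerate channel: no linear association
        else:
            out.append(float(np.corrcoef(x, y)[0, 1]))
    return np.array(out)


def detect_motion(
    channel: np.ndarray, bins: int = 100, p_set: float = 0.005
) -> np.ndarray:
    """Per-frame motion mask from the empirical distribution of |channel|.

    A histogram with ``bins`` evenly spaced bins is computed over the range
    of the absolute signal. Scanning the bins upward from the modal (rest)
    bin, the threshold is the left edge of the first bin whose empirical
    probability drops below ``p_set`` — the gap separating the rest mode
    from genuine movement. Frames with |value| above the threshold are
    motion. If the scan finds no sparse bin (no detectable rest mode) every
    frame above the signal minimum counts as motion; an all-constant channel
    yields an all-false mask.
    """
    magnitude = np.abs(np.asarray(channel, dtype=float))
    if len(magnitude) < bins:
        raise ValueError(f"need at least {bins} samples, got {len(magnitude)}")
    lo, hi = magnitude.min(), magnitude.max()
    if hi == lo:
        return np.zeros(len(magnitude), dtype=bool)
    counts, edges = np.histogram(magnitude, bins=bins, range=(lo, hi))
    prob = counts / len(magnitude)
    modal = int(np.argmax(prob))
    threshold = lo
    for b in range(modal + 1, bins):
        if prob[b] < p_set:
            threshold = edges[b]
            break
    return magnitude > threshold


def compute_duty_cycle(
    derived: DerivedStreams, config: FamilyConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Fraction of time each configured joint is in motion (15 values).

    Motion is detected independently on the joint's three Euler-axis
    angular-velocity channels and the per-frame masks are OR-combined.
    """
    out = []
    for joint in config.dutycycle_joints:
        mask = np.zeros(derived.n_frames, dtype=bool)
        for axis in ("X", "Y", "Z"):
            mask |= detect_motion(
                derived.angular_velocity_channel(joint, axis),
                bins=config.histogram_bins,
                p_set=config.motion_p_set,
            )
        out.append(mask.mean())
    return np.array(out)


def compute_segment_accel_stats(
    derived: DerivedStreams, config: FamilyConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """Mean/variance of acceleration magnitude for configured segments."""
    out = []
    for segment, stat in config.accel_entries:
        mag = np.linalg.norm(derived.acceleration_of(segment), axis=1)
        out.append(mag.mean() if stat == "mean" else mag.var())
    return np.array(out)


def feature_names(config: FamilyConfig = DEFAULT_CONFIG) -> list[str]:
    """The 87 feature names, ordered by family as in the overview table."""
    names = [
        "workspace_volume_full_cm3",
        "workspace_volume_upper_cm3",
        "workspace_volume_lower_cm3",
        "hip_orbit_area_sagittal_cm2",
        "hip_orbit_area_coronal_cm2",
        "hip_orbit_area_transverse_cm2",
    ]
    for segment in config.extremities:
        names += [f"speed_{segment}_mean", f"speed_{segment}_var"]
    names += [f"avgvel_{j}_{a}" for j, a in config.avg_velocity_channels]
    names += [f"fwhm_{j}_{a}_s" for j, a in config.fwhm_channels]
    names += [f"logscale_{j}_{a}" for j, a in config.logistic_channels]
    names += [
        f"corr_{j1}{a1}__{j2}{a2}" for (j1, a1), (j2, a2) in config.correlation_pairs
    ]
    names += [f"dutycycle_{j}" for j in config.dutycycle_joints]
    names += [f"accel_{s}_{stat}" for s, stat in config.accel_entries]
    return names


def extract_fingerprints(
    recording: Recording,
    config: FamilyConfig = DEFAULT_CONFIG,
    *,
    presmoothed: bool = False,
) -> pd.Series:
    """Compute all nine fingerprint families on one recording.

    The recording is smoothed with the centered moving average first unless
    ``presmoothed``. Returns a named Series of 87 scalars.
    """
    rec = recording if presmoothed else smooth_recording(recording, config.smooth_window)
    derived = differentiate(rec)
    values = np.concatenate(
        [
            compute_workspace_volume(rec, config),
            compute_hip_orbit_area(rec, config),
            compute_extremity_velocity_stats(derived, config),
            compute_avg_joint_velocity(derived, config),
            compute_autocorr_fwhm(derived, config),
            compute_logistic_scale(derived, config),
            compute_joint_correlations(derived, config),
            compute_duty_cycle(derived, config),
            compute_segment_accel_stats(derived, config),
        ]
    )
    return pd.Series(values, index=feature_names(config), name=recording.visit_id)


def kruskal_wallis_screen(
    features: pd.DataFrame, labels: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Kruskal–Wallis one-way ANOVA per feature column across groups.

    Returns a DataFrame indexed by feature with the tie-corrected H
    statistic, degrees of freedom, p value and per-group medians. No
    multiple-testing correction is applied.
    """
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    rows = []
    for name in features.columns:
        samples = [features.loc[labels == g, name].to_numpy(float) for g in groups]
        if all(np.all(s == samples[0][0]) for s in samples):
            h, p = 0.0, 1.0  # all observations identical
        else:
            h, p = stats.kruskal(*samples)
        row = {"feature": name, "H": h, "df": len(groups) - 1, "p": p}
        for g, s in zip(groups, samples):
            row[f"median_{g}"] = np.median(s)
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")
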