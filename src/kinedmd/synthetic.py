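"""Synthetic cohort generator: recordings plus clinical scores.

No patient data ship with this package, so every downstream stage is
exercised on simulated participants. A DMD subject carries a latent disease
severity s(age) in [0, 1] following the same tanh progression family as the
biomarker (default truth alpha* = 0.15, beta* = 1.8, chosen feasible for the
age-5/age-15 clinical boxes); controls have severity identically 0.

The movement model is deliberately simple — sum-of-sinusoid joint
oscillations gated by two-state activity bouts — but reproduces the
*directions* of the group differences the analysis relies on. Severity:

* attenuates oscillation amplitude and frequency (lower extremity speeds,
  smaller workspace, smaller hip orbit),
* shifts the hip and knee flexion baselines upward (more flexed posture),
* lowers the probability of being in a movement bout (lower duty cycle),
* shrinks the scale of the additive logistic velocity noise,
* weakens the hip–knee sagittal anticorrelation and strengthens the
  left–right coronal hip coupling (waddling-gait signature).

Clinical scores decrease with severity in expectation, with configurable
noise, integer grading and ceiling/floor clipping; 6MWD is 0 and ambulatory
False once severity crosses the ambulation threshold. Non-ambulant subjects
keep informative upper-body kinematics (lower-body channels are attenuated,
not zeroed).

Each subject owns one RNG seed, split into named substreams (kinematics,
scores) so changing one effect never reshuffles the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .biomarker import BiomarkerParams, evaluate_biomarker
from .io import MANIFEST_COLUMNS, write_csv, write_manifest
from .recording import Recording
from .skeleton import DEFAULT_SKELETON, LOWER_BODY_SEGMENTS

NSAA_MAX = 34  # 17 activities graded 0/1/2
PUL_MAX = 42  # 22 items across shoulder/elbow/distal domains


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort sizes, visit schedule and per-unit-severity effect sizes."""

    n_dmd: int = 15
    n_hc: int = 15
    age_range: tuple[float, float] = (4.0, 17.0)
    recording_duration_s: float = 120.0
    dmd_visit_months: tuple[float, ...] = (0.0, 6.0, 12.0)
    hc_visit_months: tuple[float, ...] = (0.0, 12.0)
    severity_params: tuple[float, float] = (0.15, 1.8)  # generating truth
    # kinematic effect sizes, per unit severity
    velocity_attenuation: float = 0.6
    frequency_attenuation: float = 0.5
    hip_shift_deg: float = 12.0
    knee_shift_deg: float = 8.0
    dutycycle_drop: float = 0.45
    logistic_scale_drop: float = 0.5
    coronal_coupling_gain: float = 0.7
    sagittal_anticorr_loss: float = 0.8
    # score model
    # score noise at clinically reported test-retest magnitudes
    ambulatory_threshold: float = 0.55
    sixmwd_sd: float = 30.0
    nsaa_sd: float = 2.0
    pul_sd: float = 2.0
    myogrip_sd: float = 6.0

    def __post_init__(self) -> None:
        for name in (
            "velocity_attenuation", "frequency_attenuation", "hip_shift_deg",
            "knee_shift_deg", "dutycycle_drop", "logistic_scale_drop",
            "coronal_coupling_gain", "sagittal_anticorr_loss",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"effect size {name} must be >= 0")
        if self.n_dmd < 1 or self.n_hc < 1:
            raise ValueError("cohort sizes must be >= 1")


DEFAULT_GENERATOR = GeneratorConfig()


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    group: str  # "DMD" or "HC"
    baseline_age: float
    visit_months: tuple[float, ...]
    severity_params: tuple[float, float]
    rng_seed: int

    def severity(self, age: float) -> float:
        """Latent severity in [0, 1]; identically 0 for controls."""
        if self.group == "HC":
            return 0.0
        alpha, beta = self.severity_params
        return float(
            evaluate_biomarker(min(max(age, 0.0), 25.0), BiomarkerParams(alpha, beta))
        )


# rough child-scale segment offsets from the pelvis, meters (x fwd, y left, z up)
_SEGMENT_OFFSETS: dict[str, tuple[float, float, float]] = {
    "Pelvis": (0.0, 0.0, 0.0),
    "L5": (0.0, 0.0, 0.10), "L3": (0.0, 0.0, 0.16), "T12": (0.0, 0.0, 0.24),
    "T8": (0.0, 0.0, 0.32), "Neck": (0.0, 0.0, 0.44), "Head": (0.0, 0.0, 0.55),
    "RightShoulder": (0.0, -0.16, 0.40), "RightUpperArm": (0.0, -0.22, 0.30),
    "RightForearm": (0.04, -0.24, 0.12), "RightHand": (0.10, -0.26, -0.02),
    "LeftShoulder": (0.0, 0.16, 0.40), "LeftUpperArm": (0.0, 0.22, 0.30),
    "LeftForearm": (0.04, 0.24, 0.12), "LeftHand": (0.10, 0.26, -0.02),
    "RightUpperLeg": (0.0, -0.09, -0.18), "RightLowerLeg": (0.0, -0.10, -0.45),
    "RightFoot": (0.05, -0.10, -0.70), "RightToe": (0.12, -0.10, -0.72),
    "LeftUpperLeg": (0.0, 0.09, -0.18), "LeftLowerLeg": (0.0, 0.10, -0.45),
    "LeftFoot": (0.05, 0.10, -0.70), "LeftToe": (0.12, 0.10, -0.72),
}

# oscillation amplitude of segment positions around their offsets, meters
_SEGMENT_AMPLITUDES: dict[str, float] = {
    "RightHand": 0.25, "LeftHand": 0.25, "RightForearm": 0.16, "LeftForearm": 0.16,
    "RightUpperArm": 0.08, "LeftUpperArm": 0.08,
    "RightFoot": 0.14, "LeftFoot": 0.14, "RightToe": 0.14, "LeftToe": 0.14,
    "RightLowerLeg": 0.10, "LeftLowerLeg": 0.10,
    "RightUpperLeg": 0.06, "LeftUpperLeg": 0.06,
    "Head": 0.05, "Neck": 0.04,
}
_DEFAULT_SEGMENT_AMPLITUDE = 0.03


def _activity_envelope(
    n: int, rng: np.random.Generator, on_fraction: float, sample_rate: float
) -> np.ndarray:
    """Two-state (rest/move) bout envelope in [0, 1], smoothed at the edges."""
    on_fraction = float(np.clip(on_fraction, 0.05, 0.95))
    mean_on = 2.0 * sample_rate  # ~2 s movement bouts
    mean_off = mean_on * (1.0 - on_fraction) / on_fraction
    state = rng.random() < on_fraction
    mask = np.empty(n, dtype=float)
    i = 0
    while i < n:
        mean_len = mean_on if state else mean_off
        length = max(1, int(rng.exponential(mean_len)))
        mask[i : i + length] = 1.0 if state else 0.0
        i += length
        state = not state
    # ~0.25 s ramps avoid velocity impulses at bout edges
    ramp = int(0.25 * sample_rate)
    if ramp > 1:
        kernel = np.ones(ramp) / ramp
        mask = np.convolve(mask, kernel, mode="same")
    return mask


def _oscillation(
    n: int,
    rng: np.random.Generator,
    sample_rate: float,
    amplitude: float,
    freq_scale: float,
    n_components: int = 3,
) -> np.ndarray:
    """Sum of sinusoids with random frequencies/phases, unit-free amplitude."""
    t = np.arange(n) / sample_rate
    out = np.zeros(n)
    for _ in range(n_components):
        f = rng.uniform(0.3, 1.5) * freq_scale
        phase = rng.uniform(0, 2 * np.pi)
        out += rng.uniform(0.5, 1.0) * np.sin(2 * np.pi * f * t + phase)
    return amplitude * out / n_components


def generate_recording(
    profile: SubjectProfile,
    age: float,
    duration_s: float | None = None,
    config: GeneratorConfig = DEFAULT_GENERATOR,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Simulate one visit recording at 60 Hz for the given subject and age."""
    duration_s = duration_s or config.recording_duration_s
    if duration_s < 30:
        raise ValueError("recording duration must be at least 30 s")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([profile.rng_seed, int(round(age * 12))]).spawn(2)[0]
        )
    s = profile.severity(age)
    sk = DEFAULT_SKELETON
    sample_rate = 60.0
    n = int(round(duration_s * sample_rate))
    ambulant = s < config.ambulatory_threshold

    amp_scale = 1.0 - config.velocity_attenuation * s
    freq_scale = 1.0 - config.frequency_attenuation * s
    # joints are still most of the time during everyday activity; the rest
    # mode must dominate the velocity histogram for the duty-cycle detector
    envelope = _activity_envelope(
        n, rng, on_fraction=0.40 * (1.0 - config.dutycycle_drop * s), sample_rate=sample_rate
    )
    # keep the rest-state velocity floor well below movement speeds, or the
    # histogram-threshold motion detector loses the rest/movement gap
    noise_scale = 0.3 * (1.0 - config.logistic_scale_drop * s)

    # --- joint angles -----------------------------------------------------
    angles = np.empty((n, 66))
    base_amp = 18.0  # degrees
    raw = {}

    def osc(amplitude: float) -> np.ndarray:
        return _oscillation(n, rng, sample_rate, amplitude, freq_scale)

    # shared drivers for the coupled sagittal/coronal channels
    hip_sag = {side: osc(base_amp) for side in ("Right", "Left")}
    coronal_shared = osc(base_amp * 0.5)
    kappa_sag = 0.8 * (1.0 - config.sagittal_anticorr_loss * s)
    rho_cor = min(0.9, 0.2 + config.coronal_coupling_gain * s)

    for j, joint in enumerate(sk.joint_names):
        lower = any(seg in LOWER_BODY_SEGMENTS for seg in sk.parent_map[joint][1:])
        limb_scale = 0.25 if (lower and not ambulant) else 1.0
        for a, axis in enumerate(sk.joint_axes):
            key = (joint, axis)
            mean = 0.0
            if axis == "Z" and joint in ("jRightHip", "jLeftHip"):
                mean = 25.0 + config.hip_shift_deg * s
                signal = hip_sag["Right" if "Right" in joint else "Left"]
            elif axis == "Z" and joint in ("jRightKnee", "jLeftKnee"):
                mean = 30.0 + config.knee_shift_deg * s
                side = "Right" if "Right" in joint else "Left"
                signal = -kappa_sag * hip_sag[side] + osc(base_amp * 0.6)
            elif axis == "X" and joint in ("jRightHip", "jLeftHip"):
                signal = rho_cor * coronal_shared + (1.0 - rho_cor) * osc(base_amp * 0.5)
            else:
                signal = osc(base_amp * (0.9 if axis == "Z" else 0.4))
            # limb_scale attenuates noise too: an attenuated limb is quieter
            channel = (
                mean
                + amp_scale * limb_scale * envelope * signal
                + rng.logistic(0.0, noise_scale * limb_scale, n)
            )
            raw[key] = channel
            angles[:, 3 * j + a] = channel

    # --- segment positions ------------------------------------------------
    positions = np.empty((n, 69))
    pelvis_sway = np.column_stack(
        [osc(0.02), osc(0.02), osc(0.01)]
    )  # cancels in pelvis-relative features
    for i, segment in enumerate(sk.segment_names):
        offset = np.array(_SEGMENT_OFFSETS[segment])
        if segment == "Pelvis":
            track = pelvis_sway
        else:
            amp = _SEGMENT_AMPLITUDES.get(segment, _DEFAULT_SEGMENT_AMPLITUDE)
            limb_scale = (
                0.25 if (segment in LOWER_BODY_SEGMENTS and not ambulant) else 1.0
            )
            track = pelvis_sway + np.column_stack(
                [
                    amp_scale * limb_scale * envelope * osc(amp)
                    + rng.normal(0.0, 0.002, n)
                    for _ in range(3)
                ]
            )
        positions[:, 3 * i : 3 * i + 3] = offset + track

    return Recording(
        subject_id=profile.subject_id,
        visit_id=f"{profile.subject_id}_m{int(round(age * 12 - profile.baseline_age * 12)):02d}",
        joint_angles=angles,
        segment_positions=positions,
        sample_rate=sample_rate,
        skeleton=sk,
    )


def generate_clinical_scores(
    profile: SubjectProfile,
    age: float,
    config: GeneratorConfig = DEFAULT_GENERATOR,
    rng: np.random.Generator | None = None,
) -> dict:
    """Severity-driven clinical scores with noise, grading and clipping."""
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([profile.rng_seed, int(round(age * 12))]).spawn(2)[1]
        )
    s = profile.severity(age)
    ambulatory = s < config.ambulatory_threshold
    if ambulatory:
        sixmwd = max(0.0, 620.0 * (1.0 - 1.4 * s) + rng.normal(0.0, config.sixmwd_sd))
    else:
        sixmwd = 0.0
    nsaa = int(np.clip(round(NSAA_MAX * (1.0 - 1.2 * s) + rng.normal(0.0, config.nsaa_sd)), 0, NSAA_MAX))
    pul = int(np.clip(round(PUL_MAX * (1.0 - 0.9 * s) + rng.normal(0.0, config.pul_sd)), 0, PUL_MAX))
    myogrip = float(np.clip(100.0 * (1.0 - s) + rng.normal(0.0, config.myogrip_sd), 0.0, 130.0))
    return {
        "sixmwd_m": float(sixmwd),
        "nsaa": nsaa,
        "pul": pul,
        "myogrip_pct": myogrip,
        "ambulatory": bool(ambulatory),
        "severity": s,
    }


def make_profiles(
    config: GeneratorConfig, seed: int | None
) -> list[SubjectProfile]:
    rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, 917]))
    profiles = []
    lo, hi = config.age_range
    for i in range(config.n_dmd):
        profiles.append(
            SubjectProfile(
                subject_id=f"DMD{i + 1:02d}",
                group="DMD",
                baseline_age=float(rng.uniform(lo, hi - 1.0)),
                visit_months=config.dmd_visit_months,
                severity_params=config.severity_params,
                rng_seed=int(rng.integers(2**31 - 1)),
            )
        )
    for i in range(config.n_hc):
        profiles.append(
            SubjectProfile(
                subject_id=f"HC{i + 1:02d}",
                group="HC",
                baseline_age=float(rng.uniform(lo, hi - 1.0)),
                visit_months=config.hc_visit_months,
                severity_params=config.severity_params,
                rng_seed=int(rng.integers(2**31 - 1)),
            )
        )
    return profiles


def generate_cohort(
    config: GeneratorConfig = DEFAULT_GENERATOR,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[str, Recording]]:
    """Generate a full cohort: manifest rows plus one recording per visit.

    Deterministic given ``seed``. If ``out_dir`` is set, recordings are
    written as CSV files and the manifest as ``manifest.csv`` there;
    ``recording_path`` is populated accordingly (empty when in-memory).
    """
    profiles = make_profiles(config, seed)
    rows = []
    recordings: dict[str, Recording] = {}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for profile in profiles:
        for month in profile.visit_months:
            age = profile.baseline_age + month / 12.0
            streams = np.random.SeedSequence(
                [profile.rng_seed, int(round(month))]
            ).spawn(2)
            kin_rng = np.random.default_rng(streams[0])
            score_rng = np.random.default_rng(streams[1])
            recording = generate_recording(
                profile, age, config.recording_duration_s, config, rng=kin_rng
            )
            visit_id = f"{profile.subject_id}_m{int(month):02d}"
            recording.visit_id = visit_id
            scores = generate_clinical_scores(profile, age, config, rng=score_rng)
            path = ""
            if out_path is not None:
                path = str(out_path / f"{visit_id}.csv")
                write_csv(recording, path)
            recordings[visit_id] = recording
            rows.append(
                {
                    "subject_id": profile.subject_id,
                    "visit_id": visit_id,
                    "group": profile.group,
                    "age_years": round(age, 4),
                    "visit_month": month,
                    "ambulatory": scores["ambulatory"],
                    "nsaa": scores["nsaa"],
                    "sixmwd_m": round(scores["sixmwd_m"], 2),
                    "pul": scores["pul"],
                    "myogrip_pct": round(scores["myogrip_pct"], 2),
                    "recording_path": path,
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out_path is not None:
        write_manifest(manifest, out_path / "manifest.csv")
    return manifest, recordings


def generate_feature_cohort(
    n_subjects: int = 15,
    n_informative: int = 8,
    n_noise: int = 4,
    seed: int | None = None,
    visit_months: tuple[float, ...] = (0.0, 6.0, 12.0),
    age_range: tuple[float, float] = (5.0, 16.0),
    severity_params: tuple[float, float] = (0.15, 1.8),
    feature_noise_sd: float = 0.1,
    config: GeneratorConfig = DEFAULT_GENERATOR,
) -> tuple[pd.DataFrame, list[str]]:
    """Fingerprint-level synthetic cohort (no recordings).

    Informative features are affine in the latent severity with i.i.d.
    Gaussian noise (sd ``feature_noise_sd`` relative to a unit severity
    effect); noise features are severity-independent. Clinical scores come
    from the same score model as the full generator. This is the desk-scale
    stand-in used when a test targets the modeling protocol rather than the
    kinematic feature extraction.
    """
    rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, 421]))
    alpha, beta = severity_params
    slopes = rng.uniform(0.5, 1.5, n_informative) * rng.choice([-1, 1], n_informative)
    rows = []
    lo, hi = age_range
    for i in range(n_subjects):
        profile = SubjectProfile(
            subject_id=f"S{i + 1:02d}",
            group="DMD",
            baseline_age=float(rng.uniform(lo, hi - 1.0)),
            visit_months=visit_months,
            severity_params=(alpha, beta),
            rng_seed=int(rng.integers(2**31 - 1)),
        )
        for month in visit_months:
            age = profile.baseline_age + month / 12.0
            s = profile.severity(age)
            scores = generate_clinical_scores(
                profile, age, config,
                rng=np.random.default_rng(
                    np.random.SeedSequence([profile.rng_seed, int(month), 7])
                ),
            )
            feat_rng = np.random.default_rng(
                np.random.SeedSequence([profile.rng_seed, int(month), 11])
            )
            row = {
                "subject_id": profile.subject_id,
                "visit_id": f"{profile.subject_id}_m{int(month):02d}",
                "group": "DMD",
                "age_years": age,
                "visit_month": month,
                "severity": s,
                **{k: scores[k] for k in ("sixmwd_m", "nsaa", "pul", "myogrip_pct", "ambulatory")},
            }
            for j in range(n_informative):
                row[f"f{j:02d}"] = slopes[j] * s + feat_rng.normal(0.0, feature_noise_sd)
            for j in range(n_noise):
                row[f"noise{j:02d}"] = feat_rng.normal(0.0, 1.0)
            rows.append(row)
    frame = pd.DataFrame(rows)
    feature_cols = [f"f{j:02d}" for j in range(n_informative)] + [
        f"noise{j:02d}" for j in range(n_noise)
    ]
    return frame, feature_cols
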