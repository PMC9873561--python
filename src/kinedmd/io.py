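"""Readers/writers for kinematic recordings and the cohort manifest.

Two on-disk formats are supported:

* a CSV dialect — one header row; columns ``time_s``, the 66 joint-angle
  columns ``<joint>_<X|Y|Z>_deg``, then the 69 segment-position columns
  ``<segment>_<x|y|z>_m``; UTF-8, '.' decimal;
* an MVNX-subset XML dialect — only the segment/joint declarations and the
  per-frame ``jointAngle`` (66 floats, degrees) and ``position`` (69 floats,
  meters) payloads are read, all other sensor payloads are ignored.

Gaps (missing cells / NaNs) up to 0.5 s are linearly interpolated at load
time; longer gaps abort the load.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .recording import DEFAULT_SAMPLE_RATE, MAX_GAP_SECONDS, Recording, repair_gaps
from .skeleton import DEFAULT_SKELETON, SkeletonModel

MANIFEST_COLUMNS = [
    "subject_id", "visit_id", "group", "age_years", "visit_month",
    "ambulatory", "nsaa", "sixmwd_m", "pul", "myogrip_pct", "recording_path",
]


class SchemaError(ValueError):
    """File content violates the 22-joint / 23-segment data model."""


class ParseError(ValueError):
    """File is structurally malformed."""


def load_recording(
    path: str | os.PathLike,
    format: str = "csv",
    *,
    subject_id: str = "",
    visit_id: str = "",
    skeleton: SkeletonModel = DEFAULT_SKELETON,
    max_gap_s: float = MAX_GAP_SECONDS,
) -> Recording:
    """Load one recording from disk in the declared format."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _load_csv(path, subject_id, visit_id, skeleton, max_gap_s)
    if format == "mvnx_subset":
        return _load_mvnx(path, subject_id, visit_id, skeleton, max_gap_s)
    raise ValueError(f"unknown format {format!r}; use 'csv' or 'mvnx_subset'")


def _load_csv(
    path: Path,
    subject_id: str,
    visit_id: str,
    skeleton: SkeletonModel,
    max_gap_s: float,
) -> Recording:
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: {exc}") from exc
    angle_cols = skeleton.angle_columns
    pos_cols = skeleton.position_columns
    missing = [c for c in ["time_s", *angle_cols, *pos_cols] if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    times = frame["time_s"].to_numpy(float)
    if len(times) >= 2:
        dt = np.diff(times)
        if not np.allclose(dt, dt[0], atol=1e-6):
            raise ParseError(f"{path}: non-uniform time_s column")
        sample_rate = 1.0 / dt[0]
    else:
        sample_rate = DEFAULT_SAMPLE_RATE
    angles = repair_gaps(frame[angle_cols].to_numpy(float), sample_rate, max_gap_s)
    positions = repair_gaps(frame[pos_cols].to_numpy(float), sample_rate, max_gap_s)
    labels = None
    if "activity" in frame.columns:
        labels = frame["activity"].to_numpy(str)
    return Recording(
        subject_id=subject_id or path.stem,
        visit_id=visit_id,
        joint_angles=angles,
        segment_positions=positions,
        sample_rate=sample_rate,
        activity_labels=labels,
        skeleton=skeleton,
    )


def write_csv(recording: Recording, path: str | os.PathLike) -> None:
    """Write the CSV dialect; numeric cells use repr-exact float formatting."""
    sk = recording.skeleton
    frame = pd.DataFrame(
        np.column_stack(
            [recording.times, recording.joint_angles, recording.segment_positions]
        ),
        columns=["time_s", *sk.angle_columns, *sk.position_columns],
    )
    if recording.activity_labels is not None:
        frame["activity"] = recording.activity_labels
    # repr round-trips float64 exactly
    frame.to_csv(path, index=False, float_format="%.17g")


def _load_mvnx(
    path: Path,
    subject_id: str,
    visit_id: str,
    skeleton: SkeletonModel,
    max_gap_s: float,
) -> Recording:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    root = tree.getroot()

    def _local(tag: str) -> str:
        return etree.QName(tag).localname if "}" in tag else tag

    def _find_all(parent, name):
        return [el for el in parent.iter() if _local(el.tag) == name]

    subjects = _find_all(root, "subject") or [root]
    subject = subjects[0]
    seg_labels = [
        el.get("label") for el in _find_all(subject, "segment") if el.get("label")
    ]
    joint_labels = [
        el.get("label") for el in _find_all(subject, "joint") if el.get("label")
    ]
    if len(seg_labels) != 23:
        raise SchemaError(f"{path}: expected 23 segments, found {len(seg_labels)}")
    if len(joint_labels) != 22:
        raise SchemaError(f"{path}: expected 22 joints, found {len(joint_labels)}")

    frames_el = _find_all(subject, "frames")
    if not frames_el:
        raise ParseError(f"{path}: no <frames> element")
    sample_rate = float(frames_el[0].get("frameRate", DEFAULT_SAMPLE_RATE))
    angles_rows: list[np.ndarray] = []
    pos_rows: list[np.ndarray] = []
    for frame_el in _find_all(frames_el[0], "frame"):
        if frame_el.get("type", "normal") != "normal":
            continue  # skip calibration poses
        angle_el = next(iter(_find_all(frame_el, "jointAngle")), None)
        pos_el = next(iter(_find_all(frame_el, "position")), None)
        if angle_el is None or pos_el is None:
            raise ParseError(
                f"{path}: frame {frame_el.get('index')} lacks jointAngle/position"
            )
        angles = np.fromstring(angle_el.text or "", sep=" ")
        pos = np.fromstring(pos_el.text or "", sep=" ")
        if angles.size != 66:
            raise SchemaError(
                f"{path}: frame {frame_el.get('index')} jointAngle has "
                f"{angles.size} values, expected 66"
            )
        if pos.size != 69:
            raise SchemaError(
                f"{path}: frame {frame_el.get('index')} position has "
                f"{pos.size} values, expected 69"
            )
        angles_rows.append(angles)
        pos_rows.append(pos)
    if not angles_rows:
        raise ParseError(f"{path}: no data frames")
    sk = SkeletonModel(
        segment_names=tuple(seg_labels),
        joint_names=tuple(joint_labels),
        parent_map=dict(skeleton.parent_map)
        if tuple(seg_labels) == skeleton.segment_names
        else {},
    )
    return Recording(
        subject_id=subject_id or subject.get("label", path.stem),
        visit_id=visit_id,
        joint_angles=repair_gaps(np.array(angles_rows), sample_rate, max_gap_s),
        segment_positions=repair_gaps(np.array(pos_rows), sample_rate, max_gap_s),
        sample_rate=sample_rate,
        skeleton=sk,
    )


def write_mvnx(recording: Recording, path: str | os.PathLike) -> None:
    """Write the MVNX-subset dialect (used for fixtures and interchange)."""
    sk = recording.skeleton
    root = etree.Element("mvnx", version="4")
    subject = etree.SubElement(root, "subject", label=recording.subject_id or "S")
    segments = etree.SubElement(subject, "segments")
    for i, name in enumerate(sk.segment_names):
        etree.SubElement(segments, "segment", id=str(i + 1), label=name)
    joints = etree.SubElement(subject, "joints")
    for name in sk.joint_names:
        etree.SubElement(joints, "joint", label=name)
    frames = etree.SubElement(
        subject,
        "frames",
        frameRate=f"{recording.sample_rate:g}",
        segmentCount="23",
        jointCount="22",
    )
    for i in range(recording.n_frames):
        fr = etree.SubElement(
            frames,
            "frame",
            time=f"{1000.0 * i / recording.sample_rate:.3f}",
            index=str(i),
            type="normal",
        )
        etree.SubElement(fr, "jointAngle").text = " ".join(
            f"{v:.17g}" for v in recording.joint_angles[i]
        )
        etree.SubElement(fr, "position").text = " ".join(
            f"{v:.17g}" for v in recording.segment_positions[i]
        )
    etree.ElementTree(root).write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a cohort manifest CSV and validate its column set."""
    manifest = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise SchemaError(f"{path}: manifest missing columns {missing}")
    return manifest


def write_manifest(manifest: pd.DataFrame, path: str | os.PathLike) -> None:
    manifest.to_csv(path, index=False, columns=MANIFEST_COLUMNS, float_format="%.17g")
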