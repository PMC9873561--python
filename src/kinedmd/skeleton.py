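"""Biomechanical skeleton model: 23 body segments linked by 22 joints.

The segment and joint naming follows the convention of commercial inertial
motion-capture suits (pelvis-rooted tree, separate left/right limb chains).
Joint angles are ZXY Euler decompositions reported per joint on three axes:
X = abduction/adduction, Y = internal/external rotation,
Z = flexion/extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SEGMENT_NAMES: tuple[str, ...] = (
    "Pelvis", "L5", "L3", "T12", "T8", "Neck", "Head",
    "RightShoulder", "RightUpperArm", "RightForearm", "RightHand",
    "LeftShoulder", "LeftUpperArm", "LeftForearm", "LeftHand",
    "RightUpperLeg", "RightLowerLeg", "RightFoot", "RightToe",
    "LeftUpperLeg", "LeftLowerLeg", "LeftFoot", "LeftToe",
)

JOINT_NAMES: tuple[str, ...] = (
    "jL5S1", "jL4L3", "jL1T12", "jT9T8", "jT1C7", "jC1Head",
    "jRightT4Shoulder", "jRightShoulder", "jRightElbow", "jRightWrist",
    "jLeftT4Shoulder", "jLeftShoulder", "jLeftElbow", "jLeftWrist",
    "jRightHip", "jRightKnee", "jRightAnkle", "jRightBallFoot",
    "jLeftHip", "jLeftKnee", "jLeftAnkle", "jLeftBallFoot",
)

EULER_AXES: tuple[str, str, str] = ("X", "Y", "Z")

#: joint -> (proximal segment, distal segment)
PARENT_MAP: dict[str, tuple[str, str]] = {
    "jL5S1": ("Pelvis", "L5"),
    "jL4L3": ("L5", "L3"),
    "jL1T12": ("L3", "T12"),
    "jT9T8": ("T12", "T8"),
    "jT1C7": ("T8", "Neck"),
    "jC1Head": ("Neck", "Head"),
    "jRightT4Shoulder": ("T8", "RightShoulder"),
    "jRightShoulder": ("RightShoulder", "RightUpperArm"),
    "jRightElbow": ("RightUpperArm", "RightForearm"),
    "jRightWrist": ("RightForearm", "RightHand"),
    "jLeftT4Shoulder": ("T8", "LeftShoulder"),
    "jLeftShoulder": ("LeftShoulder", "LeftUpperArm"),
    "jLeftElbow": ("LeftUpperArm", "LeftForearm"),
    "jLeftWrist": ("LeftForearm", "LeftHand"),
    "jRightHip": ("Pelvis", "RightUpperLeg"),
    "jRightKnee": ("RightUpperLeg", "RightLowerLeg"),
    "jRightAnkle": ("RightLowerLeg", "RightFoot"),
    "jRightBallFoot": ("RightFoot", "RightToe"),
    "jLeftHip": ("Pelvis", "LeftUpperLeg"),
    "jLeftKnee": ("LeftUpperLeg", "LeftLowerLeg"),
    "jLeftAnkle": ("LeftLowerLeg", "LeftFoot"),
    "jLeftBallFoot": ("LeftFoot", "LeftToe"),
}

UPPER_BODY_SEGMENTS: tuple[str, ...] = (
    "L5", "L3", "T12", "T8", "Neck", "Head",
    "RightShoulder", "RightUpperArm", "RightForearm", "RightHand",
    "LeftShoulder", "LeftUpperArm", "LeftForearm", "LeftHand",
)

LOWER_BODY_SEGMENTS: tuple[str, ...] = (
    "RightUpperLeg", "RightLowerLeg", "RightFoot", "RightToe",
    "LeftUpperLeg", "LeftLowerLeg", "LeftFoot", "LeftToe",
)

EXTREMITY_SEGMENTS: tuple[str, ...] = (
    "RightHand", "LeftHand", "RightFoot", "LeftFoot",
)


@dataclass(frozen=True)
class SkeletonModel:
    """Segment/joint naming contract for a recording.

    Invariants: exactly 23 unique segments and 22 unique joints; every
    joint's proximal and distal segments exist in ``segment_names``.
    """

    segment_names: tuple[str, ...] = SEGMENT_NAMES
    joint_names: tuple[str, ...] = JOINT_NAMES
    joint_axes: tuple[str, str, str] = EULER_AXES
    parent_map: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(PARENT_MAP)
    )

    def __post_init__(self) -> None:
        if len(self.segment_names) != 23:
            raise ValueError(
                f"skeleton needs 23 segments, got {len(self.segment_names)}"
            )
        if len(self.joint_names) != 22:
            raise ValueError(
                f"skeleton needs 22 joints, got {len(self.joint_names)}"
            )
        if len(set(self.segment_names)) != 23 or len(set(self.joint_names)) != 22:
            raise ValueError("segment/joint names must be unique")
        segs = set(self.segment_names)
        for joint, (prox, dist) in self.parent_map.items():
            if joint not in self.joint_names:
                raise ValueError(f"parent_map joint {joint!r} not in joint_names")
            if prox not in segs or dist not in segs:
                raise ValueError(f"joint {joint!r} references unknown segments")

    @property
    def angle_columns(self) -> list[str]:
        """66 joint-angle column names, ``<joint>_<axis>_deg``."""
        return [f"{j}_{a}_deg" for j in self.joint_names for a in self.joint_axes]

    @property
    def position_columns(self) -> list[str]:
        """69 segment-position column names, ``<segment>_<axis>_m``."""
        return [f"{s}_{a}_m" for s in self.segment_names for a in ("x", "y", "z")]

    def segment_slice(self, segment: str) -> slice:
        """Column slice of one segment's xyz triple in the position matrix."""
        i = self.segment_names.index(segment)
        return slice(3 * i, 3 * i + 3)

    def joint_channel(self, joint: str, axis: str) -> int:
        """Column index of one joint-axis channel in the angle matrix."""
        return 3 * self.joint_names.index(joint) + self.joint_axes.index(axis)


DEFAULT_SKELETON = SkeletonModel()
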