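"""Joint-angle channel taxonomy.

A trial carries 30 angle channels: four trunk joints (L5S1, L4L3, L1T12,
T9T8) and three leg joints (hip, knee, ankle) per body side, each in three
degrees of freedom (ISB convention: flexion/extension, abduction/adduction,
internal/external rotation).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Joint(str, enum.Enum):
    L5S1 = "L5S1"
    L4L3 = "L4L3"
    L1T12 = "L1T12"
    T9T8 = "T9T8"
    HIP = "hip"
    KNEE = "knee"
    ANKLE = "ankle"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"
    NONE = "none"  # trunk joints carry no side


class Dof(str, enum.Enum):
    FLEXION_EXTENSION = "flexion_extension"
    ABDUCTION_ADDUCTION = "abduction_adduction"
    INTERNAL_EXTERNAL_ROTATION = "internal_external_rotation"


TRUNK_JOINTS = (Joint.L5S1, Joint.L4L3, Joint.L1T12, Joint.T9T8)
LEG_JOINTS = (Joint.HIP, Joint.KNEE, Joint.ANKLE)

#: DOFs whose sign convention is handed: mirroring a side flips them.
HANDED_DOFS = (Dof.ABDUCTION_ADDUCTION, Dof.INTERNAL_EXTERNAL_ROTATION)


@dataclass(frozen=True, order=True)
class ChannelKey:
    """One angle channel: (joint, side, dof).

    Trunk joints must have ``side == Side.NONE``; leg joints must carry
    left or right.
    """

    joint: Joint
    side: Side
    dof: Dof

    def __post_init__(self) -> None:
        if self.joint in TRUNK_JOINTS and self.side is not Side.NONE:
            raise ValueError(f"trunk joint {self.joint.value} cannot have side {self.side.value}")
        if self.joint in LEG_JOINTS and self.side is Side.NONE:
            raise ValueError(f"leg joint {self.joint.value} requires a side")

    @property
    def is_trunk(self) -> bool:
        return self.joint in TRUNK_JOINTS

    @property
    def label(self) -> str:
        if self.is_trunk:
            return f"{self.joint.value}/{self.dof.value}"
        return f"{self.joint.value}/{self.side.value}/{self.dof.value}"

    def mirrored(self) -> "ChannelKey":
        """The channel this one maps to under a left/right body reflection."""
        if self.is_trunk:
            return self
        other = Side.LEFT if self.side is Side.RIGHT else Side.RIGHT
        return ChannelKey(self.joint, other, self.dof)


def angle_channels() -> list[ChannelKey]:
    """The 30 canonical angle channels, in a fixed documented order.

    12 trunk channels (4 joints x 3 DOF) followed by 18 leg channels
    (right then left, hip/knee/ankle x 3 DOF).
    """
    keys: list[ChannelKey] = []
    for joint in TRUNK_JOINTS:
        for dof in Dof:
            keys.append(ChannelKey(joint, Side.NONE, dof))
    for side in (Side.RIGHT, Side.LEFT):
        for joint in LEG_JOINTS:
            for dof in Dof:
                keys.append(ChannelKey(joint, side, dof))
    return keys


ANGLE_CHANNELS: tuple[ChannelKey, ...] = tuple(angle_channels())

# mvnx-style joint labels <-> (joint, side). The reader targets this
# documented subset of the mvnx jointAngle payload.
MVNX_JOINT_LABELS: dict[str, tuple[Joint, Side]] = {
    "jL5S1": (Joint.L5S1, Side.NONE),
    "jL4L3": (Joint.L4L3, Side.NONE),
    "jL1T12": (Joint.L1T12, Side.NONE),
    "jT9T8": (Joint.T9T8, Side.NONE),
    "jRightHip": (Joint.HIP, Side.RIGHT),
    "jRightKnee": (Joint.KNEE, Side.RIGHT),
    "jRightAnkle": (Joint.ANKLE, Side.RIGHT),
    "jLeftHip": (Joint.HIP, Side.LEFT),
    "jLeftKnee": (Joint.KNEE, Side.LEFT),
    "jLeftAnkle": (Joint.ANKLE, Side.LEFT),
}

JOINT_SIDE_TO_MVNX: dict[tuple[Joint, Side], str] = {v: k for k, v in MVNX_JOINT_LABELS.items()}

#: Component order of the three angles stored per joint in an mvnx frame.
#: Follows the ZXY Euler storage order of the jointAngle payload:
#: abduction/adduction, internal/external rotation, flexion/extension.
MVNX_DOF_ORDER: tuple[Dof, ...] = (
    Dof.ABDUCTION_ADDUCTION,
    Dof.INTERNAL_EXTERNAL_ROTATION,
    Dof.FLEXION_EXTENSION,
)

MVNX_POSITION_SEGMENTS: dict[str, str] = {
    "Pelvis": "pelvis",
    "RightFoot": "right_foot",
    "LeftFoot": "left_foot",
}
POSITION_POINTS = ("pelvis", "right_foot", "left_foot")
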