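"""Shared task vocabulary for the eight isometric torque directions.

The experiment tests maximal isometric torque in eight single-DOF directions
at the shoulder and elbow.  Each direction (class) owns one of four torque
degrees of freedom with a sign, and belongs to one of the two abnormal-synergy
groups described clinically after stroke: the flexion synergy couples elbow
flexion with shoulder abduction, external rotation and horizontal abduction;
the extension synergy couples their opposites.
"""

from __future__ import annotations

import enum

#: Names of the four joint-torque degrees of freedom, in series order.
#: Positive torque means the first-named direction (AB, HAB, ER, EF).
DOF_NAMES = ("ab_ad", "hab_had", "er_ir", "ef_ee")

#: Muscles under the eight bipolar surface-EMG electrodes, in channel order.
MUSCLE_NAMES = (
    "anterior_deltoid",
    "intermediate_deltoid",
    "posterior_deltoid",
    "pectoralis_major",
    "biceps_brachii",
    "triceps_long",
    "triceps_lateral",
    "brachioradialis",
)


class SynergyGroup(enum.Enum):
    FLEXION = "flexion"
    EXTENSION = "extension"


class TaskClass(enum.Enum):
    """One of the eight tested torque directions.

    Members carry the index of their primary torque DOF (into the 4-channel
    joint-torque series ordered AB/AD, HAB/HAD, ER/IR, EF/EE), the sign of the
    primary torque in that DOF, and their synergy group.
    """

    EF = ("EF", 3, +1, SynergyGroup.FLEXION)
    AB = ("AB", 0, +1, SynergyGroup.FLEXION)
    ER = ("ER", 2, +1, SynergyGroup.FLEXION)
    HAB = ("HAB", 1, +1, SynergyGroup.FLEXION)
    EE = ("EE", 3, -1, SynergyGroup.EXTENSION)
    AD = ("AD", 0, -1, SynergyGroup.EXTENSION)
    IR = ("IR", 2, -1, SynergyGroup.EXTENSION)
    HAD = ("HAD", 1, -1, SynergyGroup.EXTENSION)

    def __init__(self, code: str, primary_axis: int, primary_sign: int,
                 synergy_group: SynergyGroup):
        self.code = code
        self.primary_axis = primary_axis
        self.primary_sign = primary_sign
        self.synergy_group = synergy_group

    @classmethod
    def from_code(cls, code: str) -> "TaskClass":
        try:
            return cls[code.upper()]
        except KeyError:
            raise ValueError(f"unknown task class {code!r}") from None

    def opposite(self) -> "TaskClass":
        """The class sharing this one's primary axis with opposite sign."""
        for other in TaskClass:
            if other.primary_axis == self.primary_axis and other is not self:
                return other
        raise AssertionError("unreachable")


#: Reporting order: flexion-synergy classes first, then extension-synergy,
#: so confusion matrices show the two synergy blocks contiguously.
CLASS_ORDER = (
    TaskClass.EF, TaskClass.AB, TaskClass.ER, TaskClass.HAB,
    TaskClass.EE, TaskClass.AD, TaskClass.IR, TaskClass.HAD,
)

FLEXION_CLASSES = tuple(c for c in CLASS_ORDER if c.synergy_group is SynergyGroup.FLEXION)
EXTENSION_CLASSES = tuple(c for c in CLASS_ORDER if c.synergy_group is SynergyGroup.EXTENSION)
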