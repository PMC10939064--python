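"""Shared enumerations for bones, compartments, sides, sex and subregions.

The knee is scored over 12 subregions following the WORMS-style partition:
bone (F femur / T tibia) x compartment (M medial / L lateral) x third
(A anterior / C central / P posterior), e.g. FMA = anterior medial femur.
"""

from __future__ import annotations

from enum import Enum


class Bone(str, Enum):
    FEMUR = "F"
    TIBIA = "T"


class Compartment(str, Enum):
    MEDIAL = "M"
    LATERAL = "L"


class Third(str, Enum):
    ANTERIOR = "A"
    CENTRAL = "C"
    POSTERIOR = "P"


class Side(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"


class Sex(str, Enum):
    """Patient sex, encoded M / W to match LM/LW/RM/RW reference row naming."""

    M = "M"
    W = "W"


class RegionCode(str, Enum):
    """The 12 anatomical subregions: {F,T} x {M,L} x {A,C,P}."""

    FMA = "FMA"
    FMC = "FMC"
    FMP = "FMP"
    FLA = "FLA"
    FLC = "FLC"
    FLP = "FLP"
    TMA = "TMA"
    TMC = "TMC"
    TMP = "TMP"
    TLA = "TLA"
    TLC = "TLC"
    TLP = "TLP"

    @property
    def bone(self) -> Bone:
        return Bone(self.value[0])

    @property
    def compartment(self) -> Compartment:
        return Compartment(self.value[1])

    @property
    def third(self) -> Third:
        return Third(self.value[2])


def region_code(bone: Bone, compartment: Compartment, third: Third) -> RegionCode:
    """Compose a subregion code from its three anatomical axes."""
    return RegionCode(bone.value + compartment.value + third.value)
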