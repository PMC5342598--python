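"""Assay and receptor vocabulary for the NKp44/NKp30 splice-variant panel.

The qPCR panel measures total NKp44 (NCR2) and NKp30 (NCR3) transcripts,
their three splice variants each (NKp44-1/-2/-3; NKp30a/b/c), total NKp46
(NCR1), and beta-actin as the reference gene.  Amplification efficiencies
reported for the primer sets are all close to 100%, so plain 2^-dCt is used
without efficiency correction; the efficiencies are carried as metadata only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Receptor(str, enum.Enum):
    NKP44 = "NKP44"
    NKP30 = "NKP30"


class Assay(str, enum.Enum):
    NKP44_TOTAL = "NKP44_TOTAL"
    NKP44_1 = "NKP44_1"
    NKP44_2 = "NKP44_2"
    NKP44_3 = "NKP44_3"
    NKP30_TOTAL = "NKP30_TOTAL"
    NKP30_A = "NKP30_A"
    NKP30_B = "NKP30_B"
    NKP30_C = "NKP30_C"
    NKP46 = "NKP46"
    ACTB = "ACTB"


class AssayRole(str, enum.Enum):
    TARGET = "target"
    REFERENCE = "reference"
    TOTAL_REFERENCE = "total_reference"


@dataclass(frozen=True)
class AssayMeta:
    """Primer-set metadata; efficiency is informational, never applied."""

    assay: Assay
    efficiency_percent: float
    role: AssayRole

    def __post_init__(self) -> None:
        if not 50.0 < self.efficiency_percent < 150.0:
            raise ValueError(
                f"implausible amplification efficiency {self.efficiency_percent}%"
            )


#: Reported primer-set amplification efficiencies (percent).
ASSAY_METADATA: dict[Assay, AssayMeta] = {
    m.assay: m
    for m in (
        AssayMeta(Assay.NKP44_TOTAL, 98.6, AssayRole.TOTAL_REFERENCE),
        AssayMeta(Assay.NKP44_1, 99.8, AssayRole.TARGET),
        AssayMeta(Assay.NKP44_2, 102.5, AssayRole.TARGET),
        AssayMeta(Assay.NKP44_3, 99.2, AssayRole.TARGET),
        AssayMeta(Assay.NKP46, 104.432, AssayRole.TARGET),
        AssayMeta(Assay.NKP30_TOTAL, 100.205, AssayRole.TOTAL_REFERENCE),
        AssayMeta(Assay.NKP30_A, 98.568, AssayRole.TARGET),
        AssayMeta(Assay.NKP30_B, 98.387, AssayRole.TARGET),
        AssayMeta(Assay.NKP30_C, 101.560, AssayRole.TARGET),
        AssayMeta(Assay.ACTB, 103.251, AssayRole.REFERENCE),
    )
}

#: Variant labels per receptor, in canonical order.
RECEPTOR_VARIANTS: dict[Receptor, tuple[str, str, str]] = {
    Receptor.NKP44: ("NKp44-1", "NKp44-2", "NKp44-3"),
    Receptor.NKP30: ("NKp30a", "NKp30b", "NKp30c"),
}

#: Variant assay -> (receptor, variant label).
VARIANT_ASSAYS: dict[Assay, tuple[Receptor, str]] = {
    Assay.NKP44_1: (Receptor.NKP44, "NKp44-1"),
    Assay.NKP44_2: (Receptor.NKP44, "NKp44-2"),
    Assay.NKP44_3: (Receptor.NKP44, "NKp44-3"),
    Assay.NKP30_A: (Receptor.NKP30, "NKp30a"),
    Assay.NKP30_B: (Receptor.NKP30, "NKp30b"),
    Assay.NKP30_C: (Receptor.NKP30, "NKp30c"),
}

#: Receptor -> its total-transcript assay.
TOTAL_ASSAYS: dict[Receptor, Assay] = {
    Receptor.NKP44: Assay.NKP44_TOTAL,
    Receptor.NKP30: Assay.NKP30_TOTAL,
}
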