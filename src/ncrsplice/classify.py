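"""Threshold classification of splice-variant profiles and matched-pair shifts.

NKp44: a positive sample whose NKp44-1 share of total NKp44 transcripts is
at least 66% carries the NKp44-1-dominant (inhibitory, ITIM-bearing)
profile; below the threshold it is NKp44-2/3 (activating).  NKp30: the
profile is NKp30a/b (activating) when %NKp30a >= %NKp30c and NKp30c
(inhibitory/IL-10-associated) otherwise; NKp30b is measured but plays no
role in the rule.  Matched tumor-normal pairs are typed as identical or
non-identical, with the direction of any NKp30 shift recorded; a pair with
a receptor-negative side is non-defined.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .assays import Receptor
from .profiles import VariantPercentProfile


class ProfileLabel(str, enum.Enum):
    NEGATIVE = "NEGATIVE"
    NKP44_1_DOMINANT = "NKP44_1_DOMINANT"
    NKP44_2_3 = "NKP44_2_3"
    NKP30_AB = "NKP30_AB"
    NKP30_C = "NKP30_C"


class Identity(str, enum.Enum):
    IDENTICAL = "IDENTICAL"
    NON_IDENTICAL = "NON_IDENTICAL"
    NON_DEFINED = "NON_DEFINED"


class ShiftDirection(str, enum.Enum):
    AB_TO_C = "AB_TO_C"
    C_TO_AB = "C_TO_AB"
    NONE = "NONE"
    NON_DEFINED = "NON_DEFINED"


@dataclass(frozen=True)
class ClassifierConfig:
    """Threshold rules.

    nkp44_dominance_threshold
        Percent NKp44-1 at/above which the profile is NKp44-1-dominant.
    nkp44_boundary_inclusive
        Whether a sample exactly at the threshold is dominant (default
        True, i.e. ">= 66%").
    nkp30_tie_to_ab
        Whether %a == %c resolves to NKp30a/b (default True, i.e.
        "%a >= %c").
    """

    nkp44_dominance_threshold: float = 66.0
    nkp44_boundary_inclusive: bool = True
    nkp30_tie_to_ab: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.nkp44_dominance_threshold < 100.0:
            raise ValueError("dominance threshold must be in (0, 100)")


@dataclass(frozen=True)
class ProfileCall:
    sample_id: str
    receptor: Receptor
    label: ProfileLabel


@dataclass(frozen=True)
class PairedShiftCall:
    patient_id: str
    stn_call: ProfileCall
    pst_call: ProfileCall
    identity: Identity
    direction: ShiftDirection


def _check_percent(value: float, name: str) -> None:
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"{name} must be a percentage in [0, 100], got {value}")


def classify_nkp44(
    percent_nkp44_1: float | None,
    positive: bool,
    config: ClassifierConfig | None = None,
    sample_id: str = "",
) -> ProfileCall:
    config = config or ClassifierConfig()
    if not positive:
        return ProfileCall(sample_id, Receptor.NKP44, ProfileLabel.NEGATIVE)
    if percent_nkp44_1 is None:
        raise ValueError("positive sample requires a defined NKp44-1 percentage")
    _check_percent(percent_nkp44_1, "percent NKp44-1")
    thr = config.nkp44_dominance_threshold
    dominant = (
        percent_nkp44_1 >= thr if config.nkp44_boundary_inclusive else percent_nkp44_1 > thr
    )
    label = ProfileLabel.NKP44_1_DOMINANT if dominant else ProfileLabel.NKP44_2_3
    return ProfileCall(sample_id, Receptor.NKP44, label)


def classify_nkp30(
    percent_a: float | None,
    percent_c: float | None,
    positive: bool,
    config: ClassifierConfig | None = None,
    sample_id: str = "",
) -> ProfileCall:
    config = config or ClassifierConfig()
    if not positive:
        return ProfileCall(sample_id, Receptor.NKP30, ProfileLabel.NEGATIVE)
    if percent_a is None or percent_c is None:
        raise ValueError("positive sample requires defined NKp30a/c percentages")
    _check_percent(percent_a, "percent NKp30a")
    _check_percent(percent_c, "percent NKp30c")
    ab = percent_a >= percent_c if config.nkp30_tie_to_ab else percent_a > percent_c
    label = ProfileLabel.NKP30_AB if ab else ProfileLabel.NKP30_C
    return ProfileCall(sample_id, Receptor.NKP30, label)


def classify_profile(
    profile: VariantPercentProfile, config: ClassifierConfig | None = None
) -> ProfileCall:
    """Dispatch a percentage profile to the receptor's rule."""
    if profile.receptor is Receptor.NKP44:
        pct = profile.percents.get("NKp44-1") if profile.positive else None
        return classify_nkp44(pct, profile.positive, config, profile.sample_id)
    pa = profile.percents.get("NKp30a") if profile.positive else None
    pc = profile.percents.get("NKp30c") if profile.positive else None
    return classify_nkp30(pa, pc, profile.positive, config, profile.sample_id)


def classify_shift(stn_call: ProfileCall, pst_call: ProfileCall) -> PairedShiftCall:
    """Type the profile change between matched normal (STN) and tumor (PST).

    A pair with a NEGATIVE side is non-defined: it leaves the
    identical/non-identical denominator and is reported in its own bin.
    """
    if stn_call.receptor is not pst_call.receptor:
        raise ValueError(
            f"receptor mismatch: {stn_call.receptor.value} vs {pst_call.receptor.value}"
        )
    patient_id = stn_call.sample_id
    neg = ProfileLabel.NEGATIVE
    if stn_call.label is neg or pst_call.label is neg:
        return PairedShiftCall(
            patient_id, stn_call, pst_call, Identity.NON_DEFINED, ShiftDirection.NON_DEFINED
        )
    if stn_call.label is pst_call.label:
        return PairedShiftCall(
            patient_id, stn_call, pst_call, Identity.IDENTICAL, ShiftDirection.NONE
        )
    if (stn_call.label, pst_call.label) == (ProfileLabel.NKP30_AB, ProfileLabel.NKP30_C):
        direction = ShiftDirection.AB_TO_C
    elif (stn_call.label, pst_call.label) == (ProfileLabel.NKP30_C, ProfileLabel.NKP30_AB):
        direction = ShiftDirection.C_TO_AB
    else:
        # NKp44 pairs shift too, but no named direction exists for them
        direction = ShiftDirection.NONE
    return PairedShiftCall(
        patient_id, stn_call, pst_call, Identity.NON_IDENTICAL, direction
    )
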