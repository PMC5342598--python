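"""Per-sample splice-variant percentage profiles.

A profile is a composition: the three variant expressions of one receptor
in one sample, renormalised to percentages that sum to 100.  Both the qPCR
branch (2^-dCt expressions) and the RSEM branch (normalized counts) reduce
to this structure, so downstream classification is source-agnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .assays import RECEPTOR_VARIANTS, Receptor
from .errors import UndefinedProfileError

PERCENT_SUM_TOL = 1e-9


@dataclass(frozen=True)
class VariantPercentProfile:
    """Positivity flag plus variant percentages for one sample x receptor.

    Invariant: if ``positive`` the percentages sum to 100 within 1e-9;
    if negative the percentage map is empty.
    """

    sample_id: str
    receptor: Receptor
    positive: bool
    percents: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.positive:
            total = sum(self.percents.values())
            if not math.isclose(total, 100.0, abs_tol=PERCENT_SUM_TOL):
                raise ValueError(
                    f"percentages for {self.sample_id}/{self.receptor.value} "
                    f"sum to {total!r}, not 100"
                )
        elif self.percents:
            raise ValueError("negative profile must carry no percentages")

    def percent(self, variant: str) -> float:
        return self.percents[variant]

    @classmethod
    def unclosed(
        cls, sample_id: str, receptor: Receptor, percents: dict[str, float]
    ) -> "VariantPercentProfile":
        """Positive profile whose percentages need not sum to 100.

        Used only when percentages are taken against an external denominator
        (the total-transcript assay) rather than the variant sum.
        """
        obj = cls.__new__(cls)
        object.__setattr__(obj, "sample_id", sample_id)
        object.__setattr__(obj, "receptor", receptor)
        object.__setattr__(obj, "positive", True)
        object.__setattr__(obj, "percents", dict(percents))
        return obj


def variant_percentages(variant_exprs: dict[str, float]) -> dict[str, float]:
    """Renormalise variant expressions to percentages of their sum.

    The denominator is the sum of the variant expressions themselves (not a
    separate total-transcript measurement), so the result is always a
    well-formed composition.  Scale-invariant: multiplying every input by
    the same positive factor leaves the output unchanged.

    Raises
    ------
    UndefinedProfileError
        If any expression is undefined (None/NaN) or all are zero.
    """
    if not variant_exprs:
        raise UndefinedProfileError("no variant expressions supplied")
    vals = {}
    for variant, expr in variant_exprs.items():
        if expr is None or not math.isfinite(expr):
            raise UndefinedProfileError(f"expression for {variant} is undefined")
        if expr < 0:
            raise ValueError(f"negative expression for {variant}: {expr}")
        vals[variant] = float(expr)
    total = sum(vals.values())
    if total == 0.0:
        raise UndefinedProfileError("all variant expressions are zero")
    out = {variant: 100.0 * v / total for variant, v in vals.items()}
    # exact closure: push rounding residue onto the largest component
    residue = 100.0 - sum(out.values())
    if residue != 0.0:
        top = max(out, key=out.get)  # type: ignore[arg-type]
        out[top] += residue
    return out


def make_profile(
    sample_id: str,
    receptor: Receptor,
    positive: bool,
    variant_exprs: dict[str, float] | None = None,
) -> VariantPercentProfile:
    """Build a profile, renormalising expressions if the sample is positive."""
    if not positive:
        return VariantPercentProfile(sample_id, receptor, False)
    if variant_exprs is None:
        raise UndefinedProfileError(
            f"positive sample {sample_id} has no variant expressions"
        )
    expected = set(RECEPTOR_VARIANTS[receptor])
    if set(variant_exprs) != expected:
        raise ValueError(
            f"expected variants {sorted(expected)}, got {sorted(variant_exprs)}"
        )
    return VariantPercentProfile(
        sample_id, receptor, True, variant_percentages(variant_exprs)
    )
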