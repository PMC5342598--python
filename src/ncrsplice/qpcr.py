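"""qPCR branch: Ct tables -> relative expression -> variant percentage profiles.

Relative expression follows the 2^-dCt method against beta-actin; splice
variant percentages renormalise the three variant expressions of a receptor
to a composition summing to 100.  Positivity of a sample for a receptor is
called on the receptor's total-transcript assay: detected mean Ct at or
below ``max_cycles`` (default 40).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .assays import (
    TOTAL_ASSAYS,
    VARIANT_ASSAYS,
    Assay,
    Receptor,
)
from .errors import UndefinedExpressionError, UndefinedProfileError
from .profiles import VariantPercentProfile, make_profile, variant_percentages

__all__ = [
    "CtRecord",
    "ExpressionValue",
    "QpcrConfig",
    "relative_expression",
    "aggregate_replicates",
    "call_positivity_qpcr",
    "variant_percentages",
    "build_qpcr_profiles",
    "read_ct_table",
]

log = logging.getLogger(__name__)

#: Strings in a Ct column that flag an undetected well.
UNDETECTED_TOKENS = {"", "undetermined", "undetected", "na", "nan"}


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: a Ct value in cycles, or None when undetected."""

    sample_id: str
    assay: Assay
    ct: float | None
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.ct is not None and not (math.isfinite(self.ct) and self.ct > 0):
            raise ValueError(f"Ct must be finite and positive, got {self.ct}")
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")

    @property
    def detected(self) -> bool:
        return self.ct is not None


@dataclass(frozen=True)
class ExpressionValue:
    """2^-dCt relative expression of one assay against a reference assay."""

    sample_id: str
    assay: Assay
    rel_expr: float
    reference_assay: Assay


@dataclass(frozen=True)
class QpcrConfig:
    """Tunables of the qPCR branch.

    max_cycles
        Detection ceiling in cycles; a total-assay Ct at or below it
        (boundary inclusive) calls the sample positive.
    percent_denominator
        "variant_sum" (default): percentages over the sum of the three
        variant expressions, guaranteeing closure to 100.  "total_primer":
        percentages over the total-transcript assay's expression instead.
    """

    max_cycles: float = 40.0
    percent_denominator: str = "variant_sum"

    def __post_init__(self) -> None:
        if self.max_cycles <= 0:
            raise ValueError("max_cycles must be positive")
        if self.percent_denominator not in ("variant_sum", "total_primer"):
            raise ValueError(
                f"unknown percent denominator {self.percent_denominator!r}"
            )


def relative_expression(ct_target: float | None, ct_reference: float | None) -> float:
    """2^-(ct_target - ct_reference).

    Raises :class:`UndefinedExpressionError` when either Ct is undetected;
    an undetected well never maps to zero expression.
    """
    if ct_target is None or ct_reference is None:
        raise UndefinedExpressionError("undetected Ct has no relative expression")
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise UndefinedExpressionError("non-finite Ct value")
    return 2.0 ** (-(ct_target - ct_reference))


def aggregate_replicates(records: list[CtRecord]) -> CtRecord:
    """Collapse replicate wells of one sample+assay to their mean Ct.

    The mean runs over detected wells only; the aggregate is undetected
    only when every replicate is undetected.  Partially detected replicate
    sets therefore count as detected (conservative toward positivity).
    """
    if not records:
        raise ValueError("cannot aggregate an empty replicate set")
    keys = {(r.sample_id, r.assay) for r in records}
    if len(keys) != 1:
        raise ValueError(f"mixed sample/assay in replicate set: {sorted(map(str, keys))}")
    sample_id, assay = records[0].sample_id, records[0].assay
    detected = [r.ct for r in records if r.ct is not None]
    ct = sum(detected) / len(detected) if detected else None
    return CtRecord(sample_id, assay, ct)


def call_positivity_qpcr(
    sample_records: list[CtRecord],
    receptor: Receptor,
    config: QpcrConfig | None = None,
) -> bool:
    """Positive iff the receptor's total assay has mean Ct <= max_cycles."""
    config = config or QpcrConfig()
    total_assay = TOTAL_ASSAYS[receptor]
    wells = [r for r in sample_records if r.assay == total_assay]
    if not wells:
        log.warning(
            "sample %s: no %s wells, calling negative",
            sample_records[0].sample_id if sample_records else "?",
            total_assay.value,
        )
        return False
    agg = aggregate_replicates(wells)
    return agg.ct is not None and agg.ct <= config.max_cycles


def read_ct_table(path: str | Path) -> list[CtRecord]:
    """Read a Ct table (CSV or TSV) into records.

    Expected header: ``sample_id,assay,ct,replicate`` (replicate optional).
    An empty or "Undetermined" Ct marks an undetected well.  Assay names
    match the panel enum, case-insensitively.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    return ct_records_from_frame(df)


def ct_records_from_frame(df: pd.DataFrame) -> list[CtRecord]:
    required = {"sample_id", "assay", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        raw_ct = str(getattr(row, "ct")).strip()
        ct = None if raw_ct.lower() in UNDETECTED_TOKENS else float(raw_ct)
        replicate = int(getattr(row, "replicate", 1) or 1)
        records.append(
            CtRecord(
                sample_id=str(getattr(row, "sample_id")),
                assay=Assay(str(getattr(row, "assay")).upper()),
                ct=ct,
                replicate=replicate,
            )
        )
    return records


def _mean_cts(records: list[CtRecord]) -> dict[Assay, CtRecord]:
    by_assay: dict[Assay, list[CtRecord]] = {}
    for r in records:
        by_assay.setdefault(r.assay, []).append(r)
    return {a: aggregate_replicates(rs) for a, rs in by_assay.items()}


def build_qpcr_profiles(
    records: list[CtRecord],
    config: QpcrConfig | None = None,
) -> tuple[list[VariantPercentProfile], pd.DataFrame]:
    """Per-sample profiles for both receptors, plus beta-actin-normalised totals.

    Samples without a detected beta-actin well are excluded with a warning.
    The second return value holds 2^-dCt (vs ACTB) for the NKp44/NKp30/NKp46
    total assays, for expression-level comparisons between groups.
    """
    config = config or QpcrConfig()
    by_sample: dict[str, list[CtRecord]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, []).append(r)

    profiles: list[VariantPercentProfile] = []
    totals_rows: list[dict] = []
    for sample_id, sample_records in by_sample.items():
        cts = _mean_cts(sample_records)
        actb = cts.get(Assay.ACTB)
        if actb is None or actb.ct is None:
            log.warning("sample %s: no detected ACTB, excluded", sample_id)
            continue

        for assay in (Assay.NKP44_TOTAL, Assay.NKP30_TOTAL, Assay.NKP46):
            agg = cts.get(assay)
            if agg is not None and agg.ct is not None:
                totals_rows.append(
                    {
                        "sample_id": sample_id,
                        "assay": assay.value,
                        "rel_expr_vs_actb": relative_expression(agg.ct, actb.ct),
                    }
                )

        for receptor in Receptor:
            positive = call_positivity_qpcr(sample_records, receptor, config)
            if not positive:
                profiles.append(make_profile(sample_id, receptor, False))
                continue
            exprs: dict[str, float] = {}
            undefined = False
            for assay, (rec, variant) in VARIANT_ASSAYS.items():
                if rec is not receptor:
                    continue
                agg = cts.get(assay)
                if agg is None or agg.ct is None:
                    undefined = True
                    break
                exprs[variant] = relative_expression(agg.ct, actb.ct)
            if undefined:
                log.warning(
                    "sample %s: %s positive but variant assays incomplete; "
                    "profile undefined, reported negative",
                    sample_id,
                    receptor.value,
                )
                profiles.append(make_profile(sample_id, receptor, False))
                continue
            if config.percent_denominator == "total_primer":
                total_agg = cts[TOTAL_ASSAYS[receptor]]
                denom = relative_expression(total_agg.ct, actb.ct)
                percents = {v: 100.0 * e / denom for v, e in exprs.items()}
                profiles.append(
                    VariantPercentProfile.unclosed(sample_id, receptor, percents)
                )
            else:
                try:
                    profiles.append(make_profile(sample_id, receptor, True, exprs))
                except UndefinedProfileError:
                    log.warning(
                        "sample %s: %s variant expressions all zero; "
                        "profile undefined, reported negative",
                        sample_id,
                        receptor.value,
                    )
                    profiles.append(make_profile(sample_id, receptor, False))

    totals = pd.DataFrame(totals_rows, columns=["sample_id", "assay", "rel_expr_vs_actb"])
    return profiles, totals


def profiles_to_frame(profiles: list[VariantPercentProfile]) -> pd.DataFrame:
    """Tabular view: one row per sample x receptor with variant percent columns."""
    from .assays import RECEPTOR_VARIANTS

    rows = []
    for p in profiles:
        row = {
            "sample_id": p.sample_id,
            "receptor": p.receptor.value,
            "positive": p.positive,
        }
        for variant in RECEPTOR_VARIANTS[p.receptor]:
            row[f"pct_{variant}"] = p.percents.get(variant) if p.positive else None
        rows.append(row)
    return pd.DataFrame(rows)
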