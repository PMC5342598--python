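"""Synthetic cohorts: qPCR Ct tables and TCGA-like RSEM file trees.

The generators emit exactly the formats the ingest modules read, with the
class labels used to generate each sample retained as ground truth, so the
whole pipeline is testable without external downloads.  Fractions are drawn
from class-conditional Dirichlet mixtures; Ct values (qPCR) and normalized
counts (RSEM) are back-computed so that the ingested percentages reproduce
the drawn fractions.  A boundary-exclusion band keeps drawn fractions away
from the classification thresholds so that generated labels are recovered
exactly.

Draw order is fixed and documented per generator (single RNG stream seeded
from the spec), so outputs are byte-identical for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tcga import DEFAULT_VARIANT_MAP, VariantMap, write_variant_map

_NKP44_ASSAYS = ("NKP44_TOTAL", "NKP44_1", "NKP44_2", "NKP44_3")
_NKP30_ASSAYS = ("NKP30_TOTAL", "NKP30_A", "NKP30_B", "NKP30_C")


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be a probability, got {value}")


def _check_conc(triplet, name: str) -> None:
    if len(triplet) != 3 or any(a <= 0 for a in triplet):
        raise ValidationError(f"{name} must be 3 positive concentrations")


# ---------------------------------------------------------------------------
# qPCR cohorts


@dataclass(frozen=True)
class QpcrCohortSpec:
    """Conditions of a simulated decidua-style qPCR cohort.

    NKp44 positivity and profile-class rates default to the high-positivity,
    dominance-leaning regime of healthy first/third-trimester decidua;
    NKp30 is near-universally positive with a mild activating lean.
    Dirichlet concentrations set the class-conditional variant fractions:
    the dominant class's expected NKp44-1 fraction must sit at or above the
    66% threshold and the non-dominant class's below it.
    """

    n_samples: int = 20
    positivity_rate: float = 0.9
    p_dominant: float = 0.8
    dirichlet_dominant: tuple[float, float, float] = (16.0, 2.0, 2.0)
    dirichlet_nondominant: tuple[float, float, float] = (8.0, 6.0, 6.0)
    nkp30_positivity_rate: float = 1.0
    p_ab: float = 0.55
    dirichlet_ab: tuple[float, float, float] = (10.0, 5.0, 5.0)
    dirichlet_c: tuple[float, float, float] = (5.0, 5.0, 10.0)
    ct_reference_mean: float = 20.0
    ct_reference_sd: float = 1.0
    total_delta_ct_mean: float = 6.0
    total_delta_ct_sd: float = 1.0
    noise_sd: float = 0.0
    boundary_band: float = 1.0  # percentage points kept clear of thresholds
    sample_prefix: str = "S"
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 0:
            raise ValidationError("n_samples must be >= 0")
        for name in ("positivity_rate", "p_dominant", "nkp30_positivity_rate", "p_ab"):
            _check_prob(getattr(self, name), name)
        for name in (
            "dirichlet_dominant",
            "dirichlet_nondominant",
            "dirichlet_ab",
            "dirichlet_c",
        ):
            _check_conc(getattr(self, name), name)
        dom = self.dirichlet_dominant
        if dom[0] / sum(dom) < 0.66:
            raise ValidationError("dominant-class expected NKp44-1 fraction < 66%")
        non = self.dirichlet_nondominant
        if non[0] / sum(non) >= 0.66:
            raise ValidationError("non-dominant-class expected NKp44-1 fraction >= 66%")
        if self.noise_sd < 0 or self.ct_reference_sd < 0 or self.total_delta_ct_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if not 0.0 <= self.boundary_band < 30.0:
            raise ValidationError("boundary_band out of range")


def _draw_nkp44_fractions(rng: np.random.Generator, spec, dominant: bool) -> np.ndarray:
    alpha = spec.dirichlet_dominant if dominant else spec.dirichlet_nondominant
    band = spec.boundary_band / 100.0
    for _ in range(10_000):
        f = rng.dirichlet(alpha)
        if dominant and f[0] >= 0.66 + band:
            return f
        if not dominant and f[0] <= 0.66 - band:
            return f
    raise ValidationError("could not draw fractions clear of the 66% boundary")


def _draw_nkp30_fractions(rng: np.random.Generator, spec, ab: bool) -> np.ndarray:
    alpha = spec.dirichlet_ab if ab else spec.dirichlet_c
    band = spec.boundary_band / 100.0
    for _ in range(10_000):
        f = rng.dirichlet(alpha)  # (a, b, c)
        if ab and f[0] >= f[2] + band:
            return f
        if not ab and f[0] <= f[2] - band:
            return f
    raise ValidationError("could not draw fractions clear of the %a = %c boundary")


@dataclass(frozen=True)
class QpcrCohort:
    ct_table: pd.DataFrame  # sample_id, assay, ct, replicate
    truth: pd.DataFrame  # sample_id, per-receptor positivity/class/fractions

    def write(self, ct_path: str | Path, truth_path: str | Path | None = None) -> None:
        self.ct_table.to_csv(ct_path, index=False)
        if truth_path is not None:
            self.truth.to_csv(truth_path, sep="\t", index=False)


def gen_qpcr_cohort(spec: QpcrCohortSpec) -> QpcrCohort:
    """Simulate one qPCR cohort.

    Per sample, in order: beta-actin Ct; NKp46 dCt; NKp44 positivity,
    class, fractions, total dCt; NKp30 likewise.  Ct values are
    back-computed from the drawn fractions (plus optional per-well Gaussian
    noise), so with zero noise the ingested percentages equal the drawn
    fractions exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    truth_rows: list[dict] = []

    def emit(sample_id: str, assay: str, ct: float | None) -> None:
        if ct is not None and spec.noise_sd > 0:
            ct += rng.normal(0.0, spec.noise_sd)
        rows.append(
            {
                "sample_id": sample_id,
                "assay": assay,
                "ct": "" if ct is None else f"{ct:.6f}",
                "replicate": 1,
            }
        )

    for i in range(spec.n_samples):
        sample_id = f"{spec.sample_prefix}{i + 1:03d}"
        actb_ct = rng.normal(spec.ct_reference_mean, spec.ct_reference_sd)
        emit(sample_id, "ACTB", actb_ct)
        emit(
            sample_id,
            "NKP46",
            actb_ct + rng.normal(spec.total_delta_ct_mean, spec.total_delta_ct_sd),
        )

        truth: dict = {"sample_id": sample_id}
        for receptor, assays, pos_rate, draw in (
            ("NKP44", _NKP44_ASSAYS, spec.positivity_rate, "nkp44"),
            ("NKP30", _NKP30_ASSAYS, spec.nkp30_positivity_rate, "nkp30"),
        ):
            positive = bool(rng.random() < pos_rate)
            truth[f"{receptor.lower()}_positive"] = positive
            if not positive:
                truth[f"{receptor.lower()}_class"] = "NEGATIVE"
                truth[f"{receptor.lower()}_fractions"] = ""
                for assay in assays:
                    emit(sample_id, assay, None)
                continue
            if draw == "nkp44":
                dominant = bool(rng.random() < spec.p_dominant)
                fracs = _draw_nkp44_fractions(rng, spec, dominant)
                truth["nkp44_class"] = "NKP44_1_DOMINANT" if dominant else "NKP44_2_3"
            else:
                ab = bool(rng.random() < spec.p_ab)
                fracs = _draw_nkp30_fractions(rng, spec, ab)
                truth["nkp30_class"] = "NKP30_AB" if ab else "NKP30_C"
            truth[f"{receptor.lower()}_fractions"] = ",".join(f"{f:.9f}" for f in fracs)
            delta = rng.normal(spec.total_delta_ct_mean, spec.total_delta_ct_sd)
            total_expr = 2.0 ** (-delta)
            emit(sample_id, assays[0], actb_ct + delta)
            for assay, f in zip(assays[1:], fracs):
                # rel_expr = f * total_expr  =>  Ct = actb - log2(f * E)
                emit(sample_id, assay, actb_ct - math.log2(f * total_expr))
        truth_rows.append(truth)

    cols = ["sample_id", "assay", "ct", "replicate"]
    return QpcrCohort(
        ct_table=pd.DataFrame(rows, columns=cols),
        truth=pd.DataFrame(truth_rows),
    )


def qpcr_fixture_table(
    nkp44_v1_fractions: dict[str, float | None] | None = None,
    nkp30_ac_percents: dict[str, tuple[float, float] | None] | None = None,
    actb_ct: float = 20.0,
    total_delta_ct: float = 6.0,
) -> pd.DataFrame:
    """Deterministic Ct table realising prescribed variant fractions.

    ``nkp44_v1_fractions`` maps sample id -> NKp44-1 fraction (the
    remainder split equally between NKp44-2 and -3) or None for an
    NKp44-negative sample.  ``nkp30_ac_percents`` maps sample id ->
    (%NKp30a, %NKp30c), the balance going to NKp30b, or None for negative.
    Useful for worked examples where exact published percentages must be
    reproduced through the full Ct pipeline.
    """
    rows: list[dict] = []
    samples: dict[str, dict] = {}
    for sid, f1 in (nkp44_v1_fractions or {}).items():
        samples.setdefault(sid, {})["nkp44"] = f1
    for sid, ac in (nkp30_ac_percents or {}).items():
        samples.setdefault(sid, {})["nkp30"] = ac

    def emit(sid: str, assay: str, ct: float | None) -> None:
        rows.append(
            {
                "sample_id": sid,
                "assay": assay,
                "ct": "" if ct is None else f"{ct:.9f}",
                "replicate": 1,
            }
        )

    for sid, setup in samples.items():
        emit(sid, "ACTB", actb_ct)
        total_expr = 2.0 ** (-total_delta_ct)
        if "nkp44" in setup:
            f1 = setup["nkp44"]
            if f1 is None:
                for assay in _NKP44_ASSAYS:
                    emit(sid, assay, None)
            else:
                if not 0.0 < f1 <= 1.0:
                    raise ValidationError(f"NKp44-1 fraction out of (0, 1]: {f1}")
                fr = (f1, (1.0 - f1) / 2.0, (1.0 - f1) / 2.0)
                emit(sid, "NKP44_TOTAL", actb_ct + total_delta_ct)
                for assay, f in zip(_NKP44_ASSAYS[1:], fr):
                    if f == 0.0:
                        emit(sid, assay, None)
                    else:
                        emit(sid, assay, actb_ct - math.log2(f * total_expr))
        if "nkp30" in setup:
            ac = setup["nkp30"]
            if ac is None:
                for assay in _NKP30_ASSAYS:
                    emit(sid, assay, None)
            else:
                pa, pc = ac
                pb = 100.0 - pa - pc
                if pb < 0:
                    raise ValidationError(f"%a + %c exceeds 100 for {sid}")
                fr = (pa / 100.0, pb / 100.0, pc / 100.0)
                emit(sid, "NKP30_TOTAL", actb_ct + total_delta_ct)
                for assay, f in zip(_NKP30_ASSAYS[1:], fr):
                    if f == 0.0:
                        emit(sid, assay, None)
                    else:
                        emit(sid, assay, actb_ct - math.log2(f * total_expr))
    return pd.DataFrame(rows, columns=["sample_id", "assay", "ct", "replicate"])


# ---------------------------------------------------------------------------
# TCGA-like cohorts


@dataclass(frozen=True)
class TcgaCohortSpec:
    """Conditions of a simulated matched tumor-normal RSEM cohort.

    Defaults emulate the reported TCGA-scale structure: ~99% NKp30
    positivity with a roughly 60/40 activating/inhibitory split in both
    tumor and normal tissue, NKp44 positivity higher in tumors (15%) than
    in matched normals (5%) with a strongly dominant NKp44-1 profile, and
    matched-normal availability around 10% of patients.  With
    ``shift_probability`` = 1 the tumor NKp30 profile is drawn
    independently of the matched normal, which under the default 60/40 mix
    makes roughly half of defined matched pairs non-identical.
    """

    n_patients: int = 100
    matched_fraction: float = 0.1
    cancer_acronym: str = "BRCA"
    stn_profile_mix: dict[str, float] = field(
        default_factory=lambda: {"AB": 0.59, "C": 0.40, "NEGATIVE": 0.01}
    )
    pst_profile_mix: dict[str, float] = field(
        default_factory=lambda: {"AB": 0.59, "C": 0.40, "NEGATIVE": 0.01}
    )
    shift_probability: float = 1.0
    nkp44_positivity_pst: float = 0.15
    nkp44_positivity_stn: float = 0.05
    nkp44_p_dominant: float = 0.9
    dirichlet_dominant: tuple[float, float, float] = (16.0, 2.0, 2.0)
    dirichlet_nondominant: tuple[float, float, float] = (8.0, 6.0, 6.0)
    dirichlet_ab: tuple[float, float, float] = (10.0, 5.0, 5.0)
    dirichlet_c: tuple[float, float, float] = (5.0, 5.0, 10.0)
    expression_log_mean: float = 4.0  # ln-scale location of gene-level counts
    expression_log_sd: float = 0.8
    boundary_band: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValidationError("n_patients must be >= 0")
        for name in (
            "matched_fraction",
            "shift_probability",
            "nkp44_positivity_pst",
            "nkp44_positivity_stn",
            "nkp44_p_dominant",
        ):
            _check_prob(getattr(self, name), name)
        for mix_name in ("stn_profile_mix", "pst_profile_mix"):
            mix = getattr(self, mix_name)
            if set(mix) != {"AB", "C", "NEGATIVE"}:
                raise ValidationError(f"{mix_name} must cover AB/C/NEGATIVE")
            if any(p < 0 for p in mix.values()) or not math.isclose(
                sum(mix.values()), 1.0, abs_tol=1e-9
            ):
                raise ValidationError(f"{mix_name} must be a distribution")
        from .tcga import CLUSTER_MAP

        if self.cancer_acronym.upper() not in CLUSTER_MAP:
            raise ValidationError(f"unknown acronym {self.cancer_acronym!r}")
        for name in (
            "dirichlet_dominant",
            "dirichlet_nondominant",
            "dirichlet_ab",
            "dirichlet_c",
        ):
            _check_conc(getattr(self, name), name)
        if not 0.0 <= self.boundary_band < 30.0:
            raise ValidationError("boundary_band out of range")


@dataclass(frozen=True)
class TcgaCohort:
    manifest_path: Path
    variant_map_path: Path
    truth: pd.DataFrame

    @property
    def root(self) -> Path:
        return self.manifest_path.parent


def _draw_mix(rng: np.random.Generator, mix: dict[str, float]) -> str:
    cats = ("AB", "C", "NEGATIVE")
    return cats[int(rng.choice(3, p=[mix[c] for c in cats]))]


def gen_tcga_cohort(
    spec: TcgaCohortSpec,
    outdir: str | Path,
    variant_map: VariantMap | None = None,
) -> TcgaCohort:
    """Simulate a matched RSEM cohort under ``outdir``.

    Per patient, in order: matched-normal availability; STN NKp30 category;
    PST NKp30 category (copied from STN, or redrawn from the PST mix with
    probability ``shift_probability``); per-sample NKp44 positivity, class
    and fractions; per-receptor NKp30 fractions and expression levels.
    Writes one isoform and one gene RSEM-style TSV per sample, a manifest,
    the variant map, and returns the ground-truth table.
    """
    spec.validate()
    variant_map = variant_map or DEFAULT_VARIANT_MAP
    rng = np.random.default_rng(spec.seed)
    outdir = Path(outdir)
    (outdir / "samples").mkdir(parents=True, exist_ok=True)

    iso_ids = {
        (rec, variant): iso_id for iso_id, (rec, variant) in variant_map.isoforms.items()
    }
    gene_ids = {name: gid for gid, name in variant_map.genes.items()}

    manifest_rows: list[dict] = []
    truth_rows: list[dict] = []

    def write_sample(barcode: str, sample_class: str, nkp30_cat: str, truth: dict):
        from .assays import RECEPTOR_VARIANTS, Receptor

        nkp44_rate = (
            spec.nkp44_positivity_pst
            if sample_class == "PST"
            else spec.nkp44_positivity_stn
        )
        nkp44_positive = bool(rng.random() < nkp44_rate)
        iso_rows: list[dict] = []
        genes: dict[str, float] = {"NKP44": 0.0, "NKP30": 0.0, "NKP46": 0.0}

        if nkp44_positive:
            dominant = bool(rng.random() < spec.nkp44_p_dominant)
            fr = _draw_nkp44_fractions(rng, spec, dominant)
            level = float(np.exp(rng.normal(spec.expression_log_mean, spec.expression_log_sd)))
            genes["NKP44"] = level
            truth[f"{sample_class.lower()}_nkp44_class"] = (
                "NKP44_1_DOMINANT" if dominant else "NKP44_2_3"
            )
        else:
            fr, level = None, 0.0
            truth[f"{sample_class.lower()}_nkp44_class"] = "NEGATIVE"
        for j, variant in enumerate(RECEPTOR_VARIANTS[Receptor.NKP44]):
            iso_rows.append(
                {
                    "isoform_id": iso_ids[(Receptor.NKP44, variant)],
                    "normalized_count": 0.0 if fr is None else level * float(fr[j]),
                }
            )

        if nkp30_cat != "NEGATIVE":
            fr30 = _draw_nkp30_fractions(rng, spec, nkp30_cat == "AB")
            level30 = float(
                np.exp(rng.normal(spec.expression_log_mean, spec.expression_log_sd))
            )
            genes["NKP30"] = level30
        else:
            fr30, level30 = None, 0.0
        for j, variant in enumerate(RECEPTOR_VARIANTS[Receptor.NKP30]):
            iso_rows.append(
                {
                    "isoform_id": iso_ids[(Receptor.NKP30, variant)],
                    "normalized_count": 0.0 if fr30 is None else level30 * float(fr30[j]),
                }
            )
        truth[f"{sample_class.lower()}_nkp30_class"] = (
            "NKP30_AB" if nkp30_cat == "AB" else
            "NKP30_C" if nkp30_cat == "C" else "NEGATIVE"
        )

        genes["NKP46"] = float(
            np.exp(rng.normal(spec.expression_log_mean, spec.expression_log_sd))
        )

        iso_path = f"samples/{barcode}.rsem.isoforms.normalized_results.tsv"
        gene_path = f"samples/{barcode}.rsem.genes.normalized_results.tsv"
        pd.DataFrame(iso_rows).to_csv(outdir / iso_path, sep="\t", index=False)
        pd.DataFrame(
            [
                {"gene_id": gene_ids[name], "normalized_count": genes[name]}
                for name in ("NKP44", "NKP30", "NKP46")
            ]
        ).to_csv(outdir / gene_path, sep="\t", index=False)
        manifest_rows.append(
            {
                "barcode": barcode,
                "isoform_path": iso_path,
                "gene_path": gene_path,
                "cancer_acronym": spec.cancer_acronym.upper(),
            }
        )

    for i in range(spec.n_patients):
        patient = f"TCGA-SY-{i:04d}"
        truth: dict = {"patient_id": patient}
        has_stn = bool(rng.random() < spec.matched_fraction)
        truth["has_stn"] = has_stn
        stn_cat = _draw_mix(rng, spec.stn_profile_mix)
        if rng.random() < spec.shift_probability:
            pst_cat = _draw_mix(rng, spec.pst_profile_mix)
        else:
            pst_cat = stn_cat
        if has_stn:
            write_sample(f"{patient}-11A-01T-{i:04d}-01", "STN", stn_cat, truth)
        write_sample(f"{patient}-01A-01T-{i:04d}-01", "PST", pst_cat, truth)
        truth_rows.append(truth)

    manifest_path = outdir / "manifest.tsv"
    pd.DataFrame(
        manifest_rows, columns=["barcode", "isoform_path", "gene_path", "cancer_acronym"]
    ).to_csv(manifest_path, sep="\t", index=False)
    vm_path = outdir / "variant_map.tsv"
    write_variant_map(variant_map, vm_path)
    truth_df = pd.DataFrame(truth_rows)
    truth_df.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return TcgaCohort(manifest_path=manifest_path, variant_map_path=vm_path, truth=truth_df)
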