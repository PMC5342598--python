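"""TCGA-style ingest: barcodes, RSEM normalized tables, matched pairs.

Sample class is read from the barcode's sample-type token: "01" = primary
solid tumor (PST), "11" = solid tissue normal (STN), everything else is
excluded.  In a full aliquot barcode such as TCGA-AB-2842-03A-01T-0734-13
the sample-type token is the 4th dash-separated section ("03A"); its leading
two digits are the type code and the trailing letter the vial.  Gene-level
RSEM normalized counts drive positivity; isoform-level counts, mapped to
splice variants through an editable variant map, yield percentage profiles.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .assays import RECEPTOR_VARIANTS, Receptor
from .errors import BarcodeError, UnknownAcronymError
from .profiles import VariantPercentProfile, make_profile

log = logging.getLogger(__name__)

_TYPE_CODE_RE = re.compile(r"^([0-9]{2})([A-Z]?)$")


class SampleClass(str, enum.Enum):
    PST = "PST"  # 01, primary solid tumor
    STN = "STN"  # 11, solid tissue normal
    EXCLUDED = "EXCLUDED"


class Cluster(str, enum.Enum):
    BREAST = "Breast"
    LUNG = "Lung"
    CERVICAL_UTERINE = "CervicalUterine"
    KIDNEY = "Kidney"
    GI_TRACT = "GITract"
    GI_ACCESSORY = "GIAccessory"


#: Study acronym -> organ-of-origin cluster.
CLUSTER_MAP: dict[str, Cluster] = {
    "BRCA": Cluster.BREAST,
    "LUAD": Cluster.LUNG,
    "LUSC": Cluster.LUNG,
    "CESC": Cluster.CERVICAL_UTERINE,
    "UCEC": Cluster.CERVICAL_UTERINE,
    "UCS": Cluster.CERVICAL_UTERINE,
    "KICH": Cluster.KIDNEY,
    "KIRC": Cluster.KIDNEY,
    "KIRP": Cluster.KIDNEY,
    "COAD": Cluster.GI_TRACT,
    "ESCA": Cluster.GI_TRACT,
    "READ": Cluster.GI_TRACT,
    "STAD": Cluster.GI_TRACT,
    "CHOL": Cluster.GI_ACCESSORY,
    "LIHC": Cluster.GI_ACCESSORY,
    "PAAD": Cluster.GI_ACCESSORY,
}


@dataclass(frozen=True)
class TCGABarcode:
    raw: str
    patient_id: str
    sample_type_code: str
    vial: str | None = None
    analyte: str | None = None


@dataclass(frozen=True)
class SampleAnnotation:
    barcode: TCGABarcode
    sample_class: SampleClass
    cancer_acronym: str
    cluster: Cluster


def parse_barcode(raw: str) -> TCGABarcode:
    """Parse a TCGA sample/aliquot barcode.

    Requires at least four dash-separated sections; the patient id joins the
    first three, the sample-type token is the fourth.  The analyte letter
    (e.g. "T" for total RNA) is taken from the fifth section when present;
    it is recorded but never filtered on.
    """
    sections = raw.split("-")
    if len(sections) < 4 or any(not s for s in sections[:4]):
        raise BarcodeError(f"malformed barcode {raw!r}: need >= 4 dashed sections")
    m = _TYPE_CODE_RE.match(sections[3])
    if not m:
        raise BarcodeError(
            f"malformed barcode {raw!r}: sample-type token {sections[3]!r}"
        )
    code, vial = m.group(1), m.group(2) or None
    analyte = None
    if len(sections) >= 5 and sections[4]:
        trailing = sections[4][-1]
        if trailing.isalpha():
            analyte = trailing
    return TCGABarcode(
        raw=raw,
        patient_id="-".join(sections[:3]),
        sample_type_code=code,
        vial=vial,
        analyte=analyte,
    )


def classify_sample(code: str) -> SampleClass:
    """"01" -> PST, "11" -> STN, anything else -> EXCLUDED."""
    if code == "01":
        return SampleClass.PST
    if code == "11":
        return SampleClass.STN
    return SampleClass.EXCLUDED


def assign_cluster(
    acronym: str, cluster_map: dict[str, Cluster] | None = None
) -> Cluster:
    cluster_map = cluster_map if cluster_map is not None else CLUSTER_MAP
    try:
        return cluster_map[acronym.upper()]
    except KeyError:
        raise UnknownAcronymError(
            f"unknown study acronym {acronym!r}; known: {sorted(cluster_map)}"
        ) from None


def annotate(
    raw_barcode: str,
    cancer_acronym: str,
    cluster_map: dict[str, Cluster] | None = None,
) -> SampleAnnotation:
    bc = parse_barcode(raw_barcode)
    return SampleAnnotation(
        barcode=bc,
        sample_class=classify_sample(bc.sample_type_code),
        cancer_acronym=cancer_acronym.upper(),
        cluster=assign_cluster(cancer_acronym, cluster_map),
    )


# ---------------------------------------------------------------------------
# Variant map and RSEM tables


@dataclass(frozen=True)
class VariantMap:
    """Isoform/gene identifier mapping for the two receptors.

    ``isoforms`` maps transcript id -> (receptor, variant label);
    ``genes`` maps gene id -> receptor (or gene symbol for e.g. NKp46).
    The map ships as an editable TSV because transcript annotations differ
    across RSEM annotation builds.
    """

    isoforms: dict[str, tuple[Receptor, str]]
    genes: dict[str, str]

    def __post_init__(self) -> None:
        for receptor in Receptor:
            labels = {v for (r, v) in self.isoforms.values() if r is receptor}
            if labels and labels != set(RECEPTOR_VARIANTS[receptor]):
                raise ValueError(
                    f"{receptor.value} must map exactly the variants "
                    f"{RECEPTOR_VARIANTS[receptor]}, got {sorted(labels)}"
                )


#: Default synthetic identifiers, matching the bundled cohort generator.
DEFAULT_VARIANT_MAP = VariantMap(
    isoforms={
        "iso_NKp44_1": (Receptor.NKP44, "NKp44-1"),
        "iso_NKp44_2": (Receptor.NKP44, "NKp44-2"),
        "iso_NKp44_3": (Receptor.NKP44, "NKp44-3"),
        "iso_NKp30_a": (Receptor.NKP30, "NKp30a"),
        "iso_NKp30_b": (Receptor.NKP30, "NKp30b"),
        "iso_NKp30_c": (Receptor.NKP30, "NKp30c"),
    },
    genes={
        "NCR2|9436": "NKP44",
        "NCR3|259197": "NKP30",
        "NCR1|9437": "NKP46",
    },
)


def read_variant_map(path: str | Path) -> VariantMap:
    """Read a variant map TSV: columns ``feature_id receptor variant``.

    Rows with variant ``total`` are gene-level ids; other rows are isoform
    ids mapping to a named splice variant.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"feature_id", "receptor", "variant"}
    if not required <= set(df.columns):
        raise ValueError(f"variant map needs columns {sorted(required)}")
    isoforms: dict[str, tuple[Receptor, str]] = {}
    genes: dict[str, str] = {}
    for row in df.itertuples(index=False):
        fid = str(row.feature_id)
        if str(row.variant).lower() == "total":
            genes[fid] = str(row.receptor).upper()
        else:
            if fid in isoforms:
                raise ValueError(f"isoform {fid!r} mapped twice")
            isoforms[fid] = (Receptor(str(row.receptor).upper()), str(row.variant))
    return VariantMap(isoforms=isoforms, genes=genes)


def write_variant_map(vm: VariantMap, path: str | Path) -> None:
    rows = [
        {"feature_id": fid, "receptor": rec.value, "variant": variant}
        for fid, (rec, variant) in vm.isoforms.items()
    ]
    rows += [
        {"feature_id": gid, "receptor": rec, "variant": "total"}
        for gid, rec in vm.genes.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _read_rsem(path: str | Path, id_col_candidates: tuple[str, ...]) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    id_col = next((c for c in id_col_candidates if c in df.columns), df.columns[0])
    if "normalized_count" not in df.columns:
        raise ValueError(f"{path}: no normalized_count column")
    s = df.set_index(id_col)["normalized_count"].astype(float)
    if (s < 0).any():
        raise ValueError(f"{path}: negative normalized counts")
    return s


def load_isoform_table(
    path: str | Path, variant_map: VariantMap
) -> dict[Receptor, dict[str, float]]:
    """Extract receptor-variant normalized counts from one RSEM isoform file.

    Unmapped isoforms are ignored.  A receptor missing any mapped isoform is
    dropped from the result (logged), mirroring samples where the annotation
    lacks the transcript.
    """
    counts = _read_rsem(path, ("isoform_id", "transcript_id"))
    out: dict[Receptor, dict[str, float]] = {}
    for iso_id, (receptor, variant) in variant_map.isoforms.items():
        if iso_id in counts.index:
            out.setdefault(receptor, {})[variant] = float(counts[iso_id])
    complete: dict[Receptor, dict[str, float]] = {}
    for receptor, exprs in out.items():
        if set(exprs) == set(RECEPTOR_VARIANTS[receptor]):
            complete[receptor] = exprs
        else:
            log.warning("%s: incomplete isoform set for %s", path, receptor.value)
    if not out:
        log.warning("%s: no mapped isoforms found", path)
    return complete


def load_gene_table(path: str | Path, variant_map: VariantMap) -> dict[str, float]:
    """Gene-level normalized counts keyed by receptor/gene name."""
    counts = _read_rsem(path, ("gene_id",))
    return {
        name: float(counts[gid])
        for gid, name in variant_map.genes.items()
        if gid in counts.index
    }


def call_positivity_rsem(normalized_count: float, epsilon: float = 0.0) -> bool:
    """Positive iff the gene-level normalized count exceeds ``epsilon``.

    The permissive default (> 0) is required for near-universal NKp30
    positivity in bulk tissue to be reproducible.
    """
    return normalized_count > epsilon


def match_pairs(
    annotations: list[SampleAnnotation],
) -> list[tuple[str, SampleAnnotation, SampleAnnotation]]:
    """Matched (patient, STN, PST) triples.

    Patients lacking either class are excluded from paired analyses (they
    remain in total-PST analyses).  Duplicate aliquots within a class
    resolve to the lexicographically smallest barcode, deterministically.
    """
    by_patient: dict[str, dict[SampleClass, list[SampleAnnotation]]] = {}
    for ann in annotations:
        if ann.sample_class is SampleClass.EXCLUDED:
            continue
        by_patient.setdefault(ann.barcode.patient_id, {}).setdefault(
            ann.sample_class, []
        ).append(ann)
    pairs = []
    for patient_id in sorted(by_patient):
        classes = by_patient[patient_id]
        if SampleClass.PST in classes and SampleClass.STN in classes:
            stn = min(classes[SampleClass.STN], key=lambda a: a.barcode.raw)
            pst = min(classes[SampleClass.PST], key=lambda a: a.barcode.raw)
            pairs.append((patient_id, stn, pst))
    return pairs


# ---------------------------------------------------------------------------
# Cohort assembly


@dataclass(frozen=True)
class TcgaSample:
    annotation: SampleAnnotation
    profiles: dict[Receptor, VariantPercentProfile]
    gene_counts: dict[str, float]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest TSV: ``barcode  isoform_path  gene_path  cancer_acronym``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"barcode", "isoform_path", "gene_path", "cancer_acronym"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    return df


def load_cohort(
    manifest_path: str | Path,
    variant_map: VariantMap | None = None,
    epsilon: float = 0.0,
    cluster_map: dict[str, Cluster] | None = None,
) -> list[TcgaSample]:
    """Load every manifest sample into annotated percentage profiles.

    Positivity comes from the gene-level file (normalized count > epsilon);
    variant percentages from the isoform-level file by division by the
    receptor's variant-sum.  A positive sample whose isoform set is missing
    or all-zero is reported receptor-negative with a warning.
    """
    variant_map = variant_map or DEFAULT_VARIANT_MAP
    manifest = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    samples: list[TcgaSample] = []
    for row in manifest.itertuples(index=False):
        ann = annotate(str(row.barcode), str(row.cancer_acronym), cluster_map)
        gene_counts = load_gene_table(_resolve(base, row.gene_path), variant_map)
        iso = load_isoform_table(_resolve(base, row.isoform_path), variant_map)
        profs: dict[Receptor, VariantPercentProfile] = {}
        for receptor in Receptor:
            gene_count = gene_counts.get(receptor.value, 0.0)
            positive = call_positivity_rsem(gene_count, epsilon)
            exprs = iso.get(receptor)
            if positive and (exprs is None or sum(exprs.values()) == 0.0):
                log.warning(
                    "%s: %s gene-positive but isoforms missing/zero; "
                    "reported negative",
                    ann.barcode.raw,
                    receptor.value,
                )
                positive = False
            profs[receptor] = make_profile(
                ann.barcode.raw, receptor, positive, exprs if positive else None
            )
        samples.append(TcgaSample(ann, profs, gene_counts))
    return samples


def _resolve(base: Path, p) -> Path:
    path = Path(str(p))
    return path if path.is_absolute() else base / path
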