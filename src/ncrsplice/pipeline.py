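"""Study arms: decidua-style qPCR cohorts and TCGA-style tumor cohorts.

Each arm reads its inputs, builds per-sample variant-percentage profiles,
classifies them, and emits incidence tables, profile distributions,
pairwise Fisher exact tests and (for the tumor arm) matched-pair shift
summaries, as TSV tables plus one JSON report.  Every output table carries
a header line naming the pipeline version and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import pandas as pd

from . import __version__
from .assays import Receptor
from .classify import (
    ClassifierConfig,
    Identity,
    PairedShiftCall,
    ProfileCall,
    ProfileLabel,
    ShiftDirection,
    classify_profile,
    classify_shift,
)
from .qpcr import QpcrConfig, build_qpcr_profiles, profiles_to_frame, read_ct_table
from .stats import (
    IncidenceSummary,
    ProfileDistribution,
    compare_groups,
    incidence,
    profile_distribution,
)
from .tcga import SampleClass, TcgaSample, load_cohort, match_pairs, read_variant_map

log = logging.getLogger(__name__)


def _config_hash(*configs) -> str:
    blob = json.dumps([asdict(c) for c in configs], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, confhash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ncrsplice {__version__} config={confhash}\n")
        df.to_csv(fh, sep="\t", index=False)


def _incidence_row(summary: IncidenceSummary) -> dict:
    return {
        "group": summary.group,
        "n_positive": summary.n_positive,
        "n_total": summary.n_total,
        "percent_positive": round(summary.percent_positive, 2),
    }


def _distribution_rows(dist: ProfileDistribution) -> list[dict]:
    return [
        {
            "group": dist.group,
            "label": label.value,
            "count": dist.counts.get(label, 0),
            "percent_of_positive": round(pct, 2),
        }
        for label, pct in sorted(dist.percents.items(), key=lambda kv: kv[0].value)
    ]


def _pairwise_fisher(
    named: list[tuple[str, IncidenceSummary | ProfileDistribution]], what: str
) -> list[dict]:
    rows = []
    for (name_a, a), (name_b, b) in itertools.combinations(named, 2):
        try:
            table, result = compare_groups(a, b)
        except ValueError as exc:
            log.warning("skipping %s %s vs %s: %s", what, name_a, name_b, exc)
            continue
        rows.append(
            {
                "comparison": what,
                "group_a": name_a,
                "group_b": name_b,
                "a": table.a,
                "b": table.b,
                "c": table.c,
                "d": table.d,
                "p_value": result.p_value,
                "significant_0.05": result.p_value < 0.05,
                "significant_0.01": result.p_value < 0.01,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# qPCR arm


@dataclass(frozen=True)
class QpcrArmResult:
    incidence: dict[Receptor, dict[str, IncidenceSummary]]
    distributions: dict[Receptor, dict[str, ProfileDistribution]]
    calls: list[ProfileCall]
    tests: list[dict]


def read_groups(path: str | Path) -> dict[str, str]:
    """Group assignment file: columns ``sample_id`` and ``group``."""
    p = Path(path)
    sep = "\t" if p.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(p, sep=sep, dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError("groups file needs sample_id and group columns")
    return dict(zip(df["sample_id"], df["group"]))


def run_qpcr_arm(
    ct_table_path: str | Path,
    groups_path: str | Path,
    outdir: str | Path,
    qpcr_config: QpcrConfig | None = None,
    classifier_config: ClassifierConfig | None = None,
) -> QpcrArmResult:
    """Decidua-style arm: Ct table + clinical groups -> profile reports."""
    qpcr_config = qpcr_config or QpcrConfig()
    classifier_config = classifier_config or ClassifierConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    confhash = _config_hash(qpcr_config, classifier_config)

    records = read_ct_table(ct_table_path)
    if not records:
        raise ValueError(f"Ct table {ct_table_path} is empty")
    groups = read_groups(groups_path)
    sample_ids = {r.sample_id for r in records}
    unknown = sorted(set(groups) - sample_ids)
    if unknown:
        log.warning("groups file lists unknown sample ids, excluded: %s", unknown)

    profiles, totals = build_qpcr_profiles(records, qpcr_config)
    calls = [classify_profile(p, classifier_config) for p in profiles]

    grouped: dict[Receptor, dict[str, list[ProfileCall]]] = {r: {} for r in Receptor}
    for call in calls:
        group = groups.get(call.sample_id)
        if group is None:
            log.warning("sample %s has no group assignment, excluded", call.sample_id)
            continue
        grouped[call.receptor].setdefault(group, []).append(call)

    inc: dict[Receptor, dict[str, IncidenceSummary]] = {r: {} for r in Receptor}
    dists: dict[Receptor, dict[str, ProfileDistribution]] = {r: {} for r in Receptor}
    for receptor in Receptor:
        for group, group_calls in sorted(grouped[receptor].items()):
            inc[receptor][group] = incidence(group_calls, group)
            try:
                dists[receptor][group] = profile_distribution(group_calls, group)
            except ValueError:
                log.warning("%s/%s: no positive cases", receptor.value, group)

    tests: list[dict] = []
    for receptor in Receptor:
        tests += _pairwise_fisher(
            list(inc[receptor].items()), f"{receptor.value}_incidence"
        )
        tests += _pairwise_fisher(
            list(dists[receptor].items()), f"{receptor.value}_profile"
        )

    _write_table(profiles_to_frame(profiles), outdir / "profiles_per_sample.tsv", confhash)
    _write_table(totals, outdir / "totals_vs_actb.tsv", confhash)
    for receptor, stem in ((Receptor.NKP44, "nkp44"), (Receptor.NKP30, "nkp30")):
        _write_table(
            pd.DataFrame([_incidence_row(s) for s in inc[receptor].values()]),
            outdir / f"incidence_{stem}.tsv",
            confhash,
        )
        rows = [r for d in dists[receptor].values() for r in _distribution_rows(d)]
        _write_table(pd.DataFrame(rows), outdir / f"profiles_{stem}.tsv", confhash)
    _write_table(pd.DataFrame(tests), outdir / "fisher_tests.tsv", confhash)

    report = {
        "pipeline": {"name": "ncrsplice", "version": __version__, "config_hash": confhash},
        "n_fisher_tests": len(tests),
        "incidence": {
            r.value: {g: _incidence_row(s) for g, s in inc[r].items()} for r in Receptor
        },
        "distributions": {
            r.value: {g: _distribution_rows(d) for g, d in dists[r].items()}
            for r in Receptor
        },
        "tests": tests,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return QpcrArmResult(incidence=inc, distributions=dists, calls=calls, tests=tests)


# ---------------------------------------------------------------------------
# TCGA arm


@dataclass(frozen=True)
class TcgaArmResult:
    samples: list[TcgaSample]
    calls: dict[str, dict[Receptor, ProfileCall]]  # barcode -> receptor -> call
    shifts: list[PairedShiftCall]
    tests: list[dict]
    report: dict


def run_tcga_arm(
    manifest_path: str | Path,
    outdir: str | Path,
    variant_map_path: str | Path | None = None,
    epsilon: float = 0.0,
    classifier_config: ClassifierConfig | None = None,
) -> TcgaArmResult:
    """Tumor arm: manifest + RSEM files -> incidence, profiles, shifts.

    Reports, per organ cluster: NKp44 incidence in matched PST vs STN with
    Fisher tests; NKp44 incidence and profile distribution in total PST;
    NKp30 distributions in total PST, matched PST and matched STN; and the
    matched-pair NKp30 identity/shift summary (pairs with a
    receptor-negative side counted as non-defined).
    """
    classifier_config = classifier_config or ClassifierConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    confhash = _config_hash(classifier_config)

    variant_map = read_variant_map(variant_map_path) if variant_map_path else None
    samples = load_cohort(manifest_path, variant_map, epsilon=epsilon)
    calls: dict[str, dict[Receptor, ProfileCall]] = {}
    for s in samples:
        calls[s.annotation.barcode.raw] = {
            r: classify_profile(p, classifier_config) for r, p in s.profiles.items()
        }

    by_cluster: dict[str, list[TcgaSample]] = {}
    for s in samples:
        by_cluster.setdefault(s.annotation.cluster.value, []).append(s)

    inc_rows: list[dict] = []
    dist_rows: list[dict] = []
    shift_rows: list[dict] = []
    tests: list[dict] = []
    all_shifts: list[PairedShiftCall] = []
    report_clusters: dict[str, dict] = {}

    for cluster, cluster_samples in sorted(by_cluster.items()):
        anns = [s.annotation for s in cluster_samples]
        pairs = match_pairs(anns)
        pst_all = [
            s for s in cluster_samples if s.annotation.sample_class is SampleClass.PST
        ]
        paired_barcodes = {
            (stn.barcode.raw, pst.barcode.raw) for _, stn, pst in pairs
        }
        stn_matched = [s for s in cluster_samples if any(
            s.annotation.barcode.raw == b[0] for b in paired_barcodes)]
        pst_matched = [s for s in cluster_samples if any(
            s.annotation.barcode.raw == b[1] for b in paired_barcodes)]

        def _calls(samples_, receptor):
            return [calls[s.annotation.barcode.raw][receptor] for s in samples_]

        cluster_report: dict = {"n_pst_total": len(pst_all), "n_pairs": len(pairs)}

        # NKp44 incidence: matched PST vs STN (paired comparison) and total PST
        named_inc: list[tuple[str, IncidenceSummary]] = []
        for name, subset in (
            (f"{cluster}/PST_matched", pst_matched),
            (f"{cluster}/STN_matched", stn_matched),
            (f"{cluster}/PST_total", pst_all),
        ):
            if not subset:
                continue
            summary = incidence(_calls(subset, Receptor.NKP44), name)
            named_inc.append((name, summary))
            inc_rows.append({"receptor": "NKP44", **_incidence_row(summary)})
        tests += _pairwise_fisher(named_inc[:2], f"{cluster}/NKP44_incidence")
        cluster_report["nkp44_incidence"] = [
            _incidence_row(s) for _, s in named_inc
        ]

        # Profile distributions
        for receptor, stem in ((Receptor.NKP44, "NKP44"), (Receptor.NKP30, "NKP30")):
            named_dists: list[tuple[str, ProfileDistribution]] = []
            for name, subset in (
                (f"{cluster}/PST_total", pst_all),
                (f"{cluster}/PST_matched", pst_matched),
                (f"{cluster}/STN_matched", stn_matched),
            ):
                if not subset:
                    continue
                try:
                    dist = profile_distribution(_calls(subset, receptor), name)
                except ValueError:
                    continue
                named_dists.append((name, dist))
                for row in _distribution_rows(dist):
                    dist_rows.append({"receptor": stem, **row})
            tests += _pairwise_fisher(named_dists, f"{cluster}/{stem}_profile")
            cluster_report[f"{stem.lower()}_distributions"] = {
                name: _distribution_rows(d) for name, d in named_dists
            }

        # Matched-pair NKp30 shifts
        shifts = [
            replace(
                classify_shift(
                    calls[stn.barcode.raw][Receptor.NKP30],
                    calls[pst.barcode.raw][Receptor.NKP30],
                ),
                patient_id=patient,
            )
            for patient, stn, pst in pairs
        ]
        all_shifts += shifts
        n_defined = sum(1 for s in shifts if s.identity is not Identity.NON_DEFINED)
        n_identical = sum(1 for s in shifts if s.identity is Identity.IDENTICAL)
        dir_counts = {
            d.value: sum(1 for s in shifts if s.direction is d) for d in ShiftDirection
        }
        shift_summary = {
            "cluster": cluster,
            "n_pairs": len(pairs),
            "n_defined": n_defined,
            "n_identical": n_identical,
            "n_non_identical": n_defined - n_identical,
            "pct_identical": round(100.0 * n_identical / n_defined, 2)
            if n_defined
            else None,
            "pct_non_identical": round(100.0 * (n_defined - n_identical) / n_defined, 2)
            if n_defined
            else None,
            **{f"n_{k.lower()}": v for k, v in dir_counts.items()},
        }
        shift_rows.append(shift_summary)
        cluster_report["nkp30_shift"] = shift_summary
        report_clusters[cluster] = cluster_report

    pair_rows = [
        {
            "patient_id": s.patient_id,
            "stn_label": s.stn_call.label.value,
            "pst_label": s.pst_call.label.value,
            "identity": s.identity.value,
            "direction": s.direction.value,
        }
        for s in all_shifts
    ]
    _write_table(pd.DataFrame(pair_rows), outdir / "nkp30_shift_pairs.tsv", confhash)
    _write_table(pd.DataFrame(inc_rows), outdir / "incidence_nkp44.tsv", confhash)
    _write_table(pd.DataFrame(dist_rows), outdir / "profile_distributions.tsv", confhash)
    _write_table(pd.DataFrame(shift_rows), outdir / "nkp30_shift_summary.tsv", confhash)
    _write_table(pd.DataFrame(tests), outdir / "fisher_tests.tsv", confhash)

    report = {
        "pipeline": {"name": "ncrsplice", "version": __version__, "config_hash": confhash},
        "n_fisher_tests": len(tests),
        "clusters": report_clusters,
        "tests": tests,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return TcgaArmResult(
        samples=samples, calls=calls, shifts=all_shifts, tests=tests, report=report
    )
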