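import math

import numpy as np
import pytest

from ncrsplice.assays import Receptor
from ncrsplice.classify import Identity, ProfileLabel, classify_profile, classify_shift
from ncrsplice.errors import ValidationError
from ncrsplice.qpcr import build_qpcr_profiles, ct_records_from_frame, read_ct_table
from ncrsplice.simulate import (
    QpcrCohortSpec,
    TcgaCohortSpec,
    gen_qpcr_cohort,
    gen_tcga_cohort,
    qpcr_fixture_table,
)
from ncrsplice.tcga import load_cohort, match_pairs, parse_barcode, read_variant_map


class TestQpcrGenerator:
    def test_same_seed_byte_identical(self, tmp_path):
        spec = QpcrCohortSpec(n_samples=12, seed=42)
        for name in ("a.csv", "b.csv"):
            gen_qpcr_cohort(spec).write(tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_empty_cohort(self):
        cohort = gen_qpcr_cohort(QpcrCohortSpec(n_samples=0))
        assert cohort.ct_table.empty and cohort.truth.empty

    def test_full_positivity(self):
        cohort = gen_qpcr_cohort(
            QpcrCohortSpec(n_samples=50, positivity_rate=1.0, seed=1)
        )
        profiles, _ = build_qpcr_profiles(ct_records_from_frame(cohort.ct_table))
        nkp44 = [p for p in profiles if p.receptor is Receptor.NKP44]
        assert len(nkp44) == 50 and all(p.positive for p in nkp44)

    def test_dominant_rate_recovery(self):
        # binomial concentration of the classified dominant fraction
        p, n = 0.8, 400
        cohort = gen_qpcr_cohort(
            QpcrCohortSpec(n_samples=n, positivity_rate=1.0, p_dominant=p, seed=9)
        )
        profiles, _ = build_qpcr_profiles(ct_records_from_frame(cohort.ct_table))
        labels = [
            classify_profile(pr).label
            for pr in profiles
            if pr.receptor is Receptor.NKP44
        ]
        frac = labels.count(ProfileLabel.NKP44_1_DOMINANT) / n
        assert abs(frac - p) <= 3 * math.sqrt(p * (1 - p) / n)

    def test_generated_labels_recovered_exactly(self):
        cohort = gen_qpcr_cohort(QpcrCohortSpec(n_samples=60, seed=3))
        profiles, _ = build_qpcr_profiles(ct_records_from_frame(cohort.ct_table))
        truth = cohort.truth.set_index("sample_id")
        for p in profiles:
            key = "nkp44_class" if p.receptor is Receptor.NKP44 else "nkp30_class"
            assert classify_profile(p).label.value == truth.loc[p.sample_id, key]

    def test_generated_table_parses_without_warnings(self, tmp_path, caplog):
        gen_qpcr_cohort(QpcrCohortSpec(n_samples=20, seed=4)).write(tmp_path / "ct.csv")
        with caplog.at_level("WARNING"):
            records = read_ct_table(tmp_path / "ct.csv")
            build_qpcr_profiles(records)
        assert not caplog.records

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_samples": -1},
            {"positivity_rate": 1.5},
            {"dirichlet_dominant": (1.0, 2.0, 2.0)},  # expected v1 below threshold
            {"dirichlet_nondominant": (20.0, 1.0, 1.0)},  # expected v1 above it
            {"noise_sd": -0.1},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            gen_qpcr_cohort(QpcrCohortSpec(**kwargs))


class TestQpcrFixtureTable:
    def test_prescribed_fractions_come_back(self):
        df = qpcr_fixture_table(
            nkp44_v1_fractions={"s1": 0.75, "s2": None},
            nkp30_ac_percents={"s1": (50.0, 30.0)},
        )
        profiles, _ = build_qpcr_profiles(ct_records_from_frame(df))
        by = {(p.sample_id, p.receptor): p for p in profiles}
        assert by[("s1", Receptor.NKP44)].percents["NKp44-1"] == pytest.approx(75.0)
        assert not by[("s2", Receptor.NKP44)].positive
        p30 = by[("s1", Receptor.NKP30)]
        assert p30.percents["NKp30a"] == pytest.approx(50.0)
        assert p30.percents["NKp30b"] == pytest.approx(20.0)
        assert p30.percents["NKp30c"] == pytest.approx(30.0)


class TestTcgaGenerator:
    def test_same_seed_byte_identical(self, tmp_path):
        spec = TcgaCohortSpec(n_patients=8, matched_fraction=0.5, seed=21)
        c1 = gen_tcga_cohort(spec, tmp_path / "one")
        c2 = gen_tcga_cohort(spec, tmp_path / "two")
        for rel in ["manifest.tsv", "truth.tsv"] + sorted(
            p.relative_to(c1.root).as_posix() for p in (c1.root / "samples").iterdir()
        ):
            assert (c1.root / rel).read_bytes() == (c2.root / rel).read_bytes()

    def test_barcodes_round_trip(self, tcga_cohort):
        _, cohort = tcga_cohort
        samples = load_cohort(cohort.manifest_path)
        truth = cohort.truth.set_index("patient_id")
        for s in samples:
            bc = parse_barcode(s.annotation.barcode.raw)
            assert bc.patient_id in truth.index
            assert bc.sample_type_code in ("01", "11")

    def test_fully_matched_cohort_pairs(self, tmp_path):
        spec = TcgaCohortSpec(n_patients=20, matched_fraction=1.0, seed=5)
        cohort = gen_tcga_cohort(spec, tmp_path / "m")
        samples = load_cohort(cohort.manifest_path)
        pairs = match_pairs([s.annotation for s in samples])
        assert len(pairs) == 20

    def test_zero_shift_all_identical(self, tmp_path):
        spec = TcgaCohortSpec(
            n_patients=30,
            matched_fraction=1.0,
            shift_probability=0.0,
            stn_profile_mix={"AB": 1.0, "C": 0.0, "NEGATIVE": 0.0},
            pst_profile_mix={"AB": 1.0, "C": 0.0, "NEGATIVE": 0.0},
            seed=6,
        )
        cohort = gen_tcga_cohort(spec, tmp_path / "z")
        samples = load_cohort(cohort.manifest_path)
        calls = {
            s.annotation.barcode.raw: classify_profile(s.profiles[Receptor.NKP30])
            for s in samples
        }
        pairs = match_pairs([s.annotation for s in samples])
        shifts = [
            classify_shift(calls[stn.barcode.raw], calls[pst.barcode.raw])
            for _, stn, pst in pairs
        ]
        assert shifts and all(s.identity is Identity.IDENTICAL for s in shifts)

    def test_shift_fraction_matches_expectation(self, tmp_path):
        # with independent resampling, P(non-identical | defined pair)
        # = s * sum_l P_stn(l) * (1 - P_pst(l)) over the two defined labels
        s_prob = 0.6
        mix = {"AB": 0.7, "C": 0.3, "NEGATIVE": 0.0}
        spec = TcgaCohortSpec(
            n_patients=500,
            matched_fraction=1.0,
            shift_probability=s_prob,
            stn_profile_mix=mix,
            pst_profile_mix=mix,
            seed=7,
        )
        cohort = gen_tcga_cohort(spec, tmp_path / "s")
        samples = load_cohort(cohort.manifest_path)
        calls = {
            s.annotation.barcode.raw: classify_profile(s.profiles[Receptor.NKP30])
            for s in samples
        }
        pairs = match_pairs([s.annotation for s in samples])
        shifts = [
            classify_shift(calls[stn.barcode.raw], calls[pst.barcode.raw])
            for _, stn, pst in pairs
        ]
        frac = sum(s.identity is Identity.NON_IDENTICAL for s in shifts) / len(shifts)
        expected = s_prob * sum(p * (1 - p) for p in (mix["AB"], mix["C"]))
        sd = math.sqrt(expected * (1 - expected) / len(shifts))
        assert abs(frac - expected) <= 3 * sd

    def test_negative_samples_have_zero_gene_count(self, tmp_path):
        spec = TcgaCohortSpec(
            n_patients=10,
            matched_fraction=0.0,
            stn_profile_mix={"AB": 0.0, "C": 0.0, "NEGATIVE": 1.0},
            pst_profile_mix={"AB": 0.0, "C": 0.0, "NEGATIVE": 1.0},
            seed=8,
        )
        cohort = gen_tcga_cohort(spec, tmp_path / "n")
        samples = load_cohort(cohort.manifest_path)
        assert all(s.gene_counts["NKP30"] == 0.0 for s in samples)
        assert all(not s.profiles[Receptor.NKP30].positive for s in samples)

    def test_generated_files_parse_without_warnings(self, tmp_path, caplog):
        spec = TcgaCohortSpec(n_patients=10, matched_fraction=0.5, seed=9)
        cohort = gen_tcga_cohort(spec, tmp_path / "w")
        with caplog.at_level("WARNING"):
            vm = read_variant_map(cohort.variant_map_path)
            load_cohort(cohort.manifest_path, vm)
        assert not caplog.records

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"cancer_acronym": "NOPE"},
            {"stn_profile_mix": {"AB": 0.5, "C": 0.4, "NEGATIVE": 0.2}},
            {"matched_fraction": -0.2},
        ],
    )
    def test_invalid_specs_rejected(self, tmp_path, kwargs):
        with pytest.raises(ValidationError):
            gen_tcga_cohort(TcgaCohortSpec(**kwargs), tmp_path / "bad")


class TestBarcodeRoundTripBulk:
    def test_many_generated_barcodes_parse_back(self):
        rng = np.random.default_rng(13)
        for _ in range(2000):
            i = int(rng.integers(0, 10_000))
            code = "01" if rng.random() < 0.5 else "11"
            raw = f"TCGA-SY-{i:04d}-{code}A-01T-{i:04d}-01"
            bc = parse_barcode(raw)
            assert bc.patient_id == f"TCGA-SY-{i:04d}"
            assert bc.sample_type_code == code
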