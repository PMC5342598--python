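#!/usr/bin/env python
"""Tumor arm: incidence, NKp30 profiles and matched-pair shifts.

Runs the RSEM pipeline on the simulated TCGA-like cohort produced by
01_simulate_cohorts.py, writing tables to results/tumor/.  Prints the
NKp44 incidence in total tumor samples, the NKp30 activating/inhibitory
split, and the identical vs non-identical fractions among matched
tumor-normal pairs.
"""

from pathlib import Path

from ncrsplice.pipeline import run_tcga_arm

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = ROOT / "scratch" / "cohorts" / "tcga_sim"
    if not cohort.exists():
        raise SystemExit("run analysis/01_simulate_cohorts.py first")
    out = ROOT / "results" / "tumor"
    res = run_tcga_arm(
        cohort / "manifest.tsv", out, variant_map_path=cohort / "variant_map.tsv"
    )

    for cluster, rep in res.report["clusters"].items():
        print(f"cluster {cluster}: {rep['n_pst_total']} tumors, {rep['n_pairs']} matched pairs")
        for row in rep["nkp44_incidence"]:
            print(f"  NKp44 incidence {row['group']}: "
                  f"{row['n_positive']}/{row['n_total']} ({row['percent_positive']}%)")
        for name, rows in rep["nkp30_distributions"].items():
            split = ", ".join(f"{r['label']} {r['percent_of_positive']}%" for r in rows)
            print(f"  NKp30 {name}: {split}")
        shift = rep["nkp30_shift"]
        if shift["n_defined"]:
            print(f"  matched NKp30 pairs: {shift['pct_identical']}% identical, "
                  f"{shift['pct_non_identical']}% non-identical "
                  f"({shift['n_non_defined']} non-defined)")
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
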