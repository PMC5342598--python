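#!/usr/bin/env python
"""Decidua arm: positivity incidence and profile distributions per group.

Runs the qPCR pipeline on the worked-example decidua cohort produced by
01_simulate_cohorts.py and writes its tables to results/decidua/.  Prints
the headline numbers: NKp44 positivity per clinical group, the dominant
(inhibitory) NKp44-1 profile rates, the term-delivery NKp30 split, and the
elective-vs-spontaneous Fisher exact test.
"""

from pathlib import Path

from ncrsplice.assays import Receptor
from ncrsplice.classify import ProfileLabel
from ncrsplice.pipeline import run_qpcr_arm

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    cohort = ROOT / "scratch" / "cohorts" / "decidua"
    if not cohort.exists():
        raise SystemExit("run analysis/01_simulate_cohorts.py first")
    out = ROOT / "results" / "decidua"
    res = run_qpcr_arm(cohort / "ct_table.csv", cohort / "groups.csv", out)

    print("NKp44 mRNA positivity:")
    for group, s in res.incidence[Receptor.NKP44].items():
        print(f"  {group:>13}: {s.n_positive}/{s.n_total} ({s.percent_positive:.1f}%)")
    print("NKp44-1-dominant profile among positive cases:")
    for group, d in res.distributions[Receptor.NKP44].items():
        pct = d.percents.get(ProfileLabel.NKP44_1_DOMINANT, 0.0)
        print(f"  {group:>13}: {d.counts.get(ProfileLabel.NKP44_1_DOMINANT, 0)}"
              f"/{d.n_positive} ({pct:.2f}%)")
    term30 = res.distributions[Receptor.NKP30]["term"]
    print(
        "term-delivery NKp30a/b vs NKp30c: "
        f"{term30.percents[ProfileLabel.NKP30_AB]:.2f}% / "
        f"{term30.percents[ProfileLabel.NKP30_C]:.2f}%"
    )
    fisher = next(
        t for t in res.tests
        if t["comparison"] == "NKP44_profile"
        and {t["group_a"], t["group_b"]} == {"elective", "spontaneous"}
    )
    print(f"elective vs spontaneous NKp44 profile Fisher p = {fisher['p_value']:.5f}")
    print(f"tables written to {out}")


if __name__ == "__main__":
    main()
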