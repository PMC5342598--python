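#!/usr/bin/env python
"""Generate the cohorts the downstream analyses run on.

Writes, under scratch/cohorts/:
  decidua/   the worked-example decidua qPCR cohort (fixed group structure:
             elective 7, spontaneous 23, term 15, preeclampsia 10)
  qpcr_sim/  a randomly drawn qPCR cohort from the default simulator
  tcga_sim/  a TCGA-like matched RSEM cohort (200 patients, 10% matched)
"""

import sys
from pathlib import Path

import pandas as pd

from ncrsplice.examples import decidua_example_cohort
from ncrsplice.simulate import QpcrCohortSpec, TcgaCohortSpec, gen_qpcr_cohort, gen_tcga_cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    base = ROOT / "scratch" / "cohorts"
    (base / "decidua").mkdir(parents=True, exist_ok=True)

    ct, groups = decidua_example_cohort(seed=SEED)
    ct.to_csv(base / "decidua" / "ct_table.csv", index=False)
    groups.to_csv(base / "decidua" / "groups.csv", index=False)
    print(f"decidua worked example: {groups.groupby('group').size().to_dict()}")

    (base / "qpcr_sim").mkdir(exist_ok=True)
    cohort = gen_qpcr_cohort(QpcrCohortSpec(n_samples=60, seed=SEED))
    cohort.write(base / "qpcr_sim" / "ct_table.csv", base / "qpcr_sim" / "truth.tsv")
    groups = pd.DataFrame(
        {
            "sample_id": cohort.truth["sample_id"],
            "group": ["first_trimester" if i < 30 else "third_trimester" for i in range(60)],
        }
    )
    groups.to_csv(base / "qpcr_sim" / "groups.csv", index=False)
    print(f"simulated qPCR cohort: {len(cohort.truth)} samples")

    tcga = gen_tcga_cohort(
        TcgaCohortSpec(n_patients=200, matched_fraction=0.1, seed=SEED),
        base / "tcga_sim",
    )
    n_matched = int(tcga.truth["has_stn"].sum())
    print(f"simulated TCGA cohort: 200 patients, {n_matched} with matched normals")


if __name__ == "__main__":
    main()
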