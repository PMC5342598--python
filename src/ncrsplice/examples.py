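"""Worked-example decidua cohort with published group structure.

Builds a deterministic qPCR cohort whose group sizes, positivity counts and
variant fractions reproduce the reported decidua figures through the full
Ct pipeline: elective abortions (7/7 NKp44-positive, 6/7 NKp44-1-dominant),
spontaneous abortions (21/23 positive, 16/21 NKp44-2/3), term deliveries
(12/15 positive, 10/12 dominant; NKp30 8/15 a/b vs 7/15 c) and
preeclampsia (8/10 positive, 4/4 split).  Ct baselines are drawn from a
seeded RNG; variant percentages are invariant to them by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import qpcr_fixture_table

#: NKp44-1 fractions per clinical group; None marks an NKp44-negative sample.
DECIDUA_NKP44_FRACTIONS: dict[str, list[float | None]] = {
    "elective": [0.90, 0.80, 0.75, 0.70, 0.68, 0.67, 0.50],
    "spontaneous": [0.80] * 5 + [0.40] * 16 + [None, None],
    "term": [0.80] * 10 + [0.40] * 2 + [None] * 3,
    "preeclampsia": [0.80] * 4 + [0.40] * 4 + [None] * 2,
}

#: (%NKp30a, %NKp30c) pairs for the term-delivery group (remainder NKp30b).
DECIDUA_TERM_NKP30: list[tuple[float, float]] = [(50.0, 30.0)] * 8 + [(30.0, 50.0)] * 7


def decidua_example_cohort(seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(Ct table, group assignments) for the worked decidua example."""
    rng = np.random.default_rng(seed)
    tables = []
    group_rows = []
    for group, fractions in DECIDUA_NKP44_FRACTIONS.items():
        nkp30 = DECIDUA_TERM_NKP30 if group == "term" else None
        for i, f1 in enumerate(fractions):
            sample_id = f"{group[:4]}_{i + 1:02d}"
            tables.append(
                qpcr_fixture_table(
                    nkp44_v1_fractions={sample_id: f1},
                    nkp30_ac_percents={sample_id: nkp30[i]} if nkp30 else None,
                    actb_ct=float(rng.normal(20.0, 1.0)),
                    total_delta_ct=float(rng.normal(6.0, 1.0)),
                )
            )
            group_rows.append({"sample_id": sample_id, "group": group})
    ct_table = pd.concat(tables, ignore_index=True)
    return ct_table, pd.DataFrame(group_rows)
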