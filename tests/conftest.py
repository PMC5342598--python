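import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def qpcr_cohort_dir(tmp_path):
    """A 30-sample simulated qPCR cohort split into two clinical groups."""
    from ncrsplice.simulate import QpcrCohortSpec, gen_qpcr_cohort

    cohort = gen_qpcr_cohort(QpcrCohortSpec(n_samples=30, seed=11))
    cohort.write(tmp_path / "ct.csv", tmp_path / "truth.tsv")
    groups = pd.DataFrame(
        {
            "sample_id": cohort.truth["sample_id"],
            "group": ["elective" if i % 2 else "term" for i in range(len(cohort.truth))],
        }
    )
    groups.to_csv(tmp_path / "groups.csv", index=False)
    return tmp_path


@pytest.fixture()
def tcga_cohort(tmp_path):
    """A 40-patient simulated TCGA-like cohort, half with matched normals."""
    from ncrsplice.simulate import TcgaCohortSpec, gen_tcga_cohort

    spec = TcgaCohortSpec(n_patients=40, matched_fraction=0.5, seed=12)
    return spec, gen_tcga_cohort(spec, tmp_path / "tcga")
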