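import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from karyoexpr import CountMatrix, GeneAnnotation, simulate_scenario  # noqa: E402

EXPECTED_GAINS = [("ESC1", "19"), ("ESC1", "20"), ("ESC2", "20")]
EXPECTED_X_CLASSES = {
    "ESC1": "male_single_X",
    "ESC2": "female_XIST_pos_Xi",
    "ESC3": "female_XIST_pos_Xi",
    "ESC4": "male_single_X",
    "ES_REF": "female_XIST_neg_biactive",
}


@pytest.fixture(scope="session")
def study_cohort():
    """One seeded study-design cohort (5 ES lines + fibroblast outgroup)."""
    counts, annotation, truth, config = simulate_scenario("study_design", seed=0)
    return counts, annotation, truth, config


@pytest.fixture(scope="session")
def es_cohort():
    """Study-design cohort without the fibroblast outgroup."""
    counts, annotation, truth, config = simulate_scenario(
        "study_design", seed=0, include_fibroblast=False
    )
    return counts, annotation, truth, config


@pytest.fixture
def tiny_counts():
    """Hand-sized matrix: 5 genes x 2 lines x 2 replicates."""
    counts = pd.DataFrame(
        {
            "A_r1": [30, 20, 25, 15, 10],
            "A_r2": [28, 22, 24, 16, 10],
            "B_r1": [10, 40, 25, 15, 10],
            "B_r2": [12, 38, 26, 14, 10],
        },
        index=pd.Index(["g1", "g2", "g3", "g4", "g5"], name="gene_id"),
    )
    return CountMatrix(counts)


@pytest.fixture
def tiny_annotation():
    chrom = pd.Series(
        ["1", "1", "2", "X", "X"],
        index=pd.Index(["g1", "g2", "g3", "g4", "g5"], name="gene_id"),
    )
    return GeneAnnotation(chrom)
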