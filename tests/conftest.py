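import numpy as np
import pandas as pd
import pytest

from escapesel.simulate import CohortSimConfig, simulate_cohort, simulate_genome


@pytest.fixture(scope="session")
def default_config():
    return CohortSimConfig(seed=11)


@pytest.fixture(scope="session")
def default_genome(default_config):
    return simulate_genome(default_config)


@pytest.fixture(scope="session")
def default_cohort(default_genome, default_config):
    return simulate_cohort(default_genome, default_config, seed=101)


@pytest.fixture(scope="session")
def truth_groups(default_cohort):
    return default_cohort.truth["patients"].set_index("patient_id")["group"]


@pytest.fixture(scope="session")
def truth_labels(default_cohort):
    t = default_cohort.truth["patients"]
    return pd.DataFrame({"patient_id": t["patient_id"], "status": t["group"]})


def make_catalog(rows):
    """Build a minimal mutation catalog from dict rows (test helper)."""
    defaults = {
        "patient_id": "P1",
        "gene_id": "G1",
        "chromosome": "chr1",
        "position": 1,
        "ref_allele": "A",
        "alt_allele": "C",
        "variant_class": "missense",
        "context": np.nan,
        "vaf": np.nan,
        "cancer_type": "TT",
        "non_snv": False,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])
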