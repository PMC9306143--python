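import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from patternrisk.data import (
    CohortDataset,
    FactorSpec,
    MultiCohortDataset,
    RiskFactorSchema,
    default_schema,
)
from patternrisk.synthetic import (
    CohortConfig,
    SyntheticConfig,
    default_scenario,
    default_true_model,
    generate_multicohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_schema():
    """Reduced 2-mandatory + 3-optional schema for fast library tests."""
    return RiskFactorSchema(
        (
            FactorSpec("psa", "continuous", "log2", mandatory=True),
            FactorSpec("age", "continuous", "none", mandatory=True),
            FactorSpec("dre", "binary", levels=("normal", "abnormal")),
            FactorSpec("volume", "continuous", "log2"),
            FactorSpec("prior_neg_biopsy", "binary", levels=("no", "yes")),
        )
    )


@pytest.fixture(scope="session")
def default_data():
    """The default study conditions: 10 training cohorts + validation cohort."""
    return default_scenario(1)


@pytest.fixture(scope="session")
def complete_data():
    """Two cohorts, n=2,000 total, zero missingness."""
    cfg = SyntheticConfig(
        cohorts=(CohortConfig("A", 1200), CohortConfig("B", 800)),
        true_model=default_true_model(),
        target_prevalence=0.30,
        seed=5,
    )
    return generate_multicohort(cfg)


@pytest.fixture(scope="session")
def small_training(small_schema):
    """Two small cohorts under the reduced schema, sporadic missing volume."""
    rng = np.random.default_rng(17)
    cohorts = []
    for cid, n in (("A", 400), ("B", 300)):
        psa = np.exp(rng.normal(np.log(6), 0.7, n))
        age = np.clip(rng.normal(64, 8, n), 40, 90)
        dre = (rng.random(n) < 0.25).astype(float)
        volume = np.exp(rng.normal(np.log(40), 0.45, n))
        pnb = (rng.random(n) < 0.25).astype(float)
        eta = -2.0 + 0.85 * np.log2(psa) + 0.05 * (age - 64) + 0.6 * dre - 1.1 * np.log2(volume / 40) - 1.0 * pnb
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        vol = volume.copy()
        vol[rng.random(n) < 0.3] = np.nan
        frame = pd.DataFrame(
            {"outcome": y, "psa": psa, "age": age, "dre": dre, "volume": vol, "prior_neg_biopsy": pnb}
        )
        cohorts.append(CohortDataset(cid, frame, small_schema))
    return MultiCohortDataset(cohorts)


@pytest.fixture
def example_patient():
    return {
        "psa": 6.0,
        "age": 65.0,
        "dre": 0.0,
        "volume": 40.0,
        "prior_neg_biopsy": 1.0,
        "fiveari": 0.0,
        "prior_psa_screen": 1.0,
        "african_ancestry": 0.0,
        "hispanic": 0.0,
        "fam_pca_1st": 1.0,
        "fam_pca_2nd": 0.0,
        "fam_bca_1st": 0.0,
    }
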