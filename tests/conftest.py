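import numpy as np
import pandas as pd
import pytest

from ubcphen.simulate import SimulationConfig, SimulatedCohort, VariantSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_sim() -> SimulatedCohort:
    """One modest cohort with contaminants and a couple of variants, shared
    read-only across tests."""
    config = SimulationConfig(
        n_patients=400,
        seed=11,
        ineligible_rate=0.07,
        prob_noise=0.05,
        variants=(
            VariantSpec(rsid="rs_eff", allele_ref="T", allele_eff="G", maf=0.3,
                        odds_ratio=1.5, outcome_label="recurrence"),
            VariantSpec(rsid="rs_null", allele_ref="A", allele_eff="C", maf=0.2,
                        odds_ratio=1.0, outcome_label="null"),
        ),
    )
    return simulate_cohort(config)


@pytest.fixture()
def toy_catalog() -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"rsid": "rs_eff", "allele_ref": "T", "allele_eff": "G",
             "outcome_label": "recurrence", "subgroup": "UBC",
             "original_direction": "+", "original_estimate": 1.5},
            {"rsid": "rs_null", "allele_ref": "A", "allele_eff": "C",
             "outcome_label": "recurrence", "subgroup": "NMIBC",
             "original_direction": "+", "original_estimate": 1.2},
        ]
    )
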