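import math

import pytest

from t1dgrs.cohort_io import default_weights
from t1dgrs.grs_core import WeightConfig
from t1dgrs.synthetic_data import (SimulationConfig, default_group_models,
                                   simulate_cohort)


@pytest.fixture(scope="session")
def weights():
    return default_weights()


@pytest.fixture(scope="session")
def cau_models():
    return default_group_models("CAU")


@pytest.fixture(scope="session")
def toy_weights():
    """Two SNPs (OR 2 and 4), no haplotype loci, a single non-zero
    diplotype weight H = ln 3 on DR3/DR4."""
    return WeightConfig(
        snp_betas={"snpA": math.log(2.0), "snpB": math.log(4.0)},
        hla_diplotype_beta={
            "DR3_DR4": math.log(3.0), "DR4_DR4": 0.0, "DR3_DR3": 0.0,
            "DR4_X": 0.0, "DR3_X": 0.0, "X_X": 0.0,
        },
        haplotype_betas={},
        snp_chromosomes={"snpA": "1", "snpB": "2"},
    )


@pytest.fixture(scope="session")
def small_cau_cohort(cau_models, weights):
    """Modest three-group Caucasian cohort for pipeline-level checks."""
    config = SimulationConfig(
        group_sizes={"t1d": 400, "relative1": 300, "control": 300},
        seed=11)
    return simulate_cohort(cau_models, config, weights)
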