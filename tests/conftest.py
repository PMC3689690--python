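import numpy as np
import pytest

from drsim.cohort import CohortConfig, DistributionSpec, default_config
from drsim.domain import LogisticHazard, PredictorProfile, TransitionRates
from drsim.lifetable import gompertz_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def profile():
    """A typical mid-cohort profile."""
    return PredictorProfile(
        age=67.0,
        male=True,
        dm_duration=21.0,
        bmi=32.0,
        hba1c=8.2,
        hypertension=True,
        dyslipidemia=True,
        nephropathy=False,
        tobacco=False,
    )


@pytest.fixture
def training_config():
    """Packaged default: training moments, published odds ratios,
    intercept pending calibration."""
    return default_config(seed=2024)


def constant_specs(age=67.0, dur=21.0, bmi=32.0, hba1c=8.0, **flag_ps):
    ps = {
        "male": 1.0,
        "hypertension": 1.0,
        "dyslipidemia": 1.0,
        "nephropathy": 0.0,
        "tobacco": 0.0,
    }
    ps.update(flag_ps)
    specs = {
        "age": DistributionSpec("constant", mean=age),
        "dm_duration": DistributionSpec("constant", mean=dur),
        "bmi": DistributionSpec("constant", mean=bmi),
        "hba1c": DistributionSpec("constant", mean=hba1c),
    }
    for name, p in ps.items():
        specs[name] = DistributionSpec("bernoulli", p=p)
    return specs


@pytest.fixture
def frozen_config():
    """Degenerate config: every predictor constant, hazard fully given.

    With identical agents the per-year transition probabilities are the
    same for everyone, so the cohort is an iid sample from one Markov
    chain — the basis of the analytic-oracle tests.
    """
    return CohortConfig(
        n=100,
        seed=7,
        specs=constant_specs(),
        rates=TransitionRates(onset_annual=0.077, vl_annual=0.007),
        hazard=LogisticHazard({"dm_duration": 0.0}, intercept=-1.5),
        target_pdr_prevalence=0.265,
    )


@pytest.fixture
def flat_life_table():
    """Constant qx = 0.02 at every age (Gompertz with b = 0)."""
    return gompertz_table(a=-np.log(1 - 0.02), b=0.0, max_age=200)


@pytest.fixture
def zero_mortality_table():
    """No deaths until the table edge at age 500."""
    return gompertz_table(a=1e-300, b=0.0, max_age=500)
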