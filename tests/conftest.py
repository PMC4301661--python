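import numpy as np
import pytest

from hetsurv import pipeline as pl
from hetsurv import synthetic_data as sd


@pytest.fixture(scope="session")
def tiny_sim_config() -> sd.SimConfig:
    """A small but structurally complete study: 3 cohorts (2 EUR, 1 AFR),
    4 chromosomes, both reference populations."""
    return sd.SimConfig(n_cohorts=3, n_individuals=250, n_snps=320,
                        n_chromosomes=4, n_reference_per_pop=50,
                        true_log_hr_per_sd=np.log(0.8))


@pytest.fixture(scope="session")
def tiny_study(tiny_sim_config):
    return sd.simulate_study(tiny_sim_config, seed=20240917)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_study):
    return tiny_study[0]


@pytest.fixture(scope="session")
def study_config(tiny_sim_config) -> pl.StudyConfig:
    return pl.StudyConfig(sim=tiny_sim_config, seed=20240917)


def simulate_simple_survival(rng, n, beta, covariate=None, *,
                             rate=0.03, entry_range=(50.0, 70.0),
                             censor_age=95.0):
    """Minimal exponential survival draw used across survival tests."""
    import pandas as pd

    x = rng.standard_normal(n) if covariate is None else covariate
    entry = rng.uniform(*entry_range, size=n)
    dur = rng.exponential(1.0 / rate, size=n) * np.exp(-beta * x)
    exit_age = np.minimum(entry + dur, censor_age)
    dead = (entry + dur <= censor_age).astype(int)
    exit_age = np.maximum(exit_age, entry + 1e-4)
    return pd.DataFrame({"entry_age": entry, "exit_age": exit_age,
                         "dead": dead, "x": x})
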