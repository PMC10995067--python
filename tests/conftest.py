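import numpy as np
import pytest

from agemeta.studyfit import StudySummary
from agemeta.synthdata import ScenarioSpec, SimDesign, emulate_applied_table


def make_summaries(seed=0, k=12, beta_snp=1.5, slope=0.02, tau=0.15,
                   age_lo=12.0, age_hi=55.0, centre=10.0):
    """Random but reproducible study summaries following a linear age trend."""
    rng = np.random.default_rng(seed)
    mean_ages = rng.uniform(age_lo, age_hi, k)
    sd_ages = rng.uniform(1.0, 6.0, k)
    se = rng.uniform(0.05, 0.3, k)
    y = (
        beta_snp
        + slope * (mean_ages - centre)
        + rng.normal(0.0, tau, k)
        + rng.normal(0.0, se)
    )
    return [
        StudySummary(str(i), float(y[i]), float(se[i]), 1000,
                     float(mean_ages[i]), float(sd_ages[i]))
        for i in range(k)
    ]


@pytest.fixture(scope="session")
def applied_table():
    return emulate_applied_table(seed=5)


@pytest.fixture(scope="session")
def small_collection():
    """One simulated scenario-2 base-case collection at reduced study size."""
    from agemeta.synthdata import simulate_collection

    design = SimDesign(n_studies=12, n_per_study=400, seed=42)
    return simulate_collection(design, ScenarioSpec(2))
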