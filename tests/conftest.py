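import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from occrelapse.formulations import (
    active_trajectory,
    default_formulations,
    placebo_trajectory,
)
from occrelapse.simulate import HazardSpec, TrialDesign, simulate_trial

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def formulations():
    return default_formulations()


@pytest.fixture(scope="session")
def lai1m_trajectories(formulations):
    p = formulations["lai_1m"]
    return {
        "active": active_trajectory(p, 365),
        "placebo": placebo_trajectory(p, 365),
    }


@pytest.fixture(scope="session")
def group_effect_trial(formulations):
    """One 1-monthly trial simulated with a pure group effect (log-HR -1)."""
    spec = HazardSpec(baseline_hazard_per_day=0.005, beta_group=-1.0,
                      beta_occ_per_10pct=0.0)
    design = TrialDesign("grp", "lai_1m", 1000, 1000, 365, 0.0006)
    return simulate_trial(design, formulations["lai_1m"], spec, 12)


@pytest.fixture(scope="session")
def small_trial(formulations):
    """A modest trial under the default occupancy-driven hazard."""
    design = TrialDesign("small", "lai_1m", 150, 150, 365, 0.0006)
    return simulate_trial(design, formulations["lai_1m"], HazardSpec(), 123)
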