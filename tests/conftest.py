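import numpy as np
import pytest

from mathstrat.inference import FitConfig, fit_hierarchical
from mathstrat.model import preprocess_trials
from mathstrat.synth import CohortSpec, generate_item_bank, sample_population, simulate_behavior


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort with known ground truth (8 children, 60
    trials/session) shared by tests that need real-looking behavior."""
    spec = CohortSpec(n_participants=8, trials_per_session=60, seed=3)
    items = generate_item_bank(spec)
    pop = sample_population(spec)
    obs, truth = simulate_behavior(pop, items, spec, dt=2e-4)
    return {
        "spec": spec, "items": items, "pop": pop,
        "trials": preprocess_trials(obs), "truth": truth,
    }


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """A short full-model fit of the small cohort (reduced draws)."""
    return fit_hierarchical(
        small_cohort["trials"],
        cfg=FitConfig(n_chains=2, n_samples=400, burn_in=200, seed=5),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
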