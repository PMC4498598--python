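import numpy as np
import pytest

from coalor.penetrance import PenetranceModel
from coalor.scenario import ScenarioConfig, simulate_candidate


@pytest.fixture
def rng():
    return np.random.default_rng(20150710)


def make_toy_dataset(rng, n=40, loci=1, mutation_rate=1.0, model=None):
    """A small unconditioned population for oracle comparisons."""
    if model is None:
        model = PenetranceModel.logistic(-1.0, 0.5)
    cfg = ScenarioConfig(
        penetrance=model,
        population_size=n,
        loci=loci,
        mutation_rate=mutation_rate,
        prevalence_window=(0.0, 1.0),
        target_accepted=1,
        seed=0,
    )
    return simulate_candidate(cfg, rng)


@pytest.fixture
def toy_dataset(rng):
    return make_toy_dataset(rng)
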