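import numpy as np
import pytest

import rakenorm as rn


@pytest.fixture(scope="session")
def bank():
    return rn.draw_item_bank(seed=11)


@pytest.fixture(scope="session")
def spec1():
    return rn.scenario_cells(1)


@pytest.fixture(scope="session")
def reference_small(spec1):
    """Small reference population (60k/cohort) with moments and raw scores."""
    pop = rn.generate_population(spec1, 60_000, seed=101)
    moments = rn.reference_moments(pop)
    return pop, moments


@pytest.fixture(scope="session")
def moments(reference_small):
    return reference_small[1]


@pytest.fixture(scope="session")
def sample_scenario3(moments, bank):
    """One 600-person normative sample from the moderately biased scenario."""
    spec3 = rn.scenario_cells(3)
    return rn.draw_norm_sample(spec3, moments, bank, 100, seed=42)


@pytest.fixture(scope="session")
def raked_sample(sample_scenario3):
    sample = sample_scenario3.copy()
    w = rn.rake_weights(sample, rn.reference_targets())
    sample["weight"] = rn.standardize_weights(w)
    return sample


@pytest.fixture(scope="session")
def fitted_model(raked_sample):
    from rakenorm import norming
    ranked = norming.weighted_percentile_ranks(raked_sample)
    return norming.fit_norm_model(ranked)
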