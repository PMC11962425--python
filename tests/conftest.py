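import numpy as np
import pytest

import agesirs as ag


@pytest.fixture(scope="session")
def single_stage():
    """Scalar SIRS benchmark scenario (beta(0.1) = 0.4, R0 ~ 3.64)."""
    return ag.generate_scenario("single_stage")


@pytest.fixture(scope="session")
def three_stage():
    """Human-like three-stage scenario with slow aging."""
    return ag.generate_scenario("three_stage_human")


@pytest.fixture(scope="session")
def single_stage_eq(single_stage):
    sc = single_stage
    eq = ag.endemic_equilibrium(sc.population, sc.strain, sc.transmission)
    assert not eq.subcritical
    return eq


@pytest.fixture(scope="session")
def three_stage_eq(three_stage):
    sc = three_stage
    eq = ag.endemic_equilibrium(sc.population, sc.strain, sc.transmission)
    assert not eq.subcritical
    return eq


def random_outer_instance(rng, n):
    """A random supportable outer-product instance for property tests."""
    a = np.concatenate([rng.uniform(0.01, 0.1, n - 1), [0.0]]) if n > 1 else np.array([0.0])
    pop = ag.PopulationStructure(
        aging_rates=a,
        background_mortality=rng.uniform(0.01, 0.2, n),
        immunity_loss=rng.uniform(0.0, 0.1),
    )
    strain = ag.StrainTraits(
        recovery=rng.uniform(0.05, 1.0, n),
        disease_mortality=rng.uniform(0.0, 0.05, n),
    )
    trans = ag.TransmissionStructure(
        mode="outer_product",
        susceptibility=rng.uniform(0.1, 2.0, n),
        infectivity_weights=rng.uniform(0.1, 2.0, n),
    )
    return pop, strain, trans
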