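import numpy as np
import pytest
from hypothesis import settings

import matchbias as mb

# deterministic hypothesis runs
settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec1():
    return mb.make_scenario(1)


@pytest.fixture(scope="session")
def all_default_specs():
    return {sid: mb.make_scenario(sid) for sid in range(1, 10)}


@pytest.fixture(scope="session")
def pop_s1(spec1):
    """A moderately sized scenario-1 population shared across tests."""
    return mb.simulate_population(spec1, 40_000, seed=424242)


def random_params(scenario_id: int, rng: np.random.Generator) -> dict:
    """Random but well-behaved parameter draw for a scenario.

    Root probabilities away from the boundary, plausible negative-to-moderate
    intercepts, and coefficients of either sign.
    """
    edges = mb.SCENARIO_EDGES[scenario_id]
    nodes = {v for e in edges for v in e}
    children = {c for _, c in edges}
    roots = nodes - children
    params: dict[str, float] = {}
    root_key = {"C": "pi", "U": "rho", "E": "p_E"}
    icept_key = {"E": "alpha0", "D": "beta0", "C": "theta0"}
    for r in roots:
        params[root_key[r]] = rng.uniform(0.15, 0.85)
    for c in children:
        params[icept_key[c]] = rng.uniform(-2.5, -0.5)
    for p, c in edges:
        params[f"{p}{c}"] = rng.uniform(-1.2, 1.5)
    return params
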