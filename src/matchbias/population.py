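"""Seeded synthetic source populations by ancestral sampling.

Roots are drawn Bernoulli(p); each child is drawn Bernoulli(expit(eta)) with
eta the linear predictor from its already-sampled parents, in topological
order.  One RNG stream per population, so regeneration with the same spec,
size and seed is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .scenarios import ChildModel, RootModel, ScenarioSpec, spec_from_config, spec_to_config

__all__ = ["Population", "simulate_population", "write_population", "read_population"]


@dataclass(frozen=True)
class Population:
    """A simulated source population: one 0/1 column per scenario variable.

    The unobserved confounder U (scenario 9) is generated and stored so that
    tests can check the full joint, but samplers and estimators only ever read
    the spec's ``observed`` columns.
    """

    data: pd.DataFrame
    spec: ScenarioSpec
    seed: int
    N: int

    def observed_data(self) -> pd.DataFrame:
        """Columns visible to study designs (drops U where present)."""
        cols = [v for v in self.spec.variables if v in self.spec.observed]
        return self.data[cols]


def simulate_population(spec: ScenarioSpec, N: int, seed: int) -> Population:
    """Draw ``N`` individuals from the structural model with a seeded RNG."""
    if N < 1:
        raise ValueError(f"population size must be positive; got {N}")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for node in spec.variables:
        model = spec.node_models[node]
        if isinstance(model, RootModel):
            p = np.full(N, model.p)
        else:
            assert isinstance(model, ChildModel)
            eta = np.full(N, model.intercept)
            for parent, coef in model.coef.items():
                eta += coef * cols[parent]
            p = expit(eta)
        cols[node] = (rng.random(N) < p).astype(np.int8)
    data = pd.DataFrame(cols, columns=list(spec.variables))
    return Population(data=data, spec=spec, seed=int(seed), N=int(N))


def write_population(pop: Population, csv_path: str | Path) -> None:
    """Write the rows as headered CSV plus a JSON sidecar with provenance."""
    csv_path = Path(csv_path)
    pop.data.to_csv(csv_path, index=False)
    sidecar = {
        "spec": spec_to_config(pop.spec),
        "seed": pop.seed,
        "N": pop.N,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_population(csv_path: str | Path) -> Population:
    csv_path = Path(csv_path)
    data = pd.read_csv(csv_path).astype(np.int8)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    spec = spec_from_config(meta["spec"])
    return Population(data=data, spec=spec, seed=int(meta["seed"]), N=int(meta["N"]))
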