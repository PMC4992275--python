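"""Structural causal models for the nine matched case-control scenarios.

Each scenario is a small binary DAG over exposure E, outcome D, a covariate C
playing a different causal role per scenario (confounder, collider, mediator,
instrument, ...), and — in the instrumental-variable scenario — an unobserved
confounder U.  Every root node is Bernoulli with a fixed marginal probability;
every child node is Bernoulli with a logistic link in its parents, so each edge
coefficient is a conditional log-odds ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

__all__ = [
    "ScenarioSpec",
    "RootModel",
    "ChildModel",
    "SCENARIO_EDGES",
    "SCENARIO_ORDER",
    "make_scenario",
    "vary_edge",
    "spec_to_config",
    "spec_from_config",
]

Edge = tuple[str, str]

#: Normative edge sets of the nine causal diagrams.
SCENARIO_EDGES: dict[int, frozenset[Edge]] = {
    1: frozenset({("C", "E"), ("C", "D"), ("E", "D")}),   # C confounder
    2: frozenset({("C", "E"), ("C", "D")}),               # common cause, no E->D
    3: frozenset({("C", "D"), ("E", "D")}),               # independent cause of D
    4: frozenset({("C", "E"), ("E", "D")}),               # cause of E only
    5: frozenset({("E", "C"), ("D", "C"), ("E", "D")}),   # collider
    6: frozenset({("D", "C"), ("E", "D")}),               # effect of D
    7: frozenset({("E", "C"), ("E", "D")}),               # effect of E
    8: frozenset({("E", "C"), ("C", "D"), ("E", "D")}),   # mediator
    9: frozenset({("C", "E"), ("U", "E"), ("U", "D"), ("E", "D")}),  # instrument
}

#: Canonical topological order of the variables in each scenario.
SCENARIO_ORDER: dict[int, tuple[str, ...]] = {
    1: ("C", "E", "D"),
    2: ("C", "E", "D"),
    3: ("C", "E", "D"),
    4: ("C", "E", "D"),
    5: ("E", "D", "C"),
    6: ("E", "D", "C"),
    7: ("E", "C", "D"),
    8: ("E", "C", "D"),
    9: ("C", "U", "E", "D"),
}

# Conventional parameter names.  Roots take a marginal probability; children
# take an intercept (log-odds of the outcome when all parents are 0) plus one
# log-odds-ratio coefficient per incoming edge.
_ROOT_PARAM = {"C": "pi", "U": "rho", "E": "p_E"}
_INTERCEPT_PARAM = {"E": "alpha0", "D": "beta0", "C": "theta0"}
_EDGE_PARAM = {
    ("C", "E"): "alpha1",
    ("C", "D"): "beta1",
    ("E", "D"): "beta2",
    ("E", "C"): "theta_E",
    ("D", "C"): "theta_D",
    ("U", "E"): "lambda_E",
    ("U", "D"): "lambda_D",
}
_EDGE_BY_NAME = {f"{p}{c}": (p, c) for (p, c) in _EDGE_PARAM}
_EDGE_PARAM_INV = {v: k for k, v in _EDGE_PARAM.items()}

_LOGIT_01 = math.log(0.1 / 0.9)  # ~10% baseline prevalence

_DEFAULTS = {
    "pi": 0.5,
    "rho": 0.5,
    "p_E": 0.1,
    "alpha0": _LOGIT_01,
    "beta0": _LOGIT_01,
    "theta0": _LOGIT_01,
    # edge coefficients: moderate positive effects unless otherwise given
    "alpha1": math.log(2.0),
    "beta1": math.log(2.0),
    "beta2": math.log(2.0),
    "theta_E": math.log(2.0),
    "theta_D": math.log(2.0),
    # the unobserved confounder is made deliberately strong so that its
    # residual confounding is visible in the instrumental-variable scenario
    "lambda_E": math.log(4.0),
    "lambda_D": math.log(4.0),
}


class ScenarioError(ValueError):
    """Invalid scenario id, parameter, or edge request."""


@dataclass(frozen=True)
class RootModel:
    """Marginal Bernoulli probability of a root node."""

    p: float

    def validate(self, node: str) -> None:
        if not (0.0 < self.p < 1.0) or not math.isfinite(self.p):
            raise ScenarioError(
                f"root probability for {node} must lie strictly in (0,1); got {self.p}"
            )


@dataclass(frozen=True)
class ChildModel:
    """Logistic model of a child node: logit P(node=1) = intercept + sum(coef * parent)."""

    intercept: float
    coef: Mapping[str, float]  # parent name -> log-odds ratio

    def validate(self, node: str) -> None:
        vals = [self.intercept, *self.coef.values()]
        if not all(math.isfinite(v) for v in vals):
            raise ScenarioError(f"non-finite coefficient in model for {node}")


NodeModel = Union[RootModel, ChildModel]


@dataclass(frozen=True)
class ScenarioSpec:
    """A validated binary structural causal model for one scenario.

    Attributes
    ----------
    scenario_id : int
        Scenario number, 1-9.
    variables : tuple of str
        All variables in topological order.
    edges : frozenset of (parent, child)
        Directed edges; matches the normative table for ``scenario_id``.
    node_models : mapping
        ``RootModel`` for roots, ``ChildModel`` for children.
    observed : frozenset of str
        Variables visible to samplers and estimators (U never is).
    """

    scenario_id: int
    variables: tuple[str, ...]
    edges: frozenset[Edge]
    node_models: Mapping[str, NodeModel]
    observed: frozenset[str]

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIO_EDGES:
            raise ScenarioError(f"unknown scenario id {self.scenario_id}")
        if self.edges != SCENARIO_EDGES[self.scenario_id]:
            raise ScenarioError(
                f"edge set {sorted(self.edges)} does not match scenario "
                f"{self.scenario_id}"
            )
        if set(self.variables) != {v for e in self.edges for v in e}:
            raise ScenarioError("variable list inconsistent with edge set")
        # topological-order check
        pos = {v: i for i, v in enumerate(self.variables)}
        for parent, child in self.edges:
            if pos[parent] >= pos[child]:
                raise ScenarioError(
                    f"variables {self.variables} not topological for edge "
                    f"{parent}->{child}"
                )
        parents = self.parents
        for node in self.variables:
            model = self.node_models[node]
            if parents[node]:
                if not isinstance(model, ChildModel) or set(model.coef) != set(
                    parents[node]
                ):
                    raise ScenarioError(f"model for child node {node} malformed")
            else:
                if not isinstance(model, RootModel):
                    raise ScenarioError(f"model for root node {node} malformed")
            model.validate(node)
        if "U" in self.observed:
            raise ScenarioError("U is never observed")
        if not self.observed <= set(self.variables):
            raise ScenarioError("observed set contains unknown variables")

    @property
    def parents(self) -> dict[str, tuple[str, ...]]:
        """Parents of every node, in the canonical variable order."""
        out: dict[str, tuple[str, ...]] = {v: () for v in self.variables}
        for v in self.variables:
            out[v] = tuple(p for p in self.variables if (p, v) in self.edges)
        return out

    def coefficient(self, edge: Edge | str) -> float:
        """Log-odds-ratio coefficient attached to an edge."""
        parent, child = _normalize_edge(edge)
        if (parent, child) not in self.edges:
            raise ScenarioError(
                f"edge {parent}->{child} absent from scenario {self.scenario_id}"
            )
        model = self.node_models[child]
        assert isinstance(model, ChildModel)
        return model.coef[parent]


def _normalize_edge(edge: Edge | str) -> Edge:
    if isinstance(edge, str):
        if edge not in _EDGE_BY_NAME:
            raise ScenarioError(f"unknown edge name {edge!r}")
        return _EDGE_BY_NAME[edge]
    parent, child = edge
    return (parent, child)


def _required_params(scenario_id: int) -> set[str]:
    edges = SCENARIO_EDGES[scenario_id]
    nodes = {v for e in edges for v in e}
    children = {c for _, c in edges}
    roots = nodes - children
    req = {_ROOT_PARAM[r] for r in roots}
    req |= {_INTERCEPT_PARAM[c] for c in children}
    req |= {_EDGE_PARAM[e] for e in edges}
    return req


def make_scenario(
    scenario_id: int, params: Mapping[str, float] | None = None
) -> ScenarioSpec:
    """Build the validated structural model for one of the nine scenarios.

    Parameters
    ----------
    scenario_id : int
        Scenario number, 1-9.
    params : mapping, optional
        Parameter overrides.  Keys are either conventional names (``pi``,
        ``alpha0``, ``alpha1``, ``beta0``, ``beta1``, ``beta2``, ``theta0``,
        ``theta_E``, ``theta_D``, ``rho``, ``lambda_E``, ``lambda_D``) or edge
        names (``"CE"``, ``"CD"``, ``"ED"``, ``"EC"``, ``"DC"``, ``"UE"``,
        ``"UD"``, taken as log-odds coefficients).  Supplying a parameter the
        scenario's structure does not use is an error — e.g. scenario 2 has no
        E->D edge, so ``beta2`` is rejected rather than silently ignored.
        Unspecified parameters take the documented defaults.

    Returns
    -------
    ScenarioSpec
    """
    if scenario_id not in SCENARIO_EDGES:
        raise ScenarioError(f"unknown scenario id {scenario_id}")
    required = _required_params(scenario_id)
    values = {k: _DEFAULTS[k] for k in required}
    if params:
        for key, val in params.items():
            name = key
            if key in _EDGE_BY_NAME:  # edge-name alias for a coefficient
                name = _EDGE_PARAM[_EDGE_BY_NAME[key]]
            if name not in required:
                raise ScenarioError(
                    f"parameter {key!r} is not used by scenario {scenario_id}"
                )
            values[name] = float(val)

    edges = SCENARIO_EDGES[scenario_id]
    order = SCENARIO_ORDER[scenario_id]
    children = {c for _, c in edges}
    node_models: dict[str, NodeModel] = {}
    for node in order:
        if node in children:
            coef = {
                p: values[_EDGE_PARAM[(p, node)]]
                for p in order
                if (p, node) in edges
            }
            node_models[node] = ChildModel(values[_INTERCEPT_PARAM[node]], coef)
        else:
            node_models[node] = RootModel(values[_ROOT_PARAM[node]])
    observed = frozenset(set(order) - {"U"})
    return ScenarioSpec(scenario_id, order, edges, node_models, observed)


def vary_edge(spec: ScenarioSpec, edge: Edge | str, odds_ratio: float) -> ScenarioSpec:
    """Copy of ``spec`` with one edge's coefficient set to ``ln(odds_ratio)``.

    This is the knob the bias sweeps turn: figures index effect size by the
    odds ratio of a single edge while all other parameters stay fixed.
    """
    parent, child = _normalize_edge(edge)
    if (parent, child) not in spec.edges:
        raise ScenarioError(
            f"edge {parent}->{child} absent from scenario {spec.scenario_id}"
        )
    if not (odds_ratio > 0) or not math.isfinite(odds_ratio):
        raise ScenarioError(f"odds ratio must be positive and finite; got {odds_ratio}")
    old = spec.node_models[child]
    assert isinstance(old, ChildModel)
    coef = dict(old.coef)
    coef[parent] = math.log(odds_ratio)
    models = dict(spec.node_models)
    models[child] = ChildModel(old.intercept, coef)
    return ScenarioSpec(
        spec.scenario_id, spec.variables, spec.edges, models, spec.observed
    )


# -- config serialization -----------------------------------------------------
#
# The on-disk config speaks the language of the figures: effect sizes as odds
# ratios keyed by edge name, intercepts and roots as baseline prevalences.


def spec_to_config(spec: ScenarioSpec) -> dict:
    """Serialize a spec to a plain dict (YAML/JSON friendly)."""
    odds_ratios = {}
    for parent, child in sorted(spec.edges):
        odds_ratios[f"{parent}{child}"] = math.exp(spec.coefficient((parent, child)))
    baseline_prev = {}
    root_prob = {}
    for node in spec.variables:
        model = spec.node_models[node]
        if isinstance(model, RootModel):
            root_prob[node] = model.p
        else:
            baseline_prev[node] = 1.0 / (1.0 + math.exp(-model.intercept))
    return {
        "scenario": spec.scenario_id,
        "odds_ratios": odds_ratios,
        "baseline_prevalence": baseline_prev,
        "root_probability": root_prob,
    }


def spec_from_config(config: Mapping) -> ScenarioSpec:
    """Inverse of :func:`spec_to_config`."""
    scenario_id = int(config["scenario"])
    params: dict[str, float] = {}
    for name, or_val in config.get("odds_ratios", {}).items():
        if or_val <= 0:
            raise ScenarioError(f"odds ratio for {name} must be positive")
        params[name] = math.log(or_val)
    for node, prev in config.get("baseline_prevalence", {}).items():
        if not (0.0 < prev < 1.0):
            raise ScenarioError(f"baseline prevalence for {node} outside (0,1)")
        params[_INTERCEPT_PARAM[node]] = math.log(prev / (1.0 - prev))
    for node, p in config.get("root_probability", {}).items():
        params[_ROOT_PARAM[node]] = p
    return make_scenario(scenario_id, params)
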