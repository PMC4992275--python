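"""Exact causal truth for a scenario: enumeration, surgery, back-door.

The gold standard against which every estimator is judged is the marginal
causal log-odds ratio

    beta = logit P(D=1 | do(E=1)) - logit P(D=1 | do(E=0)),

computed exactly.  With at most four binary variables the joint factorizes
into node models and can be enumerated; an intervention do(E=e) deletes the
edges into E and fixes E=e in the truncated factorization.  The back-door
adjustment formula P(y|do(x)) = sum_z P(y|x,z) P(z) must give the same answer
for any valid adjustment set, and the package computes both routes so tests
can assert their agreement.

Note that beta is a *marginal* quantity while the adjusted regression models
estimate *conditional* log-odds ratios; odds ratios are non-collapsible, so
the two differ slightly even without confounding.  ``TrueEffect`` carries
both so that downstream summaries can report the gap.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .scenarios import ChildModel, RootModel, ScenarioSpec

__all__ = ["TrueEffect", "exact_joint", "true_causal_logodds", "backdoor_check",
           "backdoor_adjustment"]

_MAX_VARS = 5


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _node_prob1(spec: ScenarioSpec, node: str, assignment: dict[str, int]) -> float:
    """P(node = 1 | parents) under the structural model."""
    model = spec.node_models[node]
    if isinstance(model, RootModel):
        return model.p
    eta = model.intercept + sum(c * assignment[p] for p, c in model.coef.items())
    return 1.0 / (1.0 + math.exp(-eta))


def _factor(spec: ScenarioSpec, node: str, assignment: dict[str, int]) -> float:
    p1 = _node_prob1(spec, node, assignment)
    return p1 if assignment[node] == 1 else 1.0 - p1


def exact_joint(spec: ScenarioSpec) -> pd.DataFrame:
    """Exact joint distribution over all variable configurations.

    Returns a DataFrame with one 0/1 column per variable plus a ``prob``
    column; probabilities are products of the node-model factors and sum
    to 1 up to floating-point rounding.
    """
    if len(spec.variables) > _MAX_VARS:
        raise ValueError(
            f"enumeration supports at most {_MAX_VARS} variables; "
            f"got {len(spec.variables)}"
        )
    rows = []
    for values in itertools.product((0, 1), repeat=len(spec.variables)):
        assignment = dict(zip(spec.variables, values))
        prob = 1.0
        for node in spec.variables:
            prob *= _factor(spec, node, assignment)
        rows.append({**assignment, "prob": prob})
    return pd.DataFrame(rows)


def interventional_risk(spec: ScenarioSpec, e: int) -> float:
    """P(D = 1 | do(E = e)) by graph surgery on the truncated factorization."""
    if len(spec.variables) > _MAX_VARS:
        raise ValueError("too many variables for enumeration")
    others = [v for v in spec.variables if v != "E"]
    total = 0.0
    for values in itertools.product((0, 1), repeat=len(others)):
        assignment = dict(zip(others, values))
        assignment["E"] = e
        prob = 1.0
        for node in others:  # E's own factor is removed by the surgery
            prob *= _factor(spec, node, assignment)
        if assignment["D"] == 1:
            total += prob
    return total


@dataclass(frozen=True)
class TrueEffect:
    """Marginal causal effect of E on D on the log-odds-ratio scale."""

    beta: float
    p_do1: float
    p_do0: float
    scenario: ScenarioSpec

    @property
    def conditional_beta(self) -> float | None:
        """The E coefficient in D's generating model (conditional log-OR).

        ``None`` when the scenario has no E->D edge.  The difference
        ``conditional_beta - beta`` is the non-collapsibility gap.
        """
        model = self.scenario.node_models.get("D")
        if isinstance(model, ChildModel) and "E" in model.coef:
            return model.coef["E"]
        return None


def true_causal_logodds(spec: ScenarioSpec) -> TrueEffect:
    """True marginal causal log-odds ratio of E on D, by exact surgery."""
    graph = nx.DiGraph(spec.edges)
    if not nx.has_path(graph, "E", "D"):
        # no directed path: the interventional distributions coincide, and
        # beta is zero by construction rather than up to rounding
        p = interventional_risk(spec, 0)
        return TrueEffect(0.0, p, p, spec)
    p1 = interventional_risk(spec, 1)
    p0 = interventional_risk(spec, 0)
    # with every E coefficient exactly zero the truncated factorizations are
    # identical float-for-float, so the null is hit exactly, not approximately
    beta = 0.0 if p1 == p0 else _logit(p1) - _logit(p0)
    return TrueEffect(beta, p1, p0, spec)


def backdoor_check(spec: ScenarioSpec, adjust_set: set[str] | frozenset[str]) -> bool:
    """Does ``adjust_set`` satisfy the back-door criterion for (E, D)?

    Condition (i): it d-separates E from D in the graph with E's outgoing
    edges removed (blocks every path into E).  Condition (ii): it contains
    no descendant of E.
    """
    adjust_set = set(adjust_set)
    if adjust_set & {"E", "D"}:
        raise ValueError("adjustment set may not contain E or D")
    if not adjust_set <= set(spec.variables):
        raise ValueError("adjustment set contains unknown variables")
    graph = nx.DiGraph()
    graph.add_nodes_from(spec.variables)
    graph.add_edges_from(spec.edges)
    if adjust_set & nx.descendants(graph, "E"):
        return False
    backdoor_graph = graph.copy()
    backdoor_graph.remove_edges_from(list(graph.out_edges("E")))
    return nx.is_d_separator(backdoor_graph, {"E"}, {"D"}, adjust_set)


def backdoor_adjustment(
    spec: ScenarioSpec, adjust_set: set[str] | frozenset[str]
) -> TrueEffect:
    """Causal effect via the adjustment formula over ``adjust_set``.

    Computes P(D=1|do(E=e)) = sum_z P(D=1|E=e, Z=z) P(Z=z) from the exact
    joint.  Valid only for sets passing :func:`backdoor_check`; the caller
    (or a test) is expected to verify that, and agreement with surgery is
    itself one of the package's invariants.
    """
    if not backdoor_check(spec, adjust_set):
        raise ValueError(f"{sorted(adjust_set)} is not a valid back-door set")
    joint = exact_joint(spec)
    zvars = sorted(adjust_set)
    risks = []
    for e in (0, 1):
        total = 0.0
        if zvars:
            for zvals in itertools.product((0, 1), repeat=len(zvars)):
                mask = joint["E"].eq(e)
                zmask = pd.Series(True, index=joint.index)
                for var, val in zip(zvars, zvals):
                    zmask &= joint[var].eq(val)
                p_z = joint.loc[zmask, "prob"].sum()
                cell = joint.loc[mask & zmask]
                p_xz = cell["prob"].sum()
                p_y_xz = cell.loc[cell["D"].eq(1), "prob"].sum() / p_xz
                total += p_y_xz * p_z
        else:
            cell = joint.loc[joint["E"].eq(e)]
            total = cell.loc[cell["D"].eq(1), "prob"].sum() / cell["prob"].sum()
        risks.append(total)
    p0, p1 = risks
    beta = 0.0 if p1 == p0 else _logit(p1) - _logit(p0)
    return TrueEffect(beta, p1, p0, spec)
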