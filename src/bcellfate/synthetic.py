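"""Random Boolean networks and toy models with known dynamics.

These fixtures exercise every engine code path without the packaged model:
random networks (reproducible under a seed) for oracle comparisons and
cross-engine consistency checks, and a library of hand-built toys whose
synchronous dynamics are known in closed form.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .expr import And, BoolExpr, Not, Or, Var
from .network import RegulatoryNetwork

__all__ = ["RandomNetworkSpec", "generate_random_network", "toy_library"]


@dataclass(frozen=True)
class RandomNetworkSpec:
    """Specification of a random Boolean network.

    in_degree may be a single k (every ruled node draws k distinct
    regulators) or a per-node sequence. rule_style:

    - "random_and_or_not_tree": a random AND/OR tree over randomly negated
      regulator literals;
    - "random_truth_table_as_AST": a uniform random truth table over the
      regulators, materialized as a DNF expression tree so the continuous
      engine can fuzzify it uniformly.
    """

    n_nodes: int
    in_degree: int | Sequence[int] = 2
    rule_style: str = "random_and_or_not_tree"
    n_inputs: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        if not 0 <= self.n_inputs < self.n_nodes:
            raise ValueError("n_inputs must satisfy 0 <= n_inputs < n_nodes")
        ks = (
            [self.in_degree] * (self.n_nodes - self.n_inputs)
            if isinstance(self.in_degree, int)
            else list(self.in_degree)
        )
        if any(k < 1 or k > self.n_nodes for k in ks):
            raise ValueError("in_degree must lie in [1, n_nodes]")


def _random_tree(rng: np.random.Generator, literals: list[BoolExpr]) -> BoolExpr:
    """Random binary AND/OR tree over the given literals (all used once)."""
    nodes = list(literals)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        op = And if rng.random() < 0.5 else Or
        nodes.append(op(left, right))
    return nodes[0]


def _truth_table_dnf(
    rng: np.random.Generator, regulators: list[str]
) -> BoolExpr:
    """Uniform random truth table over regulators, as a DNF tree."""
    k = len(regulators)
    table = rng.integers(0, 2, size=2**k)
    minterms: list[BoolExpr] = []
    for row, value in enumerate(table):
        if not value:
            continue
        lits = [
            Var(r) if (row >> i) & 1 else Not(Var(r))
            for i, r in enumerate(regulators)
        ]
        minterms.append(lits[0] if len(lits) == 1 else And(*lits))
    if not minterms:  # constant-0 rule, expressed as a contradiction
        v = Var(regulators[0])
        return And(v, Not(v))
    return minterms[0] if len(minterms) == 1 else Or(*minterms)


def generate_random_network(spec: RandomNetworkSpec) -> RegulatoryNetwork:
    """A well-formed random network, deterministic given the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    names = [f"n{i:02d}" for i in range(spec.n_nodes)]
    inputs = names[: spec.n_inputs]
    ruled = names[spec.n_inputs :]
    if not ruled:
        raise ValueError("at least one ruled node is required")
    ks = (
        [spec.in_degree] * len(ruled)
        if isinstance(spec.in_degree, int)
        else list(spec.in_degree)
    )
    if len(ks) != len(ruled):
        raise ValueError("per-node in_degree must cover every ruled node")
    rules: dict[str, BoolExpr] = {}
    for target, k in zip(ruled, ks):
        regulators = [names[i] for i in rng.choice(spec.n_nodes, size=k, replace=False)]
        if spec.rule_style == "random_and_or_not_tree":
            literals = [
                Not(Var(r)) if rng.random() < 0.5 else Var(r) for r in regulators
            ]
            rules[target] = (
                literals[0] if len(literals) == 1 else _random_tree(rng, literals)
            )
        elif spec.rule_style == "random_truth_table_as_AST":
            rules[target] = _truth_table_dnf(rng, regulators)
        else:
            raise ValueError(f"unknown rule_style {spec.rule_style!r}")
    return RegulatoryNetwork.from_rules(
        rules, inputs=inputs, name=f"random_{spec.seed}", order=names
    )


def toy_library() -> dict[str, RegulatoryNetwork]:
    """Hand-built toy networks with documented synchronous dynamics.

    toggle : mutual inhibition A <- !B, B <- !A. Fixed points (1,0) and
        (0,1); the states (0,0) and (1,1) form a synchronous 2-cycle.
    self_activator : A <- A. Fixed points 0 and 1.
    neg_ring3 : three-node ring A <- !C, B <- A, C <- B. No fixed point;
        all 8 states fall on synchronous cycles (period 6 and 2).
    isolated_input : a single regulator-free node; it decays, so the
        all-zero state is the unique fixed point.
    """
    return {
        "toggle": RegulatoryNetwork.from_rules({"A": "!B", "B": "!A"}, name="toggle"),
        "self_activator": RegulatoryNetwork.from_rules({"A": "A"}, name="self_activator"),
        "neg_ring3": RegulatoryNetwork.from_rules(
            {"A": "!C", "B": "A", "C": "B"}, name="neg_ring3"
        ),
        "isolated_input": RegulatoryNetwork.from_rules(
            {}, inputs=["S"], name="isolated_input"
        ),
    }
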