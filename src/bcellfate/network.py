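"""Qualitative regulatory networks and the packaged B-cell model.

A :class:`RegulatoryNetwork` is a fixed, ordered set of named nodes plus one
logic rule per non-input node. Input (environment) nodes — extracellular
signals with no regulators — carry no rule; under both dynamical engines
they decay to the inactive state unless clamped.

The packaged 22-node model of terminal B-cell differentiation (Naive ->
germinal-center -> memory / plasma-cell fates) ships as a BoolNet-style text
resource and is loaded with :func:`load_bcell_network`. Its six core master
regulators are Bach2, Bcl6, Blimp1, Irf4, Pax5 and XBP1; the remaining nodes
form five signal-transduction cascades (Ag/BCR/ERK, CD40L/CD40/NF-kB,
IL-2/IL-2R/STAT5, IL-4/IL-4R/STAT6, IL-21/IL-21R/STAT3). Node names are
ASCII identifiers (NFkB for NF-kB, IL2 for IL-2, ...).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

from .expr import BoolExpr, parse_expression

__all__ = [
    "NodeCategory",
    "NodeSpec",
    "LogicRule",
    "Interaction",
    "Sign",
    "RegulatoryNetwork",
    "NetworkError",
    "AmbiguousSignError",
    "load_bcell_network",
    "extract_interactions",
    "eval_rule",
    "CORE_NODES",
    "INPUT_NODES",
]

#: Core master regulators, in the reporting order of the mutant tables.
CORE_NODES = ("Bach2", "Bcl6", "Blimp1", "Irf4", "Pax5", "XBP1")

#: Environment (input) nodes of the packaged model.
INPUT_NODES = ("Ag", "CD40L", "IL2", "IL4", "IL21")


class NetworkError(ValueError):
    """Raised for structurally invalid networks."""


class AmbiguousSignError(NetworkError):
    """A regulator occurs both negated and un-negated in one rule."""


class NodeCategory(str, enum.Enum):
    CORE = "core"
    SIGNALLING = "signalling"
    ENVIRONMENT = "environment"


@dataclass(frozen=True)
class NodeSpec:
    name: str
    is_input: bool = False
    category: NodeCategory = NodeCategory.SIGNALLING


@dataclass(frozen=True)
class LogicRule:
    target: str
    expression: BoolExpr

    @classmethod
    def from_text(cls, target: str, text: str) -> "LogicRule":
        return cls(target, parse_expression(text))


class Sign(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"

    @property
    def symbol(self) -> str:
        return "+" if self is Sign.POSITIVE else "-"


@dataclass(frozen=True)
class Interaction:
    source: str
    target: str
    sign: Sign


@dataclass
class RegulatoryNetwork:
    """Named nodes plus one logic rule per non-input node.

    Node order is fixed at construction (alphabetical, case-insensitive, by
    default) and defines the canonical bit/vector encoding of states.
    """

    nodes: tuple[NodeSpec, ...]
    rules: dict[str, LogicRule] = field(default_factory=dict)
    name: str = "network"

    def __post_init__(self):
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise NetworkError("duplicate node names")
        if any(not n.name for n in self.nodes):
            raise NetworkError("empty node name")
        for node in self.nodes:
            if node.is_input and node.name in self.rules:
                raise NetworkError(f"input node {node.name} must not have a rule")
            if not node.is_input and node.name not in self.rules:
                raise NetworkError(f"non-input node {node.name} lacks a rule")
        declared = set(names)
        for rule in self.rules.values():
            if rule.target not in declared:
                raise NetworkError(f"rule targets undeclared node {rule.target}")
            undeclared = rule.expression.variables() - declared
            if undeclared:
                raise NetworkError(
                    f"rule for {rule.target} references undeclared node(s) "
                    + ", ".join(sorted(undeclared))
                )

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_rules(
        cls,
        rules: Mapping[str, str | BoolExpr],
        inputs: Iterable[str] = (),
        name: str = "network",
        core: Iterable[str] = (),
        order: Sequence[str] | None = None,
    ) -> "RegulatoryNetwork":
        """Build a network from {target: expression} plus input node names."""
        inputs = tuple(inputs)
        core = set(core)
        parsed = {
            t: LogicRule(t, e if isinstance(e, BoolExpr) else parse_expression(e))
            for t, e in rules.items()
        }
        names = set(parsed) | set(inputs)
        for rule in parsed.values():
            names |= rule.expression.variables()
        if order is None:
            order = sorted(names, key=str.lower)
        else:
            if set(order) != names:
                raise NetworkError("explicit order must cover exactly all nodes")
        nodes = tuple(
            NodeSpec(
                n,
                is_input=n in inputs or n not in parsed,
                category=(
                    NodeCategory.CORE
                    if n in core
                    else NodeCategory.ENVIRONMENT
                    if (n in inputs or n not in parsed)
                    else NodeCategory.SIGNALLING
                ),
            )
            for n in order
        )
        return cls(nodes=nodes, rules=parsed, name=name)

    # -- basic queries -------------------------------------------------------

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    @property
    def input_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes if n.is_input)

    @property
    def ruled_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes if not n.is_input)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, name: str) -> int:
        try:
            return self.node_names.index(name)
        except ValueError:
            raise KeyError(f"unknown node {name!r}") from None

    def node(self, name: str) -> NodeSpec:
        return self.nodes[self.index(name)]

    def rule(self, name: str) -> LogicRule:
        return self.rules[name]

    def interactions(self) -> list[Interaction]:
        return extract_interactions(self)


def eval_rule(rule: LogicRule, state: Mapping[str, int]) -> int:
    """Evaluate a logic rule on a total {0,1} assignment (pure function)."""
    try:
        return rule.expression.eval(state)
    except KeyError as exc:
        raise KeyError(f"state does not assign node {exc.args[0]!r}") from None


def extract_interactions(net: RegulatoryNetwork) -> list[Interaction]:
    """Signed regulator->target edges implied by literal occurrences.

    One edge per distinct (regulator, target) pair; positive iff the
    regulator appears un-negated in the target's rule. A regulator occurring
    both negated and un-negated in the same rule has no well-defined sign
    and raises :class:`AmbiguousSignError`.
    """
    edges: list[Interaction] = []
    for target in net.ruled_names:
        rule = net.rules[target]
        polarity: dict[str, set[bool]] = {}
        order: list[str] = []
        for name, negated in rule.expression.literals():
            if name not in polarity:
                polarity[name] = set()
                order.append(name)
            polarity[name].add(negated)
        for name in order:
            signs = polarity[name]
            if len(signs) > 1:
                raise AmbiguousSignError(
                    f"{name} occurs both negated and un-negated in the rule for {target}"
                )
            sign = Sign.NEGATIVE if True in signs else Sign.POSITIVE
            edges.append(Interaction(name, target, sign))
    return edges


@lru_cache(maxsize=1)
def load_bcell_network() -> RegulatoryNetwork:
    """The packaged 22-node B-cell terminal-differentiation network.

    17 ruled nodes plus 5 environment inputs (Ag, CD40L, IL2, IL4, IL21);
    39 signed regulatory interactions follow from the rules.
    """
    from .io import parse_boolnet

    text = (
        resources.files("bcellfate").joinpath("data/bcell.bnet").read_text("utf-8")
    )
    net = parse_boolnet(text, name="bcell")
    # annotate categories on the packaged instance
    nodes = tuple(
        NodeSpec(
            n.name,
            is_input=n.is_input,
            category=(
                NodeCategory.CORE
                if n.name in CORE_NODES
                else NodeCategory.ENVIRONMENT
                if n.is_input
                else NodeCategory.SIGNALLING
            ),
        )
        for n in net.nodes
    )
    return RegulatoryNetwork(nodes=nodes, rules=net.rules, name="bcell")
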