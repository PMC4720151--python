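"""Synchronous Boolean dynamics.

All nodes update simultaneously: ruled nodes by their logic rule evaluated
on the previous state, input nodes to 0 (signals decay unless clamped), and
clamped nodes to their clamp value. The full state space of a network with
n nodes has 2^n states; exhaustive attractor enumeration is bit-parallel
(one numpy successor table plus pointer doubling) and exact.

States are encoded canonically as integers: bit i of the encoding is the
value of node i in the network's fixed node order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import RegulatoryNetwork

__all__ = [
    "BooleanState",
    "ClampSet",
    "DiscreteAttractor",
    "encode_state",
    "decode_state",
    "step",
    "find_attractor",
    "enumerate_attractors",
    "mutant_attractors",
    "StateSpaceTooLarge",
]

#: Refuse exhaustive enumeration beyond this many free bits.
MAX_ENUM_NODES = 26


class StateSpaceTooLarge(ValueError):
    """Exhaustive enumeration refused: state space exceeds the guard."""


ClampSet = Mapping[str, int]


def encode_state(net: RegulatoryNetwork, bits: Mapping[str, int]) -> int:
    """Canonical integer encoding of a total {0,1} assignment."""
    code = 0
    for i, name in enumerate(net.node_names):
        v = bits[name]
        if v not in (0, 1):
            raise ValueError(f"non-Boolean value {v!r} for node {name}")
        code |= int(v) << i
    return code


def decode_state(net: RegulatoryNetwork, code: int) -> dict[str, int]:
    return {name: (code >> i) & 1 for i, name in enumerate(net.node_names)}


@dataclass(frozen=True)
class BooleanState:
    """A total {0,1} assignment with its canonical integer encoding."""

    bits: Mapping[str, int]
    code: int

    @classmethod
    def from_bits(cls, net: RegulatoryNetwork, bits: Mapping[str, int]) -> "BooleanState":
        full = {n: int(bits.get(n, 0)) for n in net.node_names}
        return cls(bits=full, code=encode_state(net, full))

    @classmethod
    def from_code(cls, net: RegulatoryNetwork, code: int) -> "BooleanState":
        return cls(bits=decode_state(net, code), code=int(code))


@dataclass(frozen=True)
class DiscreteAttractor:
    """A fixed point (length 1) or synchronous limit cycle, with basin stats.

    ``states`` holds canonical integer encodings, rotated so the smallest
    encoding comes first; ``basin_fraction`` is relative to the enumerated
    initial-state space.
    """

    states: tuple[int, ...]
    basin_count: int = 0
    basin_fraction: float = 0.0
    label: str | None = None
    transient: int | None = None

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    @property
    def period(self) -> int:
        return len(self.states)

    def pattern(self, net: RegulatoryNetwork, nodes: Sequence[str] | None = None) -> tuple[int, ...]:
        """Bit pattern of the first cycle state over ``nodes`` (default all)."""
        bits = decode_state(net, self.states[0])
        names = nodes if nodes is not None else net.node_names
        return tuple(bits[n] for n in names)

    def with_label(self, label: str) -> "DiscreteAttractor":
        return DiscreteAttractor(self.states, self.basin_count, self.basin_fraction, label, self.transient)


def _canonical_cycle(cycle: Sequence[int]) -> tuple[int, ...]:
    k = cycle.index(min(cycle))
    return tuple(cycle[k:]) + tuple(cycle[:k])


def step(
    net: RegulatoryNetwork,
    state: Mapping[str, int] | BooleanState,
    clamps: ClampSet | None = None,
) -> dict[str, int]:
    """One synchronous update of every node."""
    bits = state.bits if isinstance(state, BooleanState) else state
    clamps = clamps or {}
    nxt: dict[str, int] = {}
    for node in net.nodes:
        if node.name in clamps:
            nxt[node.name] = int(clamps[node.name])
        elif node.is_input:
            nxt[node.name] = 0
        else:
            nxt[node.name] = net.rules[node.name].expression.eval(bits)
    return nxt


def find_attractor(
    net: RegulatoryNetwork,
    state: Mapping[str, int] | BooleanState,
    clamps: ClampSet | None = None,
) -> tuple[DiscreteAttractor, int]:
    """Iterate the synchronous map until a state recurs.

    Returns the attractor (canonically rotated cycle) and the number of
    steps before the trajectory enters it. Termination is guaranteed by the
    finite state space.
    """
    bits = dict(state.bits) if isinstance(state, BooleanState) else dict(state)
    seen: dict[int, int] = {}
    path: list[int] = []
    code = encode_state(net, bits)
    while code not in seen:
        seen[code] = len(path)
        path.append(code)
        bits = step(net, bits, clamps)
        code = encode_state(net, bits)
    entry = seen[code]
    return DiscreteAttractor(states=_canonical_cycle(path[entry:]), transient=entry), entry


# -- exhaustive enumeration -------------------------------------------------


def _successor_table(net: RegulatoryNetwork, clamps: ClampSet | None) -> np.ndarray:
    """Bit-parallel successor of every state in the full 2^n space."""
    n = net.n_nodes
    size = 1 << n
    codes = np.arange(size, dtype=np.uint32)
    env = {
        name: ((codes >> np.uint32(i)) & np.uint32(1)).astype(bool)
        for i, name in enumerate(net.node_names)
    }
    clamps = clamps or {}
    succ = np.zeros(size, dtype=np.uint32)
    for i, node in enumerate(net.nodes):
        if node.name in clamps:
            if clamps[node.name]:
                succ |= np.uint32(1 << i)
        elif not node.is_input:
            bit = net.rules[node.name].expression.eval_bits(env)
            succ |= bit.astype(np.uint32) << np.uint32(i)
        # input nodes decay to 0
    return succ


def _initial_codes(
    net: RegulatoryNetwork,
    clamps: ClampSet,
    free_nodes: Sequence[str] | None,
) -> np.ndarray:
    """Initial-state encodings: free bits vary, clamped bits fixed, rest 0."""
    if free_nodes is None:
        free = [n for n in net.node_names if n not in clamps]
    else:
        free = [n for n in free_nodes if n not in clamps]
    k = len(free)
    if k > MAX_ENUM_NODES:
        raise StateSpaceTooLarge(
            f"{k} free nodes exceed the exhaustive-enumeration guard ({MAX_ENUM_NODES})"
        )
    base = 0
    for name, value in clamps.items():
        base |= int(bool(value)) << net.index(name)
    counters = np.arange(1 << k, dtype=np.uint64)
    codes = np.full(1 << k, base, dtype=np.uint32)
    for j, name in enumerate(free):
        codes |= ((counters >> np.uint64(j)) & np.uint64(1)).astype(np.uint32) << np.uint32(
            net.index(name)
        )
    return codes


def enumerate_attractors(
    net: RegulatoryNetwork,
    clamps: ClampSet | None = None,
    free_nodes: Sequence[str] | None = None,
) -> list[DiscreteAttractor]:
    """All attractors and exact basin sizes over every initial state.

    By default every non-clamped node's initial value varies (2^free
    states). ``free_nodes`` restricts the enumerated initial subspace (the
    remaining nodes start at 0 / their clamp value); the reachable attractor
    set and basin fractions are then relative to that subspace.

    Complexity is linear in the number of enumerated states: one vectorized
    successor table over the full space plus log2(space) pointer-doubling
    gathers.
    """
    clamps = dict(clamps or {})
    n = net.n_nodes
    if n > MAX_ENUM_NODES:
        raise StateSpaceTooLarge(
            f"{n} nodes exceed the exhaustive-enumeration guard ({MAX_ENUM_NODES})"
        )
    succ = _successor_table(net, clamps)
    # Pointer doubling: after ceil(log2(2^n)) squarings every state has been
    # advanced 2^n steps, which exceeds any transient + period.
    terminal = succ.copy()
    for _ in range(n):
        terminal = terminal[terminal]
    init = _initial_codes(net, clamps, free_nodes)
    landed = terminal[init]

    uniq, counts = np.unique(landed, return_counts=True)
    # Map each landing state (inside its cycle) to a canonical attractor.
    cycle_of: dict[int, tuple[int, ...]] = {}
    attractors: dict[tuple[int, ...], int] = {}
    for u in uniq.tolist():
        if u in cycle_of:
            continue
        cyc = [u]
        s = int(succ[u])
        while s != u:
            cyc.append(s)
            s = int(succ[s])
        canon = _canonical_cycle(cyc)
        for c in cyc:
            cycle_of[c] = canon
        attractors.setdefault(canon, 0)
    for u, c in zip(uniq.tolist(), counts.tolist()):
        attractors[cycle_of[u]] += c

    total = len(init)
    result = [
        DiscreteAttractor(states=canon, basin_count=cnt, basin_fraction=cnt / total)
        for canon, cnt in attractors.items()
    ]
    result.sort(key=lambda a: (-a.basin_count, a.states))
    return result


def mutant_attractors(
    net: RegulatoryNetwork, node: str, fixed_value: int
) -> list[DiscreteAttractor]:
    """Attractors of the single loss- (0) or gain-of-function (1) mutant."""
    net.index(node)  # raises KeyError for unknown nodes
    return enumerate_attractors(net, clamps={node: int(fixed_value)})
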