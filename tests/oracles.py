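"""Independent oracles for the test suite.

Everything here is deliberately hand-coded and naive: the 17 model rules
as plain Python lambdas (transcribed independently of the packaged rule
file), a per-state brute-force synchronous iterator, and the sigmoid in
its textbook (overflow-prone) form. None of it shares code with the
package's bit-parallel or vectorized paths.
"""

import math
from itertools import product

# The logic rules as plain functions of a state dict. Independent
# transcription used to truth-table-check the packaged expression trees.
HAND_RULES = {
    "AID": lambda s: (s["STAT6"] or (s["NFkB"] and s["Pax5"])) and not s["Blimp1"],
    "Bach2": lambda s: s["Pax5"] and not s["Blimp1"],
    "Bcl6": lambda s: (s["STAT5"] or s["STAT6"] or (s["Pax5"] and s["Bcl6"]))
    and not (s["Blimp1"] or s["Irf4"] or s["ERK"]),
    "BCR": lambda s: s["Ag"],
    "Blimp1": lambda s: (s["ERK"] or s["STAT3"])
    or (s["Irf4"] and not (s["Pax5"] or s["Bcl6"] or s["Bach2"])),
    "CD40": lambda s: s["CD40L"],
    "ERK": lambda s: s["BCR"],
    "IL2R": lambda s: s["IL2"],
    "IL4R": lambda s: s["IL4"],
    "IL21R": lambda s: s["IL21"],
    "Irf4": lambda s: (s["NFkB"] or s["Irf4"]) or (s["Blimp1"] and not s["Bcl6"]),
    "NFkB": lambda s: s["CD40"],
    "Pax5": lambda s: (s["Pax5"] or not s["Irf4"]) and not (s["Blimp1"] or s["ERK"]),
    "STAT3": lambda s: s["IL21R"],
    "STAT5": lambda s: s["IL2R"],
    "STAT6": lambda s: s["IL4R"],
    "XBP1": lambda s: s["Blimp1"] and not s["Pax5"],
}

BCELL_INPUTS = ("Ag", "CD40L", "IL2", "IL4", "IL21")


def naive_step(net, bits, clamps=None):
    """Synchronous update semantics, re-derived: per-node scalar evaluation."""
    clamps = clamps or {}
    out = {}
    for node in net.nodes:
        if node.name in clamps:
            out[node.name] = int(clamps[node.name])
        elif node.is_input:
            out[node.name] = 0
        else:
            out[node.name] = int(net.rules[node.name].expression.eval(bits))
    return out


def naive_attractors(net, clamps=None):
    """Per-state loop over the whole state space with dict memoization.

    Returns {canonical_cycle: basin_count} where a canonical cycle is the
    tuple of state tuples rotated to start at its smallest element. State
    tuples follow the network's node order.
    """
    names = net.node_names
    clamps = clamps or {}
    memo = {}
    basins = {}
    starts = []
    free = [n for n in names if n not in clamps]
    for values in product((0, 1), repeat=len(free)):
        bits = {n: int(clamps.get(n, 0)) for n in names}
        bits.update(zip(free, values))
        starts.append(bits)
    for bits in starts:
        path = []
        key = tuple(bits[n] for n in names)
        while key not in memo:
            path.append(key)
            memo[key] = None  # mark in-progress
            bits = naive_step(net, dict(zip(names, key)), clamps)
            key = tuple(bits[n] for n in names)
        if memo[key] is None:
            # found a new cycle within the current path
            idx = path.index(key)
            cycle = tuple(path[idx:])
            k = cycle.index(min(cycle))
            canonical = cycle[k:] + cycle[:k]
            for st in path[idx:]:
                memo[st] = canonical
            for st in path[:idx]:
                memo[st] = canonical
        else:
            canonical = memo[key]
            for st in path:
                memo[st] = canonical
        start_key = path[0] if path else key
        basins[memo[start_key]] = basins.get(memo[start_key], 0) + 1
    return basins


def textbook_sigmoid(w, h):
    """Eq.-style sigmoid, straightforward evaluation (overflows for huge h)."""
    num = -math.exp(0.5 * h) + math.exp(-h * (w - 0.5))
    den = (1.0 - math.exp(0.5 * h)) * (1.0 + math.exp(-h * (w - 0.5)))
    return num / den
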