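"""Cell-fate analysis: labels, pulses, fate maps and the mutant report.

Cell types are identified by the stationary pattern of the six-node core
module [Bach2, Bcl6, Blimp1, Irf4, Pax5, XBP1]:

    Naive [1,0,0,0,1,0]   GC [1,1,0,0,1,0]   Mem [1,0,0,1,1,0]
    PC    [0,0,1,1,0,1]

plus three intermediate continuous-only states with half-activated Bcl6
and/or Irf4. Under a clamp, an attractor whose free core bits match a
signature but whose clamped bit is forced away from it is labelled
"<type>-like" (e.g. the Bach2-null state [0,0,0,0,1,0] is Naive-like).

Differentiation is driven by transient signal pulses: a node is pinned at
a level for a window (its rate forced to 0), then released. Fate maps are
built from single-node perturbations of each attractor: in the discrete
model a one-bit flip followed by free synchronous evolution, and in the
continuous model an instantaneous reset of one node to 0, 0.5 or 1
followed by free relaxation — the exact continuous analogue of the bit
flip. An edge (source -> destination) is recorded whenever the perturbed
trajectory converges to a different attractor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .boolean import (
    BooleanState,
    DiscreteAttractor,
    decode_state,
    encode_state,
    enumerate_attractors,
    find_attractor,
)
from .continuous import (
    ContinuousAttractor,
    ContinuousParams,
    ContinuousSystem,
    perturbation_search,
    sample_attractors,
)
from .network import CORE_NODES, RegulatoryNetwork

__all__ = [
    "CellTypeSignature",
    "DEFAULT_SIGNATURES",
    "EXTENDED_SIGNATURES",
    "label_attractor",
    "PulseEvent",
    "Trajectory",
    "simulate_pulses",
    "FateMapEdge",
    "FateMap",
    "build_fate_map",
    "mutant_report",
    "label_all",
]


@dataclass(frozen=True)
class CellTypeSignature:
    """A core-module activation pattern defining a cell-type label."""

    label: str
    pattern: tuple[float, ...]
    nodes: tuple[str, ...] = CORE_NODES
    tolerance: float = 0.05


#: The four experimentally characterized cell types.
DEFAULT_SIGNATURES = (
    CellTypeSignature("Naive", (1, 0, 0, 0, 1, 0)),
    CellTypeSignature("GC", (1, 1, 0, 0, 1, 0)),
    CellTypeSignature("Mem", (1, 0, 0, 1, 1, 0)),
    CellTypeSignature("PC", (0, 0, 1, 1, 0, 1)),
)

#: Adds the three intermediate (half-activation) states of the continuous
#: model, in the naming of the attractor tables.
EXTENDED_SIGNATURES = DEFAULT_SIGNATURES + (
    CellTypeSignature("New1", (1, 0.5, 0, 0, 1, 0)),
    CellTypeSignature("New2", (1, 0, 0, 0.5, 1, 0)),
    CellTypeSignature("New3", (1, 0.5, 0, 0.5, 1, 0)),
)


def _core_levels(
    attractor: DiscreteAttractor | ContinuousAttractor | Mapping[str, float],
    net: RegulatoryNetwork | None,
    nodes: Sequence[str],
) -> tuple[float, ...]:
    if isinstance(attractor, DiscreteAttractor):
        if net is None:
            raise ValueError("a network is required to decode a discrete attractor")
        return tuple(float(v) for v in attractor.pattern(net, nodes))
    if isinstance(attractor, ContinuousAttractor):
        return tuple(float(attractor.levels[n]) for n in nodes)
    return tuple(float(attractor[n]) for n in nodes)


def label_attractor(
    attractor: DiscreteAttractor | ContinuousAttractor | Mapping[str, float],
    signatures: Sequence[CellTypeSignature] = DEFAULT_SIGNATURES,
    net: RegulatoryNetwork | None = None,
    clamped: Iterable[str] = (),
) -> str:
    """Cell-type label of an attractor, or "Other".

    Signatures are matched on their core nodes within tolerance. An exact
    (all-bits) match wins; otherwise, if every *free* core bit matches but
    a clamped bit is forced away from the signature, the label gains a
    "-like" suffix. Signatures are mutually exclusive, so multiple exact
    matches indicate an inconsistent signature set and raise ValueError.
    """
    clamped = set(clamped)
    exact: list[str] = []
    like: list[str] = []
    for sig in signatures:
        levels = _core_levels(attractor, net, sig.nodes)
        devs = [abs(l - p) for l, p in zip(levels, sig.pattern)]
        if max(devs) <= sig.tolerance:
            exact.append(sig.label)
            continue
        free_ok = all(
            d <= sig.tolerance
            for d, n in zip(devs, sig.nodes)
            if n not in clamped
        )
        if free_ok and any(n in clamped for n in sig.nodes):
            like.append(sig.label)
    if len(exact) > 1:
        raise ValueError(f"ambiguous label: {exact}")
    if exact:
        return exact[0]
    if len(like) == 1:
        return f"{like[0]}-like"
    return "Other"


def label_all(
    attractors: Sequence[DiscreteAttractor | ContinuousAttractor],
    signatures: Sequence[CellTypeSignature] = DEFAULT_SIGNATURES,
    net: RegulatoryNetwork | None = None,
    clamped: Iterable[str] = (),
):
    """Label every attractor in a list (returns relabelled copies)."""
    return [
        a.with_label(label_attractor(a, signatures, net=net, clamped=clamped))
        for a in attractors
    ]


# -- pulses ------------------------------------------------------------------


@dataclass(frozen=True)
class PulseEvent:
    """A transient clamp: ``node`` pinned at ``level`` on [t_on, t_on+duration)."""

    node: str
    level: float = 1.0
    t_on: float = 25.0
    duration: float = 2.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")


@dataclass
class Trajectory:
    """Time course of all node levels under a pulse protocol."""

    times: np.ndarray
    states: list[dict[str, float]]
    events: tuple[PulseEvent, ...] = ()

    def level(self, node: str) -> np.ndarray:
        return np.array([s[node] for s in self.states])


def simulate_pulses(
    net: RegulatoryNetwork,
    params: ContinuousParams | None = None,
    start: ContinuousAttractor | Mapping[str, float] | None = None,
    pulses: Sequence[PulseEvent] = (),
    signatures: Sequence[CellTypeSignature] = EXTENDED_SIGNATURES,
    relax_time: float = 60.0,
    dt_report: float = 0.5,
    clamps: Mapping[str, float] | None = None,
) -> tuple[Trajectory, ContinuousAttractor, str]:
    """Drive the continuous system with a sequence of signal pulses.

    The trajectory is integrated segment by segment — free dynamics up to
    each pulse onset, pinned dynamics during the pulse — and finally
    relaxed for ``relax_time`` plus convergence. Returns the trajectory on
    a fixed reporting grid, the final converged attractor (flagged if not
    converged) and its cell-type label.

    Pulses must not overlap in time.
    """
    params = params or ContinuousParams()
    sys = ContinuousSystem(net, params, clamps)
    if start is None:
        start = {n: 0.0 for n in net.node_names}
    levels = start.levels if isinstance(start, ContinuousAttractor) else start
    x = np.array([float(levels.get(n, 0.0)) for n in net.node_names])

    pulses = tuple(sorted(pulses, key=lambda p: p.t_on))
    for a, b in zip(pulses, pulses[1:]):
        if a.t_on + a.duration > b.t_on:
            raise ValueError(f"overlapping pulses: {a} and {b}")

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    t0 = 0.0

    def _segment(duration: float, pinned: Sequence[str]):
        nonlocal x, t0
        if duration <= 0:
            return
        n_pts = max(2, int(round(duration / dt_report)) + 1)
        grid = np.linspace(0.0, duration, n_pts)
        tt, xs = sys.integrate(x, duration, pinned_nodes=pinned, t_eval=grid)
        times.append(tt + t0)
        states.append(xs)
        x = xs[-1]
        t0 += duration

    for pulse in pulses:
        _segment(pulse.t_on - t0, ())
        x[net.index(pulse.node)] = pulse.level
        _segment(pulse.duration, (pulse.node,))
    _segment(relax_time, ())
    final = sys.relax(x)

    all_t = np.concatenate(times) if times else np.array([0.0])
    all_x = np.vstack(states) if states else x[None, :]
    traj = Trajectory(
        times=all_t,
        states=[dict(zip(net.node_names, map(float, row))) for row in all_x],
        events=pulses,
    )
    label = label_attractor(final, signatures)
    return traj, final, label


# -- fate maps ---------------------------------------------------------------


@dataclass(frozen=True)
class FateMapEdge:
    source: str
    destination: str
    node: str
    level: float

    @property
    def perturbation(self) -> str:
        symbol = {0.0: "-", 0.5: "int", 1.0: "+"}.get(self.level, str(self.level))
        return f"{self.node}{symbol}"


@dataclass
class FateMap:
    """Directed graph over attractors; edges are fate-changing perturbations."""

    vertices: dict[str, object] = field(default_factory=dict)
    edges: list[FateMapEdge] = field(default_factory=list)
    mode: str = "continuous"

    def successors(self, label: str) -> set[str]:
        return {e.destination for e in self.edges if e.source == label}

    def out_degree(self, label: str) -> int:
        return sum(1 for e in self.edges if e.source == label)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph(mode=self.mode)
        for v in self.vertices:
            g.add_node(v)
        for e in self.edges:
            if g.has_edge(e.source, e.destination):
                g[e.source][e.destination]["perturbations"] += f",{e.perturbation}"
            else:
                g.add_edge(e.source, e.destination, perturbations=e.perturbation)
        return g


def _unique_names(labels: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for lab in labels:
        if lab in seen:
            seen[lab] += 1
            out.append(f"{lab}#{seen[lab]}")
        else:
            seen[lab] = 1
            out.append(lab)
    return out


def build_fate_map(
    net: RegulatoryNetwork,
    params: ContinuousParams | None = None,
    mode: str = "continuous",
    levels: Sequence[float] | None = None,
    duration: float = 0.0,
    attractors: Sequence[DiscreteAttractor | ContinuousAttractor] | None = None,
    signatures: Sequence[CellTypeSignature] = EXTENDED_SIGNATURES,
    clamps: Mapping[str, float] | None = None,
    n_runs: int = 1000,
    seed: int = 0,
) -> FateMap:
    """Single-node-perturbation fate map of the wild-type (or clamped) model.

    discrete mode: every attractor state x node -> bit flip, then free
    synchronous evolution. continuous mode: every attractor x node x level
    in {0, 0.5, 1} -> instantaneous reset (or a held clamp when
    ``duration`` > 0), then relaxation.
    """
    params = params or ContinuousParams()
    if mode == "discrete":
        if attractors is None:
            attractors = enumerate_attractors(net, clamps=clamps)
        att_list = list(attractors)
        labels = _unique_names(
            [label_attractor(a, signatures, net=net, clamped=clamps or ()) for a in att_list]
        )
        key_of = {a.states: lab for a, lab in zip(att_list, labels)}
        fmap = FateMap(vertices=dict(zip(labels, att_list)), mode="discrete")
        flip_levels = levels if levels is not None else (0, 1)
        for att, lab in zip(att_list, labels):
            for state_code in att.states:
                bits = decode_state(net, state_code)
                for node in net.node_names:
                    if clamps and node in clamps:
                        continue
                    for lvl in flip_levels:
                        if bits[node] == lvl:
                            continue
                        perturbed = dict(bits)
                        perturbed[node] = int(lvl)
                        dest, _ = find_attractor(net, perturbed, clamps=clamps)
                        dest_lab = key_of.get(dest.states)
                        if dest_lab is None:
                            dest_lab = _unique_names(list(fmap.vertices) + ["Other"])[-1]
                            fmap.vertices[dest_lab] = dest
                            key_of[dest.states] = dest_lab
                        if dest_lab != lab:
                            fmap.edges.append(FateMapEdge(lab, dest_lab, node, float(lvl)))
        fmap.edges = sorted(set(fmap.edges), key=lambda e: (e.source, e.node, e.level))
        return fmap

    if mode != "continuous":
        raise ValueError("mode must be 'discrete' or 'continuous'")

    if attractors is None:
        base = sample_attractors(net, params, n_runs=n_runs, seed=seed, clamps=clamps)
        attractors, _ = perturbation_search(
            net, params, base, duration=duration, clamps=clamps
        )
    att_list = list(attractors)
    _, records = perturbation_search(
        net,
        params,
        att_list,
        levels=levels if levels is not None else (0.0, 0.5, 1.0),
        duration=duration,
        clamps=clamps,
        closure=False,
    )
    dec = params.merge_decimals
    labels = _unique_names(
        [label_attractor(a, signatures, clamped=clamps or ()) for a in att_list]
    )
    key_of = {a.key(dec): lab for a, lab in zip(att_list, labels)}
    fmap = FateMap(vertices=dict(zip(labels, att_list)), mode="continuous")
    for rec in records:
        src = key_of[rec.source]
        dst = key_of.get(rec.destination)
        if dst is None:
            # a state outside the supplied attractor set: name it Other#k
            dst = _unique_names(list(fmap.vertices) + ["Other"])[-1]
            key_of[rec.destination] = dst
            fmap.vertices[dst] = rec.destination
        if dst != src:
            fmap.edges.append(FateMapEdge(src, dst, rec.node, rec.level))
    fmap.edges = sorted(set(fmap.edges), key=lambda e: (e.source, e.node, e.level))
    return fmap


# -- mutant report -----------------------------------------------------------


def _effect_class(labels: Sequence[str], wt_labels: set[str]) -> str:
    """Coarse Table-5-style classification of a mutant's attractor set."""
    labs = set(labels)
    plain = {l for l in labs if not l.endswith("-like") and l != "Other"}
    likes = {l[:-5] for l in labs if l.endswith("-like")}
    lost = wt_labels - plain - likes
    parts = []
    if len(labs) == 1:
        parts.append(f"Only the {next(iter(labs))} attractor is found")
    elif lost:
        parts.append("Loss of " + "/".join(sorted(lost)) + " attractor(s)")
    if likes:
        parts.append("Replaced " + "/".join(sorted(likes)) + " by -like attractor(s)")
    if "Other" in labs:
        parts.append("Atypical attractor found")
    if not parts:
        parts.append("All wild-type attractors retained")
    return "; ".join(parts)


def mutant_report(
    net: RegulatoryNetwork,
    params: ContinuousParams | None = None,
    nodes: Sequence[str] | None = None,
    values: Sequence[int] = (0, 1),
    engines: Sequence[str] = ("discrete",),
    signatures: Sequence[CellTypeSignature] = DEFAULT_SIGNATURES,
    n_runs: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attractors of every single-node clamp, labelled and classified.

    Loss-of-function = node fixed at 0, gain-of-function = node fixed at 1;
    signalling-pathway clamps model sustained external signals. The
    discrete engine enumerates exhaustively; the continuous engine samples
    ``n_runs`` random initial states per mutant.

    Returns (detail, summary): one row per (node, value, engine,
    attractor), and one row per (node, value, engine) with the effect
    class relative to the wild type.
    """
    params = params or ContinuousParams()
    nodes = list(nodes if nodes is not None else net.node_names)
    wt_labels = {s.label for s in DEFAULT_SIGNATURES}
    detail_rows = []
    summary_rows = []
    for engine in engines:
        for node in nodes:
            for value in values:
                clamp = {node: value}
                if engine == "discrete":
                    atts = label_all(
                        enumerate_attractors(net, clamps=clamp),
                        signatures,
                        net=net,
                        clamped=clamp,
                    )
                    patterns = [a.pattern(net, CORE_NODES) for a in atts]
                    basins = [a.basin_fraction for a in atts]
                elif engine == "continuous":
                    atts = label_all(
                        sample_attractors(
                            net, params, n_runs=n_runs, seed=seed, clamps=clamp
                        ),
                        signatures,
                        clamped=clamp,
                    )
                    patterns = [a.pattern(CORE_NODES) for a in atts]
                    total = sum(a.support_count for a in atts)
                    basins = [a.support_count / total for a in atts]
                else:
                    raise ValueError(f"unknown engine {engine!r}")
                labels = [a.label for a in atts]
                for a, pat, frac in zip(atts, patterns, basins):
                    detail_rows.append(
                        {
                            "node": node,
                            "value": value,
                            "engine": engine,
                            "label": a.label,
                            "core_pattern": str([_fmt(v) for v in pat]),
                            "basin_fraction": frac,
                        }
                    )
                summary_rows.append(
                    {
                        "node": node,
                        "value": value,
                        "engine": engine,
                        "n_attractors": len(atts),
                        "labels": "|".join(sorted(labels)),
                        "effect": _effect_class(labels, wt_labels),
                    }
                )
    return pd.DataFrame(detail_rows), pd.DataFrame(summary_rows)


def _fmt(v: float):
    return int(v) if float(v).is_integer() else float(v)
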