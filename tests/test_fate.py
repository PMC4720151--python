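"""Labelling, pulse-driven differentiation, fate maps, mutant report."""

import numpy as np
import pytest

from bcellfate import (
    CORE_NODES,
    PulseEvent,
    build_fate_map,
    label_attractor,
    mutant_report,
    simulate_pulses,
    toy_library,
)
from bcellfate.continuous import perturbation_search, sample_attractors
from bcellfate.fate import DEFAULT_SIGNATURES, EXTENDED_SIGNATURES, CellTypeSignature

from .conftest import CORE_PATTERNS


def _core(levels):
    return dict(zip(CORE_NODES, levels))


class TestLabelling:
    @pytest.mark.parametrize("label,pattern", sorted(CORE_PATTERNS.items()))
    def test_wildtype_signatures(self, label, pattern):
        assert label_attractor(_core(pattern)) == label

    def test_bach2_null_naive_like(self):
        assert (
            label_attractor(_core((0, 0, 0, 0, 1, 0)), clamped=["Bach2"]) == "Naive-like"
        )

    def test_clamped_bit_matching_signature_keeps_plain_label(self):
        # PC has Bach2=0, so a Bach2-null PC is labelled PC, not PC-like
        assert label_attractor(_core((0, 0, 1, 1, 0, 1)), clamped=["Bach2"]) == "PC"

    def test_exact_match_beats_like_match(self):
        # under a Bcl6 clamp at 1, the GC pattern matches GC exactly and
        # Naive only modulo the clamped bit: GC wins
        assert label_attractor(_core((1, 1, 0, 0, 1, 0)), clamped=["Bcl6"]) == "GC"

    def test_unmatched_is_other(self):
        assert label_attractor(_core((0, 0, 0, 1, 0, 0))) == "Other"

    def test_intermediate_signatures(self):
        assert label_attractor(_core((1, 0.5, 0, 0, 1, 0)), EXTENDED_SIGNATURES) == "New1"
        assert label_attractor(_core((1, 0.5, 0, 0.5, 1, 0)), EXTENDED_SIGNATURES) == "New3"

    def test_overlapping_signatures_raise(self):
        sigs = (
            CellTypeSignature("X", (1, 0, 0, 0, 1, 0)),
            CellTypeSignature("Y", (1, 0, 0, 0, 1, 0)),
        )
        with pytest.raises(ValueError, match="ambiguous"):
            label_attractor(_core((1, 0, 0, 0, 1, 0)), sigs)


class TestPulses:
    def test_il4_pulse_moves_naive_to_gc(self, bcell, params):
        traj, final, label = simulate_pulses(
            bcell,
            params,
            start=_start(bcell, CORE_PATTERNS["Naive"]),
            pulses=[PulseEvent("IL4", 1.0, t_on=25.0, duration=2.0)],
        )
        assert label == "GC"
        assert final.converged
        # the pulse is visible in the trajectory
        assert traj.level("IL4").max() > 0.99
        assert traj.level("Bcl6")[-1] > 0.99

    def test_full_differentiation_chain(self, bcell, params):
        """Sequential IL-4, CD40L and Ag pulses drive the Naive cell
        through the GC and Mem programs into the plasma-cell state."""
        traj, final, label = simulate_pulses(
            bcell,
            params,
            start=_start(bcell, CORE_PATTERNS["Naive"]),
            pulses=[
                PulseEvent("IL4", 1.0, t_on=25.0, duration=2.0),
                PulseEvent("CD40L", 1.0, t_on=55.0, duration=2.0),
                PulseEvent("Ag", 1.0, t_on=75.0, duration=2.0),
            ],
        )
        assert label == "PC"
        assert final.converged
        # the intermediate programs appear in order
        bcl6, irf4, blimp1 = traj.level("Bcl6"), traj.level("Irf4"), traj.level("Blimp1")
        t = traj.times
        assert bcl6[(t > 30) & (t < 55)].max() > 0.9  # GC phase
        assert irf4[(t > 60) & (t < 75)].max() > 0.9  # Mem phase
        assert blimp1[-1] > 0.99  # PC endpoint

    def test_noop_pulse_returns_to_start(self, bcell, params):
        # pulsing IL4 at the level it already has leaves the Naive state
        traj, final, label = simulate_pulses(
            bcell,
            params,
            start=_start(bcell, CORE_PATTERNS["Naive"]),
            pulses=[PulseEvent("IL4", 0.0, t_on=5.0, duration=2.0)],
            relax_time=20.0,
        )
        assert label == "Naive"

    def test_overlapping_pulses_rejected(self, bcell, params):
        with pytest.raises(ValueError, match="overlap"):
            simulate_pulses(
                bcell,
                params,
                start=_start(bcell, CORE_PATTERNS["Naive"]),
                pulses=[PulseEvent("IL4", 1.0, 10.0, 5.0), PulseEvent("Ag", 1.0, 12.0, 5.0)],
            )

    def test_zero_duration_pulse_rejected(self):
        with pytest.raises(ValueError):
            PulseEvent("IL4", 1.0, 10.0, 0.0)


class TestDiscreteFateMap:
    def test_toggle_flip_switches_fixed_points(self):
        toggle = toy_library()["toggle"]
        fmap = build_fate_map(toggle, mode="discrete", signatures=())
        # flipping the active node moves (1,0) <-> (0,1)
        labels = set(fmap.vertices)
        assert len(labels) == 3  # two fixed points + the 2-cycle
        assert any(e.source != e.destination for e in fmap.edges)

    def test_bcell_signal_flips_drive_differentiation(self, bcell, params):
        fmap = build_fate_map(bcell, params, mode="discrete")
        assert set(fmap.vertices) == {"Naive", "GC", "Mem", "PC"}
        assert ("GC", "IL4") in {(e.destination, e.node) for e in fmap.edges if e.source == "Naive"}
        assert "Mem" in fmap.successors("GC")
        assert "PC" in fmap.successors("Mem")
        assert fmap.out_degree("PC") == 0  # plasma cells are terminal

    def test_edges_resimulate_to_same_destination(self, bcell, params):
        from bcellfate import find_attractor
        from bcellfate.boolean import decode_state

        fmap = build_fate_map(bcell, params, mode="discrete")
        by_label = fmap.vertices
        for e in list(fmap.edges)[:20]:
            src = by_label[e.source]
            bits = decode_state(bcell, src.states[0])
            bits[e.node] = int(e.level)
            dest, _ = find_attractor(bcell, bits)
            assert dest.states == by_label[e.destination].states


@pytest.fixture(scope="module")
def wt_continuous_attractors(bcell, params):
    base = sample_attractors(bcell, params, n_runs=200, seed=3)
    atts, _ = perturbation_search(bcell, params, base)
    return atts


class TestContinuousFateMap:
    def test_seven_attractors_and_absorbing_pc(self, bcell, params, wt_continuous_attractors):
        assert len(wt_continuous_attractors) == 7
        fmap = build_fate_map(
            bcell, params, mode="continuous", attractors=wt_continuous_attractors
        )
        named = {"Naive", "GC", "Mem", "PC", "New1", "New2", "New3"}
        assert named <= set(fmap.vertices)
        # perturbing the intermediate states can expose further saddle
        # equilibria; any such destination is an unnamed Other vertex
        assert all(v in named or v.startswith("Other") for v in fmap.vertices)
        assert fmap.out_degree("PC") == 0
        assert "Mem" in fmap.successors("GC")  # Irf4 activation exits the GC

    def test_graph_export_roundtrip(self, bcell, params, wt_continuous_attractors, tmp_path):
        import networkx as nx

        from bcellfate.io import write_fate_map_dot, write_fate_map_graphml

        fmap = build_fate_map(
            bcell, params, mode="continuous", attractors=wt_continuous_attractors
        )
        write_fate_map_graphml(fmap, tmp_path / "fm.graphml")
        g = nx.read_graphml(tmp_path / "fm.graphml")
        assert set(g.nodes) == set(fmap.vertices)
        write_fate_map_dot(fmap, tmp_path / "fm.dot")
        text = (tmp_path / "fm.dot").read_text()
        assert "digraph" in text and "PC" in text


class TestMutantReport:
    def test_discrete_subset_structure(self, bcell, params):
        detail, summary = mutant_report(
            bcell, params, nodes=["Blimp1", "Irf4"], engines=("discrete",)
        )
        assert set(summary["node"]) == {"Blimp1", "Irf4"}
        assert set(summary["value"]) == {0, 1}
        blimp1_gof = summary[(summary.node == "Blimp1") & (summary.value == 1)]
        assert blimp1_gof["effect"].iloc[0].startswith("Only the PC attractor")
        irf4_lof = detail[(detail.node == "Irf4") & (detail.value == 0)]
        assert set(irf4_lof["label"]) == {"Naive", "GC"}

    def test_continuous_engine_agrees_on_attractor_labels(self, bcell, params):
        detail, _ = mutant_report(
            bcell,
            params,
            nodes=["Blimp1"],
            values=(1,),
            engines=("discrete", "continuous"),
            n_runs=40,
            seed=9,
        )
        by_engine = {
            eng: set(rows["label"]) for eng, rows in detail.groupby("engine")
        }
        assert by_engine["discrete"] == by_engine["continuous"] == {"PC"}


def _start(net, core_pattern):
    levels = {n: 0.0 for n in net.node_names}
    levels.update({k: float(v) for k, v in zip(CORE_NODES, core_pattern)})
    return levels
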