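"""Synchronous Boolean engine: stepping, attractors, basins, clamps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcellfate import (
    BooleanState,
    RegulatoryNetwork,
    enumerate_attractors,
    find_attractor,
    mutant_attractors,
    step,
    toy_library,
)
from bcellfate.boolean import StateSpaceTooLarge, decode_state, encode_state
from bcellfate.synthetic import RandomNetworkSpec, generate_random_network

from .conftest import CORE_PATTERNS
from .oracles import naive_attractors, naive_step


def _state(net, **on):
    bits = {n: 0 for n in net.node_names}
    bits.update(on)
    return bits


def _canon(cycle):
    """Rotation-invariant form of a cycle of state tuples."""
    k = cycle.index(min(cycle))
    return tuple(cycle[k:]) + tuple(cycle[:k])


def _engine_basins(net, atts):
    return {
        _canon([tuple(decode_state(net, c)[n] for n in net.node_names) for c in a.states]): a.basin_count
        for a in atts
    }


class TestStep:
    def test_naive_pattern_is_a_fixed_point(self, bcell):
        naive = _state(bcell, Bach2=1, Pax5=1)
        assert step(bcell, naive) == naive

    def test_pc_pattern_is_a_fixed_point(self, bcell):
        pc = _state(bcell, Blimp1=1, Irf4=1, XBP1=1)
        assert step(bcell, pc) == pc

    def test_clamped_input_holds_and_free_inputs_decay(self, bcell):
        ones = {n: 1 for n in bcell.node_names}
        nxt = step(bcell, ones, clamps={"Ag": 1})
        assert nxt["Ag"] == 1  # clamped
        assert nxt["IL2"] == 0  # free input decays
        assert nxt["IL4"] == 0

    def test_clamp_overrides_rule(self, bcell):
        pc = _state(bcell, Blimp1=1, Irf4=1, XBP1=1)
        assert step(bcell, pc, clamps={"Blimp1": 0})["Blimp1"] == 0

    def test_step_matches_naive_reimplementation(self, bcell):
        rng = np.random.default_rng(42)
        for _ in range(25):
            bits = dict(zip(bcell.node_names, rng.integers(0, 2, bcell.n_nodes).tolist()))
            assert step(bcell, bits) == naive_step(bcell, bits)
            assert step(bcell, bits, {"Irf4": 1}) == naive_step(bcell, bits, {"Irf4": 1})


class TestEncoding:
    @given(st.integers(min_value=0, max_value=2**22 - 1))
    @settings(max_examples=50, deadline=None)
    def test_encoding_bijective(self, code):
        net = toy_library()["toggle"]  # cheap handle; use bcell-sized codes below
        from bcellfate import load_bcell_network

        bcell = load_bcell_network()
        assert encode_state(bcell, decode_state(bcell, code)) == code

    def test_boolean_state_roundtrip(self, bcell):
        s = BooleanState.from_bits(bcell, {"Pax5": 1})
        assert s.code == 1 << bcell.index("Pax5")
        assert BooleanState.from_code(bcell, s.code).bits == s.bits

    def test_non_boolean_value_rejected(self, bcell):
        with pytest.raises(ValueError):
            encode_state(bcell, {n: 2 for n in bcell.node_names})


class TestFindAttractor:
    def test_toggle_fixed_point_no_transient(self):
        toggle = toy_library()["toggle"]
        att, transient = find_attractor(toggle, {"A": 1, "B": 0})
        assert att.states == (encode_state(toggle, {"A": 1, "B": 0}),)
        assert transient == 0

    def test_toggle_two_cycle(self):
        toggle = toy_library()["toggle"]
        att, _ = find_attractor(toggle, {"A": 0, "B": 0})
        assert att.period == 2
        assert set(att.states) == {0, 3}  # (0,0) <-> (1,1)

    def test_bcell_antigen_start_reaches_a_wildtype_attractor(self, bcell):
        att, _ = find_attractor(bcell, _state(bcell, Ag=1))
        assert att.is_fixed_point
        from bcellfate import CORE_NODES

        assert att.pattern(bcell, CORE_NODES) in set(CORE_PATTERNS.values())

    def test_attractor_closed_under_step(self, bcell):
        att, _ = find_attractor(bcell, _state(bcell, Ag=1, IL4=1, CD40L=1))
        for k, code in enumerate(att.states):
            nxt = step(bcell, decode_state(bcell, code))
            assert encode_state(bcell, nxt) == att.states[(k + 1) % att.period]


class TestEnumerate:
    def test_toggle_attractor_set(self):
        toggle = toy_library()["toggle"]
        atts = enumerate_attractors(toggle)
        states = {a.states for a in atts}
        assert states == {(1,), (2,), (0, 3)}
        by_states = {a.states: a for a in atts}
        assert by_states[(0, 3)].basin_count == 2
        assert by_states[(1,)].basin_count == 1

    def test_neg_ring_has_only_cycles(self):
        ring = toy_library()["neg_ring3"]
        atts = enumerate_attractors(ring)
        assert all(not a.is_fixed_point for a in atts)
        assert sum(a.basin_count for a in atts) == 8

    def test_isolated_input_decays_to_zero(self):
        net = toy_library()["isolated_input"]
        atts = enumerate_attractors(net)
        assert [a.states for a in atts] == [(0,)]
        assert atts[0].basin_count == 2

    def test_basin_fractions_sum_to_one_under_clamps(self, bcell):
        for clamps in ({}, {"Irf4": 1}, {"Bcl6": 0, "Ag": 1}):
            atts = enumerate_attractors(bcell, clamps=clamps)
            assert sum(a.basin_fraction for a in atts) == pytest.approx(1.0, abs=1e-12)

    def test_clamped_bit_fixed_in_reported_states(self, bcell):
        for att in mutant_attractors(bcell, "Blimp1", 1):
            for code in att.states:
                assert decode_state(bcell, code)["Blimp1"] == 1

    def test_size_guard(self):
        spec = RandomNetworkSpec(n_nodes=28, in_degree=2, seed=1)
        net = generate_random_network(spec)
        with pytest.raises(StateSpaceTooLarge):
            enumerate_attractors(net)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize(
        "style", ["random_and_or_not_tree", "random_truth_table_as_AST"]
    )
    def test_matches_bruteforce_oracle_on_random_networks(self, seed, style):
        """Exact agreement with the naive per-state iterator: attractor
        states, cycle lengths, and basin counts."""
        spec = RandomNetworkSpec(
            n_nodes=9, in_degree=2, n_inputs=2, seed=seed, rule_style=style
        )
        net = generate_random_network(spec)
        expected = {_canon(list(cyc)): n for cyc, n in naive_attractors(net).items()}
        assert _engine_basins(net, enumerate_attractors(net)) == expected

    def test_mutant_clamp_matches_oracle(self):
        net = generate_random_network(RandomNetworkSpec(n_nodes=8, in_degree=2, seed=7))
        clamp = {"n03": 1}
        expected = {_canon(list(cyc)): n for cyc, n in naive_attractors(net, clamps=clamp).items()}
        assert _engine_basins(net, enumerate_attractors(net, clamps=clamp)) == expected

    def test_restricted_initial_space(self, bcell):
        """Restricting the enumerated initial subspace restricts basins
        accordingly (free bits only) while attractors stay fixed points."""
        from bcellfate import CORE_NODES

        atts = enumerate_attractors(bcell, free_nodes=CORE_NODES)
        assert sum(a.basin_count for a in atts) == 2 ** len(CORE_NODES)
        assert all(a.is_fixed_point for a in atts)


class TestWildTypeAttractors:
    def test_exactly_four_fixed_points(self, wt_attractors):
        assert len(wt_attractors) == 4
        assert all(a.is_fixed_point for a in wt_attractors)

    def test_attractor_set_independent_of_enumeration_convention(self, bcell, wt_attractors):
        """The same four attractors are reached from single trajectories."""
        from bcellfate import CORE_NODES

        expected = {a.states[0] for a in wt_attractors}
        seen = set()
        for signal in ("Ag", "IL4", "CD40L", "IL21", "IL2"):
            att, _ = find_attractor(bcell, _state(bcell, **{signal: 1}))
            seen.add(att.states[0])
        att, _ = find_attractor(bcell, _state(bcell))
        seen.add(att.states[0])
        assert seen <= expected
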