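"""Continuous engine: sigmoid, fuzzification, equilibria, relaxation."""

from itertools import product

import numpy as np
import pytest

from bcellfate import (
    CORE_NODES,
    ContinuousParams,
    ContinuousSystem,
    derivative,
    fuzzify,
    relax,
    sample_attractors,
    sigmoid,
)
from bcellfate.boolean import decode_state
from bcellfate.synthetic import RandomNetworkSpec, generate_random_network

from .conftest import CORE_PATTERNS
from .oracles import textbook_sigmoid

H_GRID = [1.0, 4.0, 8.0, 50.0, 100.0]

# Intermediate continuous-only fixed points: half-activation of Bcl6
# and/or Irf4 on a Bach2+/Pax5+ background.
INTERMEDIATE_PATTERNS = {
    "New1": {"Bach2": 1, "Pax5": 1, "Bcl6": 0.5},
    "New2": {"Bach2": 1, "Pax5": 1, "Irf4": 0.5},
    "New3": {"Bach2": 1, "Pax5": 1, "Bcl6": 0.5, "Irf4": 0.5},
}


def _full_state(net, levels):
    x = {n: 0.0 for n in net.node_names}
    x.update(levels)
    return x


class TestSigmoid:
    @pytest.mark.parametrize("h", H_GRID)
    def test_anchor_points(self, h):
        assert sigmoid(0.0, h) == pytest.approx(0.0, abs=1e-14)
        assert sigmoid(0.5, h) == pytest.approx(0.5, abs=1e-14)
        assert sigmoid(1.0, h) == pytest.approx(1.0, abs=1e-14)

    @pytest.mark.parametrize("h", H_GRID)
    def test_monotone_nondecreasing(self, h):
        w = np.linspace(0, 1, 2001)
        assert np.all(np.diff(sigmoid(w, h)) >= -1e-15)

    @pytest.mark.parametrize("h", [1.0, 4.0, 8.0, 50.0])
    def test_matches_textbook_formula(self, h):
        for w in np.linspace(0.0, 1.0, 41):
            assert sigmoid(w, h) == pytest.approx(textbook_sigmoid(w, h), abs=1e-12)

    def test_step_like_at_high_gain(self):
        assert sigmoid(0.45, 50.0) < 0.1
        assert sigmoid(0.55, 50.0) > 0.9
        assert sigmoid(0.4, 50.0) < 0.01
        assert sigmoid(0.6, 50.0) > 0.99

    def test_large_gain_does_not_overflow(self):
        with np.errstate(over="raise"):
            vals = sigmoid(np.linspace(0, 1, 101), 1000.0)
        assert np.all(np.isfinite(vals))

    def test_nonpositive_gain_rejected(self):
        with pytest.raises(ValueError):
            sigmoid(0.5, 0.0)


class TestFuzzify:
    def test_bach2_rule_is_min_of_pax5_and_one_minus_blimp1(self, bcell):
        fz = fuzzify(bcell.rules["Bach2"])
        env = {n: 0.0 for n in bcell.node_names}
        env.update(Pax5=0.7, Blimp1=0.2)
        assert fz.eval(env) == pytest.approx(0.7)  # min(0.7, 0.8)
        assert "min" in fz.to_text()

    def test_xbp1_rule_pc_corner(self, bcell):
        fz = fuzzify(bcell.rules["XBP1"])
        env = {n: 0.0 for n in bcell.node_names}
        env.update(Blimp1=1.0, Pax5=0.0)
        assert fz.eval(env) == pytest.approx(1.0)

    @pytest.mark.parametrize("target", ["AID", "Bcl6", "Blimp1", "Irf4", "Pax5", "XBP1"])
    def test_fuzzy_equals_boolean_on_all_corners(self, bcell, target):
        rule = bcell.rules[target]
        fz = fuzzify(rule)
        variables = sorted(rule.expression.variables())
        base = {n: 0.0 for n in bcell.node_names}
        for values in product((0.0, 1.0), repeat=len(variables)):
            env = dict(base)
            env.update(zip(variables, values))
            bool_env = {k: int(v) for k, v in env.items()}
            assert fz.eval(env) == pytest.approx(rule.expression.eval(bool_env))


class TestDerivative:
    @pytest.mark.parametrize("label", sorted(CORE_PATTERNS))
    def test_binary_fixed_points_are_equilibria(self, bcell, params, label):
        state = _full_state(bcell, dict(zip(CORE_NODES, CORE_PATTERNS[label])))
        rates = derivative(bcell, params, state)
        assert max(abs(v) for v in rates.values()) < 1e-12

    def test_input_node_pure_decay(self, bcell, params):
        state = _full_state(bcell, {"IL4": 0.8})
        assert derivative(bcell, params, state)["IL4"] == pytest.approx(-0.8)

    @pytest.mark.parametrize("h", H_GRID)
    @pytest.mark.parametrize("name", sorted(INTERMEDIATE_PATTERNS))
    def test_intermediate_patterns_are_equilibria_for_every_gain(self, bcell, name, h):
        """The half-activated fixed points have exactly zero rates for any
        h, because their fuzzy inputs sit at the sigmoid anchor 0.5."""
        state = _full_state(bcell, INTERMEDIATE_PATTERNS[name])
        rates = derivative(bcell, ContinuousParams(h=h), state)
        assert max(abs(v) for v in rates.values()) == pytest.approx(0.0, abs=1e-14)

    def test_clamped_node_rate_zero(self, bcell, params):
        state = _full_state(bcell, {"Blimp1": 0.4})
        rates = derivative(bcell, params, state, clamps={"Blimp1": 0.4})
        assert rates["Blimp1"] == 0.0


class TestRelax:
    def test_gc_pattern_relaxes_to_itself(self, bcell, params):
        gc = _full_state(bcell, dict(zip(CORE_NODES, CORE_PATTERNS["GC"])))
        att = relax(bcell, params, gc)
        assert att.converged
        for node, expect in zip(CORE_NODES, CORE_PATTERNS["GC"]):
            assert att.levels[node] == pytest.approx(expect, abs=1e-9)

    def test_origin_flows_to_naive(self, bcell, params):
        """With every node off, Pax5's NOT-Irf4 arm switches it on: the
        resting cell settles into the Naive program."""
        att = relax(bcell, params, _full_state(bcell, {}))
        assert att.converged
        for node, expect in zip(CORE_NODES, CORE_PATTERNS["Naive"]):
            assert att.levels[node] == pytest.approx(expect, abs=1e-9)

    def test_clamped_level_held(self, bcell, params):
        att = relax(bcell, params, _full_state(bcell, {}), clamps={"Blimp1": 1.0})
        assert att.levels["Blimp1"] == 1.0

    def test_nonconvergence_is_flagged(self, bcell):
        p = ContinuousParams(max_time=0.5, convergence_tol=1e-14)
        att = relax(bcell, p, _full_state(bcell, {"Blimp1": 0.3, "Pax5": 0.6}))
        assert not att.converged

    def test_steady_state_closed_form_single_node(self):
        """A self-sustaining node with saturated input converges to
        f(omega)/gamma; gamma=2 halves the level (decay-rate sensitivity)."""
        from bcellfate import RegulatoryNetwork

        net = RegulatoryNetwork.from_rules({"A": "B", "B": "B"})
        # B=1 keeps omega_A = 1; with gamma=2, x*_A = f(1)/2 = 0.5
        att = relax(net, ContinuousParams(gamma=2.0), {"A": 1.0, "B": 1.0}, clamps={"B": 1.0})
        assert att.levels["A"] == pytest.approx(0.5, abs=1e-8)
        att = relax(net, ContinuousParams(gamma=1.0), {"A": 0.2, "B": 1.0}, clamps={"B": 1.0})
        assert att.levels["A"] == pytest.approx(1.0, abs=1e-8)


class TestSampling:
    def test_seeded_runs_are_reproducible(self, bcell, params):
        a = sample_attractors(bcell, params, n_runs=3, seed=123)
        b = sample_attractors(bcell, params, n_runs=3, seed=123)
        assert [x.levels for x in a] == [y.levels for y in b]

    def test_small_sample_finds_only_binary_core_attractors(self, bcell, params):
        atts = sample_attractors(bcell, params, n_runs=60, seed=5)
        assert all(a.converged for a in atts)
        patterns = {a.pattern(CORE_NODES) for a in atts}
        allowed = {tuple(map(float, p)) for p in CORE_PATTERNS.values()}
        assert patterns <= allowed

    def test_trajectories_stay_in_unit_box(self, bcell, params):
        sys = ContinuousSystem(bcell, params)
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, size=(20, sys.n))
        for _ in range(10):
            X = sys.integrate_batch(X, 2.0)
            assert X.min() > -1e-6 and X.max() < 1 + 1e-6

    def test_batch_and_adaptive_integrators_agree(self, bcell, params):
        sys = ContinuousSystem(bcell, params)
        rng = np.random.default_rng(11)
        X0 = rng.uniform(0, 1, size=(5, sys.n))
        Xb, ok = sys.relax_batch(X0.copy())
        assert ok.all()
        for x0, xb in zip(X0, Xb):
            xa = sys.relax(x0)
            assert np.allclose(
                [xa.levels[n] for n in bcell.node_names], xb, atol=1e-6
            )


class TestCrossEngineConsistency:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_discrete_fixed_points_are_continuous_equilibria(self, seed):
        """On arbitrary random networks, every synchronous fixed point is
        an equilibrium of the fuzzified ODE system at h=50, gamma=1."""
        from bcellfate import enumerate_attractors

        net = generate_random_network(
            RandomNetworkSpec(n_nodes=8, in_degree=2, n_inputs=1, seed=seed)
        )
        params = ContinuousParams()
        fixed = [a for a in enumerate_attractors(net) if a.is_fixed_point]
        for att in fixed:
            state = {k: float(v) for k, v in decode_state(net, att.states[0]).items()}
            rates = derivative(net, params, state)
            assert max(abs(v) for v in rates.values()) < 1e-12
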