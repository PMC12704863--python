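"""Normalized Hill functions, logic gates, and the ODE engine contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hormonet.engine import (
    HillParams,
    NetworkModel,
    ReactionRule,
    SpeciesNode,
    build_rhs,
    hill_activation,
    hill_inhibition,
    integrate_to_steady_state,
    logic_and,
    logic_or,
)

HILL = HillParams(n=1.4, ec50=0.5)
UNIT = st.floats(min_value=0.0, max_value=1.0)


class TestHillFunctions:
    def test_derived_constants_satisfy_half_maximum_identity(self):
        # B and K are defined exactly so that f_act(EC50) = W/2; the
        # construction requires EC50**n < 1/2
        for ec50 in (0.3, 0.4, 0.5):
            for n in (1.2, 1.4, 2.0):
                h = HillParams(n=n, ec50=ec50)
                assert hill_activation(ec50, 1.0, h) == pytest.approx(0.5, abs=1e-14)

    def test_boundary_identities_exact(self):
        assert hill_activation(0.0, 1.0, HILL) == 0.0
        assert hill_activation(1.0, 1.0, HILL) == pytest.approx(1.0, abs=1e-15)
        assert hill_inhibition(0.0, 1.0, HILL) == pytest.approx(1.0, abs=1e-15)
        assert hill_inhibition(1.0, 1.0, HILL) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize(
        "x,expected",
        [
            (0.5, 0.5),
            (0.3, 0.2716),  # direct evaluation with B~2.5649, K~1.3771
            (0.15, 0.1102),
        ],
    )
    def test_reference_values(self, x, expected):
        assert hill_activation(x, 1.0, HILL) == pytest.approx(expected, abs=5e-5)
        assert hill_inhibition(x, 1.0, HILL) == pytest.approx(1 - expected, abs=5e-5)

    @given(x=UNIT, w=UNIT)
    @settings(derandomize=True, max_examples=80)
    def test_range_and_linearity_in_weight(self, x, w):
        f = hill_activation(x, w, HILL)
        assert 0.0 <= f <= w + 1e-12
        assert f == pytest.approx(w * hill_activation(x, 1.0, HILL), abs=1e-12)

    @given(x1=UNIT, x2=UNIT)
    @settings(derandomize=True, max_examples=80)
    def test_monotone_nondecreasing(self, x1, x2):
        lo, hi = sorted((x1, x2))
        assert hill_activation(lo, 1.0, HILL) <= hill_activation(hi, 1.0, HILL) + 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hill_activation(1.2, 1.0, HILL)
        with pytest.raises(ValueError):
            hill_activation(0.5, -0.1, HILL)
        with pytest.raises(ValueError):
            HillParams(n=0.9, ec50=0.5)
        with pytest.raises(ValueError):
            HillParams(n=1.4, ec50=1.0)
        with pytest.raises(ValueError, match="too large"):
            HillParams(n=1.2, ec50=0.7)


class TestLogicGates:
    @given(a=UNIT, b=UNIT)
    @settings(derandomize=True, max_examples=80)
    def test_gate_bounds(self, a, b):
        assert logic_and(a, b) <= min(a, b) + 1e-12
        assert logic_or(a, b) >= max(a, b) - 1e-12
        assert 0.0 <= logic_and(a, b) <= 1.0 + 1e-12
        assert 0.0 <= logic_or(a, b) <= 1.0 + 1e-12

    @given(a=UNIT, b=UNIT, c=UNIT)
    @settings(derandomize=True, max_examples=80)
    def test_gate_monotonicity(self, a, b, c):
        lo, hi = sorted((b, c))
        assert logic_and(a, lo) <= logic_and(a, hi) + 1e-12
        assert logic_or(a, lo) <= logic_or(a, hi) + 1e-12

    @pytest.mark.parametrize(
        "op,a,b,expected",
        [
            (logic_and, 1.0, 1.0, 1.0),
            (logic_and, 0.5, 0.5, 0.25),
            (logic_and, 0.0, 0.7, 0.0),
            (logic_or, 0.0, 0.7, 0.7),
            (logic_or, 0.5, 0.5, 0.75),
            (logic_or, 1.0, 0.3, 1.0),
        ],
    )
    def test_gate_examples(self, op, a, b, expected):
        assert op(a, b) == pytest.approx(expected, abs=1e-12)

    def test_or_fold_permutation_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 1, 6)
        from functools import reduce

        ref = reduce(logic_or, vals)
        for _ in range(10):
            rng.shuffle(vals)
            assert reduce(logic_or, vals) == pytest.approx(ref, abs=1e-12)


def _simple_chain(w=0.5, tau=0.1):
    species = [
        SpeciesNode("IN", tau=tau),
        SpeciesNode("A", tau=tau),
        SpeciesNode("B", tau=tau),
    ]
    rules = [
        ReactionRule("IN", weight=w),
        ReactionRule("A", (("IN", 1),)),
        ReactionRule("B", (("A", 1),)),
    ]
    return NetworkModel(species, rules, inputs=["IN"], output="B")


class TestRhsAndSteadyState:
    def test_single_activation_fixed_point(self):
        # product of a single activation relaxes to f_act of its held source
        model = NetworkModel(
            [SpeciesNode("T", tau=0.1), SpeciesNode("IP3", tau=0.1)],
            [ReactionRule("T", weight=0.15), ReactionRule("IP3", (("T", 1),))],
            inputs=["T"],
            output="IP3",
        )
        res = integrate_to_steady_state(model)
        assert res.converged
        assert res["IP3"] == pytest.approx(0.1102, abs=1e-4)

    def test_and_or_gate_assembly(self):
        # OR(AND(f_act(E), f_act(C)), f_inh(G)) drive, evaluated at a point
        species = [SpeciesNode(n) for n in ["E", "C", "G", "NFAT"]]
        rules = [
            ReactionRule("E", weight=0.4),
            ReactionRule("C", weight=0.6),
            ReactionRule("G", weight=0.3),
            ReactionRule("NFAT", (("E", 1), ("C", 1))),
            ReactionRule("NFAT", (("G", -1),)),
        ]
        model = NetworkModel(species, rules, inputs=["E", "C", "G"], output="NFAT")
        y = np.array([0.4, 0.6, 0.3, 0.0])
        fa, fc = hill_activation(0.4), hill_activation(0.6)
        fg = hill_inhibition(0.3)
        expected = logic_or(logic_and(fa, fc), fg)
        assert model.phi(y)[3] == pytest.approx(expected, abs=1e-12)

    def test_clamped_node_has_zero_derivative_everywhere(self):
        model = _simple_chain()
        rhs = build_rhs(model, clamps={"A": 0.7})
        rng = np.random.default_rng(0)
        for _ in range(5):
            dy = rhs(0.0, rng.uniform(0, 1, 3))
            assert dy[model.index["A"]] == 0.0

    def test_chain_steady_state_closed_form(self):
        model = _simple_chain(w=0.5)
        res = integrate_to_steady_state(model)
        assert res["IN"] == pytest.approx(0.5, abs=1e-7)
        assert res["A"] == pytest.approx(hill_activation(0.5), abs=1e-6)
        assert res["B"] == pytest.approx(
            hill_activation(hill_activation(0.5)), abs=1e-6
        )

    def test_zero_weight_network_stays_at_zero(self):
        model = _simple_chain(w=0.0)
        res = integrate_to_steady_state(model)
        assert res.converged
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in res.steady_state.values())

    def test_steady_state_independent_of_tau(self):
        fast = _simple_chain(w=0.5, tau=0.05)
        slow = _simple_chain(w=0.5, tau=2.0)
        r1 = integrate_to_steady_state(fast)
        r2 = integrate_to_steady_state(slow)
        for k in r1.steady_state:
            assert r1.steady_state[k] == pytest.approx(r2.steady_state[k], abs=1e-6)

    def test_trajectories_bounded(self, hypertrophy_model):
        res = integrate_to_steady_state(hypertrophy_model)
        assert res.activities.min() >= -1e-8
        assert res.activities.max() <= 1.0 + 1e-8

    def test_model_error_for_orphan_species(self):
        with pytest.raises(ValueError, match="no reaction"):
            NetworkModel(
                [SpeciesNode("A"), SpeciesNode("B")],
                [ReactionRule("B", (("A", 1),))],
                inputs=[],
            )

    def test_unknown_clamp_target_rejected(self):
        model = _simple_chain()
        with pytest.raises(ValueError, match="clamp target"):
            build_rhs(model, clamps={"nope": 0.5})
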