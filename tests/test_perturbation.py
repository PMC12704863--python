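"""Clamp screens, response curves, crosstalk landscapes, Sobol indices."""

import numpy as np
import pytest

from hormonet.engine import (
    NetworkModel,
    ReactionRule,
    SpeciesNode,
    hill_activation,
    steady_state,
)
from hormonet.perturbation import (
    ClampExperiment,
    batch_steady_states,
    crosstalk_landscape,
    influence_sensitivity_screen,
    response_curve,
    sobol_first_order,
)
from hormonet.synthetic import SyntheticSpec, generate


def _chain2(w=0.5):
    # source(w) -> A -> B
    species = [SpeciesNode("A"), SpeciesNode("B")]
    rules = [
        ReactionRule("A", weight=w),
        ReactionRule("B", (("A", 1),)),
    ]
    return NetworkModel(species, rules, inputs=["A"], output="B")


class TestScreen:
    def test_clamp_at_background_value_has_zero_influence(self):
        model = _chain2(0.5)
        rep = influence_sensitivity_screen(model, 0.5, method="fixed_point")
        assert rep.influence["A"] == pytest.approx(0.0, abs=1e-8)

    def test_chain_influence_closed_form(self):
        w = 0.4
        model = _chain2(w)
        rep = influence_sensitivity_screen(model, 0.8, method="fixed_point")
        expected = abs(hill_activation(0.8) - hill_activation(w))
        assert rep.influence["A"] == pytest.approx(expected, abs=1e-6)

    def test_terminal_node_has_zero_influence(self):
        model = _chain2(0.5)
        rep = influence_sensitivity_screen(model, 0.8, method="fixed_point")
        assert rep.influence["B"] == pytest.approx(0.0, abs=1e-8)
        assert rep.sensitivity["B"] > 0

    def test_diagonal_excluded(self):
        model = _chain2(0.5)
        rep = influence_sensitivity_screen(model, 0.8, method="fixed_point")
        assert (np.diag(rep.delta.loc[rep.delta.columns]) == 0).all()

    def test_order_invariance_by_construction(self, hypertrophy_model):
        # experiments are independent; two runs give identical tables
        r1 = influence_sensitivity_screen(hypertrophy_model, 0.1, method="fixed_point")
        r2 = influence_sensitivity_screen(hypertrophy_model, 0.1, method="fixed_point")
        assert np.allclose(r1.delta.values, r2.delta.values)

    def test_clamp_value_validation(self):
        with pytest.raises(ValueError):
            ClampExperiment("X", 1.2)


class TestResponseCurves:
    def test_no_path_node_gives_flat_curve(self):
        # Y is a dead-end side branch: clamping it cannot move OUT
        species = [SpeciesNode("IN"), SpeciesNode("Y"), SpeciesNode("OUT")]
        rules = [
            ReactionRule("IN", weight=0.5),
            ReactionRule("Y", (("IN", 1),)),
            ReactionRule("OUT", (("IN", 1),)),
        ]
        model = NetworkModel(species, rules, inputs=["IN"], output="OUT")
        curve = response_curve(model, "Y", grid=np.linspace(0, 1, 5),
                               method="fixed_point")
        assert curve["output"].std() == pytest.approx(0.0, abs=1e-10)

    def test_input_weight_sweep_monotone_on_packaged(self, hypertrophy_model):
        t = response_curve(hypertrophy_model, "T", grid=np.linspace(0, 1, 9),
                           method="fixed_point")
        e2 = response_curve(hypertrophy_model, "E2", grid=np.linspace(0, 1, 9),
                            method="fixed_point")
        assert (np.diff(t["output"]) >= -1e-9).all()
        assert (np.diff(e2["output"]) <= 1e-9).all()

    def test_clamp_grid_endpoints_match_dedicated_clamps(self, hypertrophy_model):
        curve = response_curve(
            hypertrophy_model, "eNOS", grid=[0.0, 1.0], mode="clamp",
            method="fixed_point",
        )
        for x, expected in zip([0.0, 1.0], curve["output"]):
            res = steady_state(hypertrophy_model, clamps={"eNOS": x},
                               method="fixed_point")
            assert res.steady_state["CellArea"] == pytest.approx(expected, abs=1e-9)

    def test_weight_sweep_rejected_for_interior_node(self, hypertrophy_model):
        with pytest.raises(ValueError, match="not an input"):
            response_curve(hypertrophy_model, "eNOS", mode="weight")


class TestLandscape:
    def test_symmetric_for_exchangeable_inputs(self):
        model = generate(SyntheticSpec(topology="motif_or", seed=0))
        grid = np.linspace(0, 1, 6)
        mat = crosstalk_landscape(model, "U1", "U2", grid=grid)
        assert np.allclose(mat.values, mat.values.T, atol=1e-9)

    def test_monotone_along_pro_hypertrophic_axes(self, hypertrophy_model):
        grid = np.linspace(0, 1, 6)
        mat = crosstalk_landscape(hypertrophy_model, "AngII", "Strain", grid=grid)
        assert (np.diff(mat.values, axis=0) >= -1e-9).all()
        assert (np.diff(mat.values, axis=1) >= -1e-9).all()

    def test_estradiol_axis_reverses_gradient(self, hypertrophy_model):
        grid = np.linspace(0, 1, 6)
        mat = crosstalk_landscape(hypertrophy_model, "Strain", "E2", grid=grid)
        # increasing E2 (rows) lowers CellArea at every strain level
        assert (np.diff(mat.values, axis=0) <= 1e-9).all()
        # high estradiol prevents hypertrophy even at maximal strain
        assert mat.values[-1, -1] < 0.5


def _two_input_additive_like():
    # OUT driven by OR of two independent inputs
    return generate(SyntheticSpec(topology="motif_or", seed=0))


class TestSobol:
    def test_single_dependency_index_saturates(self):
        model = generate(SyntheticSpec(n_species=3, topology="chain", seed=0))
        res = sobol_first_order(
            model, inputs=["IN"], n_base=256, outputs=["OUT"], n_boot=20
        )
        assert res.indices.loc["IN", "OUT"] == pytest.approx(1.0, abs=0.05)

    def test_two_input_variance_shares_match_monte_carlo_oracle(self):
        model = _two_input_additive_like()
        res = sobol_first_order(
            model, inputs=["U1", "U2"], n_base=512, outputs=["OUT"], n_boot=20,
            seed=11,
        )
        # brute-force double-loop estimate of S1 = Var(E[f|x1]) / Var(f)
        rng = np.random.default_rng(0)
        n_outer, n_inner = 300, 300
        f = hill_activation
        x1 = rng.uniform(size=n_outer)
        inner_means = []
        for v in x1:
            x2 = rng.uniform(size=n_inner)
            y = f(v) + f(x2) - f(v) * f(x2)
            inner_means.append(y.mean())
        x1g = rng.uniform(size=n_outer * n_inner)
        x2g = rng.uniform(size=n_outer * n_inner)
        yg = f(x1g) + f(x2g) - f(x1g) * f(x2g)
        s1_oracle = np.var(inner_means) / np.var(yg)
        assert res.indices.loc["U1", "OUT"] == pytest.approx(s1_oracle, abs=0.08)
        # exchangeable inputs: indices agree with each other
        assert res.indices.loc["U1", "OUT"] == pytest.approx(
            res.indices.loc["U2", "OUT"], abs=0.08
        )

    def test_convergence_with_sample_size(self):
        model = generate(SyntheticSpec(n_species=3, topology="chain", seed=0))
        errs = []
        for n in (64, 256, 1024):
            res = sobol_first_order(
                model, inputs=["IN"], n_base=n, outputs=["OUT"], n_boot=10
            )
            errs.append(abs(res.indices.loc["IN", "OUT"] - 1.0))
        assert errs[-1] <= errs[0] + 0.02
        assert errs[-1] < 0.03

    def test_non_power_of_two_warns_and_rounds(self):
        model = generate(SyntheticSpec(n_species=3, topology="chain", seed=0))
        with pytest.warns(UserWarning, match="power of two"):
            res = sobol_first_order(
                model, inputs=["IN"], n_base=100, outputs=["OUT"], n_boot=5
            )
        assert res.n_base == 128

    def test_batch_matches_individual_steady_states(self, hypertrophy_model):
        m = hypertrophy_model
        rng = np.random.default_rng(2)
        W = rng.uniform(0, 1, size=(4, 5))
        inputs = list(m.inputs)
        batch = batch_steady_states(m, W, inputs)
        for k in range(4):
            res = steady_state(
                m.with_input_weights(dict(zip(inputs, W[k]))), method="fixed_point"
            )
            vec = np.array([res.steady_state[s.name] for s in m.species])
            assert np.allclose(batch[k], vec, atol=1e-7)
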