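"""Causal layer: propensities, weighted loss, regularizers, counterfactuals."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import geoexposure as gx
from geoexposure import cam
from geoexposure.baselines import CausalDataset

from conftest import build_linear_model


def _dataset(rng, n=200, slope=1.5):
    Z = rng.standard_normal((n, 1))
    prob = 1 / (1 + np.exp(-slope * Z[:, 0]))
    T = (rng.uniform(size=n) < prob).astype(int)
    return CausalDataset(unit_ids=list(range(n)), treatment=T,
                         confounders=Z, outcome=rng.standard_normal(n))


class TestPropensity:
    def test_logistic_hand_values(self):
        pm = cam.PropensityModel(weights=np.array([1.0, -1.0]))
        assert cam.propensity_score(np.array([2.0, 1.0]), pm) == pytest.approx(
            1 / (1 + np.exp(-1)), abs=1e-9)
        pm0 = cam.PropensityModel(weights=np.zeros(3))
        assert cam.propensity_score(np.zeros(3), pm0) == pytest.approx(0.5)

    def test_saturation_stays_strictly_inside_unit_interval(self):
        pm = cam.PropensityModel(weights=np.array([1.0]))
        hi = cam.propensity_score(np.array([30.0]), pm)
        assert hi < 1.0 and 1.0 - hi < 1e-9
        lo = cam.propensity_score(np.array([-800.0]), pm)
        assert lo > 0.0

    def test_non_finite_confounders_rejected(self):
        pm = cam.PropensityModel(weights=np.array([1.0]))
        with pytest.raises(ValueError):
            cam.propensity_score(np.array([np.nan]), pm)

    def test_null_association_yields_small_slopes(self):
        # treatment independent of the confounders: slopes scatter around
        # zero at the O(1/sqrt(n)) sampling scale, with no systematic drift
        slopes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            Z = rng.standard_normal((2000, 2))
            T = (rng.uniform(size=2000) < 0.5).astype(int)
            ds = CausalDataset(unit_ids=list(range(2000)), treatment=T,
                               confounders=Z, outcome=np.zeros(2000))
            slopes.append(cam.fit_propensity(ds).weights)
        slopes = np.abs(slopes)
        assert slopes.mean() < 0.05
        assert np.quantile(slopes, 0.9) < 0.1

    def test_known_slope_recovered(self):
        rng = np.random.default_rng(42)
        n = 5000
        Z = rng.standard_normal((n, 1))
        prob = 1 / (1 + np.exp(-1.5 * Z[:, 0]))
        T = (rng.uniform(size=n) < prob).astype(int)
        ds = CausalDataset(unit_ids=list(range(n)), treatment=T,
                           confounders=Z, outcome=np.zeros(n))
        pm = cam.fit_propensity(ds)
        assert pm.weights[0] == pytest.approx(1.5, abs=0.15)
        assert not pm.ridged

    def test_degenerate_designs_trigger_ridge_fallback(self):
        rng = np.random.default_rng(3)
        # constant confounder column: unidentifiable coefficient
        Z = np.column_stack([np.ones(100), rng.standard_normal(100)])
        T = (rng.uniform(size=100) < 0.5).astype(int)
        ds = CausalDataset(unit_ids=list(range(100)), treatment=T,
                           confounders=Z, outcome=np.zeros(100))
        with pytest.warns(RuntimeWarning, match="ridge"):
            assert cam.fit_propensity(ds).ridged
        # perfect separation
        Zs = np.linspace(-1, 1, 40).reshape(-1, 1)
        ds2 = CausalDataset(unit_ids=list(range(40)),
                            treatment=(Zs[:, 0] > 0).astype(int),
                            confounders=Zs, outcome=np.zeros(40))
        with pytest.warns(RuntimeWarning, match="ridge"):
            assert cam.fit_propensity(ds2).ridged


class TestIPWLoss:
    def test_hand_values(self):
        assert cam.ipw_loss(np.array([1.0]), np.array([1.0]),
                            np.array([0.7]), 0.1) == 0.0
        assert cam.ipw_loss(np.array([1.0]), np.array([0.0]),
                            np.array([1.0]), 0.0) == pytest.approx(1.0)
        # errors (1, 4) at pi (0.5, 0.25): 2 + 16
        assert cam.ipw_loss(np.array([1.0, 2.0]), np.array([0.0, 0.0]),
                            np.array([0.5, 0.25]), 0.0) == pytest.approx(18.0)

    def test_negative_epsilon_and_bad_propensities_rejected(self):
        with pytest.raises(ValueError):
            cam.ipw_loss(np.zeros(2), np.zeros(2), np.full(2, 0.5), -0.1)
        with pytest.raises(ValueError):
            cam.ipw_loss(np.zeros(2), np.zeros(2), np.array([0.0, 0.5]), 0.1)

    def test_tensor_path_matches_numpy_path(self, rng):
        from geoexposure import autodiff as ad
        pred = rng.standard_normal((4, 5, 2))
        obs = rng.standard_normal((4, 5, 2))
        pi = rng.uniform(0.2, 0.8, 4)
        a = cam.ipw_loss(pred, obs, pi, 1e-3)
        b = cam.ipw_loss(ad.Tensor(pred), obs, pi, 1e-3)
        assert float(b.data) == pytest.approx(a, rel=1e-12)


class TestEpiRegularizer:
    def test_matched_signs_give_zero_in_eval_mode(self, rng, linear_model):
        m = linear_model(np.array([2.0, 0.7]))
        E = rng.standard_normal((4, 6, 2))
        priors = cam.EpidemiologicalPriors(directions=[1, 1], strength=0.3)
        assert cam.epi_regularizer(m, E, priors, "eval") == 0.0

    def test_single_mismatch_worst_case_value(self, rng, linear_model):
        m = linear_model(np.array([2.0]))  # positive response
        E = rng.standard_normal((1, 4, 1))
        priors = cam.EpidemiologicalPriors(directions=[-1], strength=0.1)
        assert cam.epi_regularizer(m, E, priors, "eval") == pytest.approx(0.4)

    def test_zero_direction_contributes_nothing(self, rng, linear_model):
        m = linear_model(np.array([2.0, -1.0]))
        E = rng.standard_normal((3, 5, 2))
        only_second = cam.EpidemiologicalPriors(directions=[0, -1], strength=1.0)
        assert cam.epi_regularizer(m, E, only_second, "eval") == 0.0

    def test_unknown_mode_rejected(self, rng, linear_model):
        m = linear_model(np.array([1.0]))
        with pytest.raises(ValueError, match="mode"):
            cam.epi_regularizer(m, rng.standard_normal((2, 4, 1)),
                                cam.EpidemiologicalPriors([1], 1.0), "predict")

    def test_train_mode_is_differentiable_and_near_eval_value(self, rng, linear_model):
        from geoexposure.autodiff import Tensor
        m = linear_model(np.array([2.0]))
        E = rng.standard_normal((2, 5, 1))
        priors = cam.EpidemiologicalPriors(directions=[-1], strength=0.1)
        out = cam.epi_regularizer(m, E, priors, "train", kappa=0.01)
        assert isinstance(out, Tensor)
        out.backward()
        assert float(out.data) == pytest.approx(0.4, abs=1e-3)


class TestPolicyGate:
    def _model(self):
        cfg = gx.ModelConfig(d=2, tau=1, n_exposures=1, policy_dim=1,
                             context_dim=1)
        m = gx.init_model(cfg, seed=0)
        m.params["Wp"].data[:] = np.array([[1.0, 0.0]])
        m.params["bp"].data[:] = 0.0
        return m

    def test_hand_values_and_saturation(self):
        m = self._model()
        z = cam.policy_gate(np.array([2.0]), m)
        assert z == pytest.approx([0.880797, 0.5], abs=1e-6)
        m.params["Wp"].data[:] = 0.0
        assert np.allclose(cam.policy_gate(np.array([5.0]), m), 0.5)
        m.params["bp"].data[:] = 30.0
        z = cam.policy_gate(np.array([0.0]), m)
        assert np.all(z < 1.0) and np.all(1.0 - z < 1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(-50, 50))
    def test_gate_strictly_inside_unit_interval(self, p):
        z = cam.policy_gate(np.array([p]), self._model())
        assert np.all((z > 0) & (z < 1))

    def test_apply_gate_modulates_elementwise(self):
        U = np.array([[1.0, 1.0], [2.0, -2.0]])
        assert np.array_equal(cam.apply_gate(U, np.ones(2)), U)
        assert np.allclose(cam.apply_gate(U, np.full(2, 0.5)), U / 2)
        z = np.array([0.880797, 0.5])
        assert np.allclose(cam.apply_gate(np.array([[1.0, 1.0]]), z), z[None])


class TestCounterfactuals:
    def _kernel(self):
        return cam.LinearLagKernel(beta=[[0.5]], lag_weights=np.ones(4))

    def test_linear_kernel_hand_sum(self):
        k = self._kernel()
        high = cam.ExposureScenario(np.full((4, 1), 2.0), "high")
        zero = cam.ExposureScenario(np.zeros((4, 1)), "zero")
        assert cam.counterfactual_response(high, k) == pytest.approx([4.0])
        assert cam.counterfactual_response(zero, k) == pytest.approx([0.0])
        assert cam.causal_effect(high, zero, k) == pytest.approx([4.0])

    def test_homogeneity_identity_antisymmetry(self, rng):
        k = self._kernel()
        doubled = cam.LinearLagKernel(beta=[[1.0]], lag_weights=np.ones(4))
        e1 = cam.ExposureScenario(rng.standard_normal((4, 1)))
        e2 = cam.ExposureScenario(rng.standard_normal((4, 1)))
        assert np.allclose(cam.counterfactual_response(e1, doubled),
                           2 * cam.counterfactual_response(e1, k))
        assert cam.causal_effect(e1, e1, k) == pytest.approx([0.0], abs=0.0)
        assert np.array_equal(cam.causal_effect(e1, e2, k),
                              -cam.causal_effect(e2, e1, k))

    def test_plain_callable_kernel_discrete_sum(self):
        def G(e_s, s, S, C_s):
            return 0.5 * e_s
        out = cam.counterfactual_response(np.full((4, 1), 2.0), G)
        assert out == pytest.approx([4.0])

    def test_matrix_columns_and_duplicates(self):
        k = self._kernel()
        scens = [cam.ExposureScenario(np.full((4, 1), lv), f"l{lv}")
                 for lv in (1.0, 2.0, 3.0)]
        mat = cam.counterfactual_matrix(scens, k)
        assert np.allclose(mat.values, [[2.0, 4.0, 6.0]])
        dup = cam.counterfactual_matrix([scens[0], scens[0]], k)
        assert np.array_equal(dup.values[:, 0], dup.values[:, 1])
        with pytest.raises(ValueError):
            cam.counterfactual_matrix(
                [scens[0], cam.ExposureScenario(np.zeros((3, 1)))], k)
        with pytest.raises(ValueError):
            cam.counterfactual_matrix([], k)

    def test_model_adapter_agrees_with_linear_truth(self, rng, linear_model):
        beta = np.array([0.8, -0.3])
        m = linear_model(beta, tau=3)
        E = rng.standard_normal((4, 8, 2))
        adapter = cam.ModelScenarioAdapter(m, None, E, None,
                                           node_index=1, time_index=5)
        traj = rng.standard_normal((3, 2))
        # lag-0 linear model: the response is the window's last row . beta
        assert adapter.response(traj) == pytest.approx([traj[-1] @ beta])


class TestSelectScenario:
    def test_micro_and_edge_cases(self):
        mat = cam.CounterfactualMatrix(values=np.array([[2.0, 5.0, 3.0]]))
        assert cam.select_scenario(mat, [3.5]) == 2
        single = cam.CounterfactualMatrix(values=np.array([[4.0]]))
        assert cam.select_scenario(single, [0.0]) == 0
        exact = cam.CounterfactualMatrix(values=np.array([[1.0, 7.0]]))
        assert cam.select_scenario(exact, [7.0]) == 1
        tie = cam.CounterfactualMatrix(values=np.array([[2.0, 4.0]]))
        assert cam.select_scenario(tie, [3.0]) == 0
        with pytest.raises(ValueError):
            cam.select_scenario(
                cam.CounterfactualMatrix(values=np.zeros((1, 0))), [0.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(1, 20), st.integers(1, 4), st.integers(0, 10_000))
    def test_matches_brute_force_minimum(self, K, q, seed):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((q, K))
        target = rng.standard_normal(q)
        got = cam.select_scenario(cam.CounterfactualMatrix(values=vals), target)
        dists = [np.linalg.norm(vals[:, k] - target) for k in range(K)]
        assert got == int(np.argmin(dists))


class TestSpatialAndMapOps:
    def test_laplacian_penalty_values_and_properties(self, rng):
        L = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert cam.laplacian_penalty(np.array([[1.0], [-1.0]]), L, 0.5) == \
            pytest.approx(2.0)
        assert cam.laplacian_penalty(np.array([[3.0], [3.0]]), L, 0.5) == \
            pytest.approx(0.0)
        assert cam.laplacian_penalty(rng.standard_normal((2, 1)), L, 0.0) == 0.0
        g = gx.build_adjacency(rng.uniform(0, 1, (7, 2)), 0.5, 2.0)
        H = rng.standard_normal((7, 3))
        assert cam.laplacian_penalty(H, g.laplacian, 1.0) >= 0.0
        assert cam.laplacian_penalty(np.tile(H[:1] * 0 + 2.5, (1, 1)).repeat(7, 0),
                                     g.laplacian, 1.0) == pytest.approx(0.0, abs=1e-10)

    def test_vulnerability_map_is_prior_weighted_sum(self):
        g = np.zeros((1, 2, 1))
        g[0, 0, 0], g[0, 1, 0] = 1.0, 2.0
        pri = cam.EpidemiologicalPriors(directions=[1, -1])
        assert np.allclose(cam.vulnerability_map(g, pri).values, [[-1.0]])
        zero = cam.EpidemiologicalPriors(directions=[0, 0])
        assert np.allclose(cam.vulnerability_map(g, zero).values, 0.0)
        single = cam.EpidemiologicalPriors(directions=[1])
        with pytest.raises(ValueError):
            cam.vulnerability_map(g, single)

    def test_vulnerability_linearity_in_gradients(self, rng):
        g1 = rng.uniform(0, 1, (5, 3, 4))
        g2 = rng.uniform(0, 1, (5, 3, 4))
        pri = cam.EpidemiologicalPriors(directions=[1, -1, 1])
        v1 = cam.vulnerability_map(g1, pri).values
        v2 = cam.vulnerability_map(g2, pri).values
        v12 = cam.vulnerability_map(g1 + 2 * g2, pri).values
        assert np.allclose(v12, v1 + 2 * v2, atol=1e-12)


class TestTotalLossAndTraining:
    def test_components_sum_and_micro_values(self, rng, linear_model):
        # weighted 18 + epi 0.4 + laplacian 2.0 = 20.4 assembled by hand
        m = linear_model(np.array([2.0]))
        weighted = cam.ipw_loss(np.array([1.0, 2.0]), np.zeros(2),
                                np.array([0.5, 0.25]), 0.0)
        epi = cam.epi_regularizer(m, rng.standard_normal((1, 4, 1)),
                                  cam.EpidemiologicalPriors([-1], 0.1), "eval")
        lap = cam.laplacian_penalty(np.array([[1.0], [-1.0]]),
                                    np.array([[1.0, -1.0], [-1.0, 1.0]]), 0.5)
        assert weighted + epi + lap == pytest.approx(20.4)

    def test_total_loss_breakdown_adds_up(self, rng):
        model, graph, E, ctx = _setup_training(rng)
        pred = gx.forward(E, ctx, graph, model)
        obs = rng.standard_normal(pred.shape)
        pi = rng.uniform(0.3, 0.7, E.shape[0])
        cfgs = cam.LossConfig(lambda_epi=0.1, mu_lap=0.2)
        priors = cam.EpidemiologicalPriors([1, -1], strength=0.1)
        total, comps = cam.total_loss(pred, obs, pi, model, priors, graph,
                                      cfgs, exposure_field=E, context=ctx)
        assert total == pytest.approx(
            comps["weighted"] + comps["epi"] + comps["laplacian"])
        assert comps["laplacian"] >= 0

    def test_zero_epochs_leaves_parameters_unchanged(self, rng):
        model, graph, E, ctx = _setup_training(rng)
        before = {k: v.data.copy() for k, v in model.params.items()}
        data = _training_data(rng, model, graph, E, ctx)
        cam.train(model, data, cam.LossConfig(), cam.OptimizerConfig(epochs=0))
        for k, v in model.params.items():
            assert np.array_equal(before[k], v.data)

    def test_fixed_seed_reproduces_loss_trace(self, rng):
        traces = []
        for _ in range(2):
            r = np.random.default_rng(77)
            model, graph, E, ctx = _setup_training(r)
            data = _training_data(r, model, graph, E, ctx)
            res = cam.train(model, data, cam.LossConfig(),
                            cam.OptimizerConfig(epochs=8, lr=1e-2))
            traces.append(res.loss_trace)
        assert np.array_equal(traces[0], traces[1])

    def test_training_reduces_loss_on_noiseless_linear_data(self):
        # convergence experiment: final loss under 1% of the initial loss
        out = gx.parameter_recovery_experiment()
        assert out["loss_ratio"] < 0.01

    def test_non_finite_loss_aborts_with_diagnostic(self, rng):
        model, graph, E, ctx = _setup_training(rng)
        data = _training_data(rng, model, graph, E, ctx)
        model.params["out_W"].data[:] = np.inf
        with pytest.raises(RuntimeError, match="diverged"):
            cam.train(model, data, cam.LossConfig(),
                      cam.OptimizerConfig(epochs=1))


def _setup_training(rng, N=6, T=10):
    cfg = gx.ModelConfig(d=4, diffusion_depth=1, tau=3, n_exposures=2,
                         n_outcomes=1, context_dim=2, policy_dim=1)
    model = gx.init_model(cfg, seed=5)
    graph = gx.build_adjacency(rng.uniform(0, 1, (N, 2)), 0.4, 1.5)
    E = rng.standard_normal((N, T, 2))
    ctx = gx.ContextSeries(values=rng.standard_normal((T, 2)),
                           policy=rng.standard_normal((T, 1)))
    return model, graph, E, ctx


def _training_data(rng, model, graph, E, ctx):
    Tprime = E.shape[1] - model.config.tau + 1
    H = gx.SpatioTemporalField(rng.standard_normal((E.shape[0], Tprime, 1)),
                               list(range(E.shape[0])),
                               np.arange(Tprime, dtype=float), ["h1"])
    Ef = gx.SpatioTemporalField(E, list(range(E.shape[0])),
                                np.arange(E.shape[1], dtype=float), ["e1", "e2"])
    return cam.TrainingData(exposure=Ef, outcomes=H, graph=graph, context=ctx)
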