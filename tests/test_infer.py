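import numpy as np
import pytest

import pepflux as pf
from conftest import linear_balance_solve


class TestExpectedAmounts:
    def test_single_event_hand_solution(self, toy_graph, toy_params):
        phi = pf.expected_amounts(toy_graph, toy_params)
        assert phi["AGAV"] == pytest.approx(10.0)
        assert phi["AG"] == pytest.approx(5.0)
        assert phi["AV"] == pytest.approx(2.0)

    @pytest.mark.parametrize("c", [1e-3, 0.5, 1.0, 7.0, 1e3])
    def test_joint_scale_invariance(self, toy_graph, toy_params, c):
        phi = pf.expected_amounts(toy_graph, toy_params)
        phi_scaled = pf.expected_amounts(toy_graph, toy_params.scaled(c))
        for k in phi:
            assert phi_scaled[k] == pytest.approx(phi[k], rel=1e-12)

    def test_matches_linear_solver_on_generated_graph(self, benchmark):
        gt = benchmark.truth
        oracle = linear_balance_solve(gt.graph, gt.z_true)
        for k, v in gt.phi_true.items():
            assert v == pytest.approx(oracle[k], rel=1e-10)

    def test_all_amounts_strictly_positive(self, benchmark):
        assert all(v > 0 for v in benchmark.truth.phi_true.values())

    def test_unpruned_graph_rejected(self):
        g = pf.CleavageGraph()
        g.add_event(pf.EventNode("AGAV", "AG", "AV", "p", 1.0))
        g.add_node("LKPQ", y=1.0)  # isolated: both source and leaf
        z = pf.ModelParameters({"AGAV": 1.0, "LKPQ": 1.0},
                               {"AG": 1.0, "AV": 1.0}, {"p": 1.0})
        with pytest.raises(ValueError, match="not pruned"):
            pf.expected_amounts(g, z)

    def test_wrong_parameter_domains_rejected(self, toy_graph):
        z = pf.ModelParameters({"AGAV": 1.0}, {"AG": 1.0}, {"p": 1.0})  # AV missing
        with pytest.raises(ValueError, match="domains"):
            pf.expected_amounts(toy_graph, z)


class TestBalanceResiduals:
    def test_zero_at_stationary_state(self, toy_graph, toy_params):
        phi = pf.expected_amounts(toy_graph, toy_params)
        res = pf.balance_residuals(toy_graph, toy_params, phi)
        assert max(abs(v) for v in res.values()) < 1e-12

    def test_perturbation_is_local(self, benchmark):
        gt = benchmark.truth
        base = pf.balance_residuals(gt.graph, gt.z_true, gt.phi_true)
        s, l, interior = pf.classify_nodes(gt.graph)
        v = sorted(interior)[0]
        phi = dict(gt.phi_true)
        phi[v] += 1.0
        perturbed = pf.balance_residuals(gt.graph, gt.z_true, phi)
        children = {p for e in gt.graph.out_events(v) for p in (e.prefix, e.suffix)}
        changed = {k for k in base
                   if abs(perturbed[k] - base[k]) > 1e-9 * (1 + abs(base[k]))}
        assert changed == {v} | children

    def test_empty_graph_empty_map(self):
        g = pf.CleavageGraph()
        z = pf.ModelParameters({}, {}, {"p": 1.0})
        assert pf.balance_residuals(g, z, {}) == {}


class TestObjective:
    def test_zero_vector_at_generating_parameters(self, chain_graph, chain_params):
        y = pf.expected_amounts(chain_graph, chain_params)
        assert np.allclose(pf.objective(chain_graph, chain_params, y), 0.0)

    def test_hand_example_residuals(self, chain_graph, chain_params):
        # hand-solved balance: phi = (10, 20, 10, 2) down the chain
        y = {"AGAGAV": 10.0, "AGAV": 20.0, "AG": 10.0, "AV": 2.0}
        assert np.allclose(pf.objective(chain_graph, chain_params, y), 0.0, atol=1e-12)

    def test_under_determined_rejected(self, toy_graph, toy_params):
        with pytest.raises(ValueError, match=r"under-determined: m=2 < n=4"):
            pf.objective(toy_graph, toy_params, {"AGAV": 10.0, "AG": 5.0})


class TestRelativeSquaredError:
    def test_perfect_prediction_is_zero(self):
        y = {"a": 1.0, "b": 2.0}
        assert pf.relative_squared_error(y, y) == 0.0

    def test_mean_predictor_is_one(self):
        y = {"a": 1.0, "b": 2.0, "c": 3.0}
        yhat = {k: 2.0 for k in y}
        assert pf.relative_squared_error(yhat, y) == pytest.approx(1.0)

    def test_hand_value(self):
        y = {"a": 1.0, "b": 2.0, "c": 3.0}
        yhat = {"a": 1.0, "b": 2.0, "c": 4.0}
        assert pf.relative_squared_error(yhat, y) == pytest.approx(0.5)

    def test_constant_observations_rejected(self):
        y = {"a": 2.0, "b": 2.0}
        with pytest.raises(ValueError, match="zero denominator"):
            pf.relative_squared_error(y, y)


class TestFit:
    def test_noiseless_self_consistency(self, benchmark):
        gt = benchmark.truth
        result = pf.fit(gt.graph, gt.phi_true, n_starts=7, max_iter=200, seed=0)
        assert result.rse < 1e-4
        assert result.converged

    def test_same_seed_bit_identical(self, benchmark):
        gt = benchmark.truth
        a = pf.fit(gt.graph, gt.phi_true, n_starts=3, max_iter=100, seed=11)
        b = pf.fit(gt.graph, gt.phi_true, n_starts=3, max_iter=100, seed=11)
        assert a.rse == b.rse
        assert a.z_hat.activities == b.z_hat.activities
        assert a.iterations_per_start == b.iterations_per_start

    def test_normalized_activities_seed_independent_on_noiseless_data(self, benchmark):
        gt = benchmark.truth
        profiles = []
        for seed in (0, 1):
            result = pf.fit(gt.graph, gt.phi_true, n_starts=7, max_iter=200, seed=seed)
            profile, _ = pf.normalize_activities(result.z_hat)
            profiles.append(profile.normalized)
        assert np.max(np.abs(profiles[0] - profiles[1])) < 1e-3

    def test_best_start_has_lowest_rse(self, benchmark):
        gt = benchmark.truth
        result = pf.fit(gt.graph, gt.phi_true, n_starts=5, max_iter=100, seed=2)
        assert result.rse == min(result.rse_per_start)
        assert result.rse_per_start[result.best_start_index] == result.rse

    def test_under_determined_rejected(self, toy_graph):
        with pytest.raises(ValueError, match="under-determined"):
            pf.fit(toy_graph, {"AGAV": 1.0, "AG": 2.0, "AV": 3.0})

    def test_result_json_round_trip(self, tmp_path, benchmark):
        gt = benchmark.truth
        result = pf.fit(gt.graph, gt.phi_true, n_starts=2, max_iter=50, seed=0)
        result.to_json(tmp_path / "fit.json")
        back = pf.FitResult.from_json(tmp_path / "fit.json")
        assert back.rse == result.rse
        assert back.z_hat.activities == result.z_hat.activities


class TestActivityIdentifiability:
    def test_true_activities_span_the_null_space(self, benchmark):
        gt = benchmark.truth
        m, peps = pf.activity_constraint_matrix(gt.graph, gt.phi_true)
        lam = np.array([gt.z_true.activities[p] for p in peps])
        # lambda_true satisfies every interior constraint...
        assert np.max(np.abs(m @ lam)) < 1e-9 * np.max(np.abs(m))
        # ...and is the only direction that does (rank |P| - 1)
        assert np.linalg.matrix_rank(m) == len(peps) - 1
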