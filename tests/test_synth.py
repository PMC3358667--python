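import numpy as np
import pytest

import pepflux as pf
from pepflux.profiles import AMINO_ACIDS, LOCI
from pepflux.synth import (
    Benchmark,
    generate_rt_model,
    generate_rt_training,
    write_benchmark,
)
from pepflux.msmatch import MatchConfig, match_peaks, train_rt_model
from conftest import linear_balance_solve


class TestFrequencyMatrixGenerator:
    def test_columns_sum_to_one(self):
        for fm in pf.generate_frequency_matrices(pf.SynthConfig(seed=3)):
            np.testing.assert_allclose(fm.f.sum(axis=0), 1.0)

    def test_deterministic_given_seed(self):
        a = pf.generate_frequency_matrices(pf.SynthConfig(seed=3))
        b = pf.generate_frequency_matrices(pf.SynthConfig(seed=3))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.f, y.f)

    def test_sharpness_concentrates_p1(self):
        cfg = pf.SynthConfig(seed=3, specificity_sharpness=1e6)
        j = LOCI.index("P1")
        for fm in pf.generate_frequency_matrices(cfg):
            assert fm.f[:, j].max() > 0.999

    def test_distinct_p1_preferences(self):
        j = LOCI.index("P1")
        doms = [fm.f[:, j].argmax() for fm in
                pf.generate_frequency_matrices(pf.SynthConfig(seed=3))]
        assert len(set(doms)) == len(doms)


class TestPrecursorGenerator:
    def test_length_range_respected(self):
        cfg = pf.SynthConfig(seed=4, precursor_length_range=(11, 11))
        assert all(len(s) == 11 for s in pf.generate_precursors(cfg))

    def test_alphabet_is_residues_only(self):
        for s in pf.generate_precursors(pf.SynthConfig(seed=4)):
            assert set(s) <= set(AMINO_ACIDS)

    def test_different_seeds_differ(self):
        a = pf.generate_precursors(pf.SynthConfig(seed=4))
        b = pf.generate_precursors(pf.SynthConfig(seed=5))
        assert a != b


class TestSimulateAmounts:
    def test_all_positive(self, benchmark):
        amounts = pf.simulate_amounts(benchmark.truth, 0.5, seed=9)
        assert all(v > 0 for v in amounts.values())

    def test_relative_noise_scale(self, benchmark):
        gt = benchmark.truth
        node = max(gt.phi_true, key=gt.phi_true.get)
        sigma = 0.1
        draws = [pf.simulate_amounts(gt, sigma, seed=s)[node] for s in range(2000)]
        sd = np.std(draws)
        assert sd == pytest.approx(sigma * gt.phi_true[node], rel=0.10)

    def test_deterministic_given_seed(self, benchmark):
        a = pf.simulate_amounts(benchmark.truth, 0.01, seed=5)
        b = pf.simulate_amounts(benchmark.truth, 0.01, seed=5)
        assert a == b

    def test_absolute_sigma_mode(self, benchmark):
        gt = benchmark.truth
        a = pf.simulate_amounts(gt, 1e-9, seed=3, absolute=True)
        for k, v in a.items():
            assert v == pytest.approx(gt.phi_true[k], abs=1e-6)


class TestSimulatePeaklist:
    def test_zero_noise_round_trip_recovers_amounts(self, benchmark):
        amounts = benchmark.datasets[0.01]
        rtm = train_rt_model(generate_rt_training(generate_rt_model(2), n=30, seed=3))
        peaks = pf.simulate_peaklist(amounts, rtm, coordinate_noise=(0.0, 0.0), seed=1)
        recovered = match_peaks(sorted(amounts), peaks, rtm, MatchConfig())
        assert recovered == pytest.approx(amounts)

    def test_peaks_within_scan_range(self, benchmark):
        rtm = generate_rt_model(2)
        peaks = pf.simulate_peaklist(benchmark.datasets[0.01], rtm, seed=1,
                                     scan_range=(100.0, 2000.0))
        assert all(100.0 <= p.mz <= 2000.0 for p in peaks)

    def test_deterministic_given_seed(self, benchmark):
        rtm = generate_rt_model(2)
        a = pf.simulate_peaklist(benchmark.datasets[0.01], rtm,
                                 coordinate_noise=(5.0, 0.2), seed=4)
        b = pf.simulate_peaklist(benchmark.datasets[0.01], rtm,
                                 coordinate_noise=(5.0, 0.2), seed=4)
        assert a == b


class TestGillespie:
    def test_toy_graph_means_match_balance_solution(self, toy_graph, toy_params):
        phi = pf.expected_amounts(toy_graph, toy_params)
        sim = pf.gillespie_stationary_means(toy_graph, toy_params,
                                            horizon=800.0, burn_in=80.0, seed=2)
        for k, (mean, se) in sim.items():
            assert abs(mean - phi[k]) < 3.0 * se

    def test_negligible_creation_empties_network(self, toy_graph):
        z = pf.ModelParameters({"AGAV": 1e-9}, {"AG": 1.0, "AV": 1.0}, {"pep": 1.0})
        sim = pf.gillespie_stationary_means(toy_graph, z, horizon=200.0,
                                            burn_in=20.0, seed=2)
        assert all(mean < 1e-3 for mean, _ in sim.values())

    def test_longer_horizon_shrinks_standard_errors(self, toy_graph, toy_params):
        short = pf.gillespie_stationary_means(toy_graph, toy_params,
                                              horizon=150.0, burn_in=30.0, seed=3)
        long = pf.gillespie_stationary_means(toy_graph, toy_params,
                                             horizon=1200.0, burn_in=30.0, seed=3)
        mean_se = lambda sim: np.mean([se for _, se in sim.values()])
        assert mean_se(long) < mean_se(short)


class TestBenchmark:
    def test_well_posedness_guarantees(self, benchmark):
        g = benchmark.truth.graph
        assert not (g.sources() & g.leaves())
        m = len(g.nodes)
        n = len(g.sources()) + len(g.leaves()) + len(g.peptidases())
        assert m >= n
        assert set(benchmark.datasets) == {0.1, 0.01, 0.001}

    def test_phi_true_consistent_with_parameters(self, benchmark):
        gt = benchmark.truth
        oracle = linear_balance_solve(gt.graph, gt.z_true)
        for k, v in gt.phi_true.items():
            assert v == pytest.approx(oracle[k], rel=1e-10)

    def test_reproducible_given_config(self, benchmark):
        again = pf.make_benchmark(pf.SynthConfig(seed=1))
        assert again.truth.graph == benchmark.truth.graph
        assert again.datasets == benchmark.datasets

    def test_directory_round_trip(self, tmp_path, benchmark):
        write_benchmark(benchmark, tmp_path)
        back = pf.CleavageGraph.from_json(tmp_path / "graph.json")
        assert back == benchmark.truth.graph
        from pepflux.profiles import read_frequency_matrices
        matrices = read_frequency_matrices(tmp_path / "matrices")
        assert [m.peptidase_id for m in matrices] == \
            [m.peptidase_id for m in benchmark.matrices]
        assert (tmp_path / "peaks.tsv").exists()
        assert (tmp_path / "precursors.fasta").exists()
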