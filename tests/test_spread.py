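import math

import networkx as nx
import numpy as np
import pytest

from glinet import (
    SpreadParams,
    all_spreading_powers,
    meanfield_sir,
    si_infection_rate,
    simulate_si,
    simulate_sir,
    spreading_power,
    topk_infection_curve,
)


class TestParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"alpha": -0.1},
            {"alpha": 1.5},
            {"beta": 2.0},
            {"max_steps": 0},
            {"iterations": 0},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            SpreadParams(**kw)

    def test_si_benchmark_rate(self):
        assert si_infection_rate() == 0.125
        assert si_infection_rate(1) == 0.5


class TestSir:
    def test_seed_validation(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            simulate_sir(g, [], rng=0)
        with pytest.raises(KeyError):
            simulate_sir(g, [99], rng=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_compartment_conservation_every_step(self, seed):
        g = nx.gnp_random_graph(40, 0.1, seed=seed)
        params = SpreadParams(alpha=0.4, beta=0.3, max_steps=50)
        traj = simulate_sir(g, [0, 1], params, rng=seed)
        assert np.all(traj.total == g.number_of_nodes())
        assert np.all(np.diff(traj.removed) >= 0)
        assert np.all(np.diff(traj.susceptible) <= 0)

    def test_no_transmission_when_alpha_zero(self):
        g = nx.complete_graph(10)
        traj = simulate_sir(g, [0, 1], SpreadParams(alpha=0.0, beta=1.0), rng=0)
        assert traj.infected.max() == 2
        assert traj.removed[-1] == 2

    def test_certain_transmission_wave_on_path(self):
        """alpha=1, beta=1 on a-b-c seeded at a: b at t1, c at t2, all removed."""
        g = nx.Graph([("a", "b"), ("b", "c")])
        traj = simulate_sir(g, ["a"], SpreadParams(alpha=1.0, beta=1.0, max_steps=10), rng=0)
        assert traj.infected.tolist() == [1, 1, 1, 0]
        assert traj.removed.tolist() == [0, 1, 2, 3]

    def test_fixed_seed_is_bit_reproducible(self):
        g = nx.gnp_random_graph(30, 0.2, seed=2)
        params = SpreadParams(alpha=0.3, beta=0.5, max_steps=40)
        a = simulate_sir(g, [0], params, rng=123)
        b = simulate_sir(g, [0], params, rng=123)
        assert a.to_frame().equals(b.to_frame())


class TestSi:
    def test_bfs_layers_when_alpha_one(self):
        g = nx.path_graph(6)
        traj = simulate_si(g, [0], SpreadParams(alpha=1.0, max_steps=10), rng=0)
        # ball of radius t around the seed
        assert traj.infected.tolist()[:6] == [1, 2, 3, 4, 5, 6]

    @pytest.mark.parametrize("seed", range(3))
    def test_monotone_and_no_removal(self, seed):
        g = nx.gnp_random_graph(30, 0.15, seed=seed)
        traj = simulate_si(g, [0], rng=seed)  # default benchmark rate 0.125
        assert np.all(np.diff(traj.infected) >= 0)
        assert np.all(traj.removed == 0)
        assert np.all(traj.total == 30)


class TestMeanfield:
    def test_no_infected_means_constant(self):
        traj = meanfield_sir(100, 0, 0, alpha=0.05, beta=0.4, steps=10)
        assert np.all(traj.susceptible == 100) and np.all(traj.removed == 0)

    def test_one_step_increments(self):
        """From (99, 1, 0) with alpha=0.01, beta=1: dS=-0.99, dI=-0.01, dR=1."""
        traj = meanfield_sir(99, 1, 0, alpha=0.01, beta=1.0, steps=1)
        assert traj.susceptible[1] == pytest.approx(99 - 0.99)
        assert traj.infected[1] == pytest.approx(1 + 0.99 - 1.0)
        assert traj.removed[1] == pytest.approx(1.0)

    @pytest.mark.parametrize("alpha,beta", [(0.0005, 1.0), (0.001, 0.3)])
    def test_total_conserved_exactly(self, alpha, beta):
        # parameters inside the stable regime (alpha * population < 1)
        traj = meanfield_sir(500, 5, 2, alpha=alpha, beta=beta, steps=50)
        assert traj.total == pytest.approx(507, abs=1e-9)


class TestSpreadingPower:
    def test_isolated_node_scores_exactly_one(self):
        g = nx.star_graph(3)
        g.add_node("iso")
        params = SpreadParams(alpha=0.5, beta=1.0, iterations=50)
        assert spreading_power(g, "iso", "sir", params, rng=0) == 1.0

    def test_alpha_zero_scores_exactly_one(self):
        g = nx.complete_graph(8)
        params = SpreadParams(alpha=0.0, beta=1.0, iterations=20)
        assert all(spreading_power(g, v, "sir", params, rng=0) == 1.0 for v in g)

    def test_single_edge_final_size_law(self):
        """On one edge with beta=1 the final size is 1 w.p. 1-alpha, 2 w.p. alpha."""
        g = nx.path_graph(2)
        alpha, runs = 0.3, 10_000
        params = SpreadParams(alpha=alpha, beta=1.0, iterations=runs)
        mean = spreading_power(g, 0, "sir", params, rng=42)
        sigma = math.sqrt(alpha * (1 - alpha) / runs)
        assert abs(mean - (1 + alpha)) < 3 * sigma

    def test_star_hub_mean_and_dominance(self):
        """Hub of a k-star at beta=1 infects each leaf once: mean 1 + k*alpha."""
        k, alpha, runs = 8, 0.05, 10_000
        g = nx.star_graph(k)
        params = SpreadParams(alpha=alpha, beta=1.0, iterations=runs)
        hub = spreading_power(g, 0, "sir", params, rng=7)
        sigma = math.sqrt(k * alpha * (1 - alpha) / runs)
        assert abs(hub - (1 + k * alpha)) < 3 * sigma
        leaf = spreading_power(g, 1, "sir", params, rng=8)
        assert hub > leaf

    def test_unknown_node_and_model(self):
        g = nx.path_graph(3)
        with pytest.raises(KeyError):
            spreading_power(g, 99, "sir", SpreadParams(iterations=1), rng=0)
        with pytest.raises(ValueError):
            spreading_power(g, 0, "seir", SpreadParams(iterations=1), rng=0)

    def test_all_powers_reproducible_under_experiment_seed(self):
        g = nx.gnp_random_graph(25, 0.15, seed=4)
        params = SpreadParams(alpha=0.1, beta=1.0, iterations=50, seed=99)
        assert all_spreading_powers(g, "sir", params).equals(
            all_spreading_powers(g, "sir", params)
        )


class TestTopkCurve:
    def test_alpha_zero_constant(self):
        g = nx.complete_graph(10)
        params = SpreadParams(alpha=0.0, beta=1.0, max_steps=5, iterations=10)
        curve = topk_infection_curve(g, [0, 1, 2], params, rng=0)
        assert (curve == 3.0).all()

    def test_monotone_nondecreasing(self):
        g = nx.gnp_random_graph(40, 0.1, seed=5)
        params = SpreadParams(alpha=0.2, beta=1.0, max_steps=15, iterations=100)
        curve = topk_infection_curve(g, [0, 1], params, rng=1)
        assert (curve.diff().dropna() >= -1e-12).all()

    def test_saturates_within_diameter_at_certain_transmission(self):
        g = nx.gnp_random_graph(30, 0.3, seed=6)
        assert nx.is_connected(g)
        diam = nx.diameter(g)
        params = SpreadParams(alpha=1.0, beta=1.0, max_steps=diam + 2, iterations=3)
        curve = topk_infection_curve(g, [0], params, rng=2)
        assert curve.iloc[diam] == 30.0
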