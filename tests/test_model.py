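import math

import numpy as np
import pytest
import sympy
from scipy.stats import kstest

from netdim.model import (ModelParams, angular_distance, compute_mu,
                          compute_radius, connection_probability,
                          ensemble_mean_degree, generate_network, refine_mu,
                          sample_edge_arrays, sample_hidden_degrees,
                          sample_positions)


def _radius_sympy(N, D):
    expr = (N * sympy.gamma(sympy.Rational(D + 1, 2))
            / (2 * sympy.pi ** sympy.Rational(D + 1, 2))) ** sympy.Rational(1, D)
    return float(expr.evalf(30))


class TestClosedForms:
    @pytest.mark.parametrize("N,D", [(1000, 1), (1000, 2), (500, 3), (2000, 7)])
    def test_radius_matches_high_precision_evaluation(self, N, D):
        assert compute_radius(N, D) == pytest.approx(_radius_sympy(N, D), rel=1e-12)

    def test_radius_d1_is_circle_circumference(self):
        assert compute_radius(1000, 1) == pytest.approx(1000 / (2 * math.pi))

    def test_radius_rejects_bad_parameters(self):
        for N, D in [(1, 1), (10, 0), (10.5, 1)]:
            with pytest.raises(ValueError):
                compute_radius(N, D)

    def test_mu_symbolic_values(self):
        # beta=2, D=1: 2*Gamma(1/2)*sin(pi/2) / (2*pi^(3/2)*10) = 1/(10*pi)
        assert compute_mu(2.0, 1, 10.0) == pytest.approx(1 / (10 * math.pi))
        # beta -> inf limit at D=1: Gamma(3/2)/(sqrt(pi)*10) = 1/20
        assert compute_mu(math.inf, 1, 10.0) == pytest.approx(0.05)

    @pytest.mark.parametrize("D", [1, 2, 3, 5])
    def test_mu_converges_to_zero_temperature_limit(self, D):
        assert compute_mu(1e7, D, 10.0) == pytest.approx(
            compute_mu(math.inf, D, 10.0), rel=1e-5)

    def test_mu_rejects_beta_at_or_below_d(self):
        with pytest.raises(ValueError):
            compute_mu(2.0, 2, 10.0)
        with pytest.raises(ValueError):
            compute_mu(1.0, 1, 10.0)

    def test_model_params_derives_invariants(self):
        p = ModelParams(N=1000, D=3, beta=5.0, mean_degree=10.0)
        assert p.R == pytest.approx(compute_radius(1000, 3))
        assert p.mu == pytest.approx(compute_mu(5.0, 3, 10.0))
        assert p.small_world  # beta < 2D
        with pytest.raises(ValueError):
            ModelParams(N=1000, D=3, beta=2.5, mean_degree=10.0)


class TestPositions:
    def test_unit_norm(self):
        x = sample_positions(500, 4, seed=0)
        assert np.allclose(np.linalg.norm(x, axis=1), 1.0, atol=1e-12)

    def test_circle_angles_uniform(self):
        x = sample_positions(10_000, 1, seed=1)
        phi = np.mod(np.arctan2(x[:, 1], x[:, 0]), 2 * math.pi)
        assert kstest(phi, "uniform", args=(0, 2 * math.pi)).pvalue > 0.01

    def test_mean_pairwise_dot_is_zero(self):
        x = sample_positions(1000, 2, seed=2)
        dots = (x @ x.T)[np.triu_indices(1000, 1)]
        se = dots.std() / math.sqrt(dots.size)
        assert abs(dots.mean()) < 3 * se + 1e-3

    def test_angular_distance_identities(self):
        v = np.array([1.0, 0.0, 0.0])
        w = np.array([0.0, 1.0, 0.0])
        assert angular_distance(v, v) == 0.0
        assert angular_distance(v, -v) == pytest.approx(math.pi)
        assert angular_distance(v, w) == pytest.approx(math.pi / 2)
        with pytest.raises(ValueError):
            angular_distance(v, np.array([1.0, 0.0]))


class TestConnectionLaw:
    def setup_method(self):
        self.p = ModelParams(N=1000, D=1, beta=4.0, mean_degree=10.0)

    def test_fermi_level_is_one_half(self):
        # chi = 1 at dtheta = (mu k_i k_j) / R for D=1
        dtheta = self.p.mu * 10 * 10 / self.p.R
        assert connection_probability(10, 10, dtheta, self.p) == pytest.approx(0.5)

    def test_zero_distance_connects(self):
        assert connection_probability(1, 1, 0.0, self.p) == 1.0

    def test_zero_temperature_step(self):
        p_inf = ModelParams(N=1000, D=1, beta=math.inf, mean_degree=10.0)
        dtheta_star = p_inf.mu * 100 / p_inf.R
        assert connection_probability(10, 10, 0.99 * dtheta_star, p_inf) == 1.0
        assert connection_probability(10, 10, 1.01 * dtheta_star, p_inf) == 0.0

    @pytest.mark.parametrize("scale,expect_increasing", [(0.5, True), (2.0, False)])
    def test_sharpening_is_monotone_in_beta(self, scale, expect_increasing):
        # raising beta raises p below the Fermi level (chi<1), lowers it above
        dtheta_star = self.p.mu * 100 / self.p.R
        probs = [connection_probability(
            10, 10, scale * dtheta_star,
            ModelParams(N=1000, D=1, beta=b, mean_degree=10.0))
            for b in (2.0, 4.0, 8.0, 16.0)]
        diffs = np.diff(probs)
        assert np.all(diffs > 0) if expect_increasing else np.all(diffs < 0)


class TestHiddenDegrees:
    def test_mean_matches_target(self):
        k = sample_hidden_degrees(100_000, 2.7, 10.0, seed=3)
        se = k.std() / math.sqrt(k.size)
        assert abs(k.mean() - 10.0) < 3 * se

    def test_support_lower_bound(self):
        k = sample_hidden_degrees(10_000, 2.5, 10.0, seed=4)
        kappa0 = 10.0 * 0.5 / 1.5
        assert k.min() >= kappa0

    def test_tail_exponent(self):
        gamma = 2.5
        k = np.sort(sample_hidden_degrees(100_000, gamma, 10.0, seed=5))
        # CCDF slope on log-log should be -(gamma-1); fit the inner tail
        ccdf = 1.0 - np.arange(1, k.size + 1) / k.size
        sel = slice(int(0.5 * k.size), int(0.999 * k.size))
        slope = np.polyfit(np.log(k[sel]), np.log(ccdf[sel]), 1)[0]
        assert slope == pytest.approx(-(gamma - 1), abs=0.1)

    def test_gamma_at_most_two_rejected(self):
        with pytest.raises(ValueError):
            sample_hidden_degrees(100, 2.0, 10.0, seed=0)


class TestGeneration:
    def test_graph_shape_and_determinism(self):
        p = ModelParams(N=300, D=2, beta=4.0, mean_degree=8.0)
        k = sample_hidden_degrees(300, 2.7, 8.0, seed=6)
        g1 = generate_network(p, k, seed=7)
        g2 = generate_network(p, k, seed=7)
        assert g1.number_of_nodes() == 300
        assert not any(u == v for u, v in g1.edges())
        assert set(g1.edges()) == set(g2.edges())
        assert g1.nodes[0]["kappa"] == k[0]
        g3 = generate_network(p, k, seed=8)
        assert set(g3.edges()) != set(g1.edges())

    def test_edge_count_matches_sum_of_probabilities(self):
        # edge indicators are independent Bernoulli: total count over many
        # seeds matches the analytic expectation within binomial error
        N = 60
        p = ModelParams(N=N, D=1, beta=3.0, mean_degree=6.0)
        k = sample_hidden_degrees(N, 2.7, 6.0, seed=9)
        pos = sample_positions(N, 1, seed=10)
        iu, ju = np.triu_indices(N, 1)
        probs = np.array([
            connection_probability(k[a], k[b],
                                   angular_distance(pos[a], pos[b]), p)
            for a, b in zip(iu, ju)])
        counts = [sample_edge_arrays(p, k, seed=s, positions=pos)[0].size
                  for s in range(300)]
        expected = probs.sum()
        sd = math.sqrt(np.sum(probs * (1 - probs)) / 300)
        assert abs(np.mean(counts) - expected) < 4 * sd

    def test_refined_mean_degree_hits_target(self):
        vals = []
        for s in range(3):
            k = sample_hidden_degrees(1000, 2.7, 10.0, seed=100 + s)
            p = refine_mu(k, ModelParams(N=1000, D=3, beta=math.inf,
                                         mean_degree=10.0))
            assert ensemble_mean_degree(k, p) == pytest.approx(10.0, abs=0.02)
            eu, _, _ = sample_edge_arrays(p, k, seed=200 + s)
            vals.append(2 * eu.size / 1000)
        assert np.mean(vals) == pytest.approx(10.0, abs=0.3)

    def test_degree_tracks_hidden_degree(self):
        # nodes binned by kappa realize mean degrees close to kappa when mu
        # is refined to this draw's own mean (kappa = expected degree)
        rng = np.random.default_rng(11)
        k = sample_hidden_degrees(1000, 2.7, 10.0, seed=rng)
        p = refine_mu(k, ModelParams(N=1000, D=2, beta=math.inf,
                                     mean_degree=10.0), target=float(k.mean()))
        deg_sum = np.zeros(1000)
        n_reals = 10
        for _ in range(n_reals):
            eu, ev, _ = sample_edge_arrays(p, k, seed=rng)
            deg_sum += np.bincount(np.concatenate([eu, ev]), minlength=1000)
        mean_deg = deg_sum / n_reals
        order = np.argsort(k)
        for chunk in np.array_split(order, 10):
            kappa_bin = k[chunk].mean()
            deg_bin = mean_deg[chunk].mean()
            se = math.sqrt(kappa_bin / (chunk.size * n_reals))
            assert abs(deg_bin - kappa_bin) < 4 * se + 0.05 * kappa_bin
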