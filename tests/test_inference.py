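import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from netdim.cycles import CyclePhasePoint
from netdim.inference import (SurrogateRecord, build_surrogate_ensemble,
                              classify_dimension, default_k_grid,
                              estimate_accuracy, optimize_k,
                              phase_space_scan)
from netdim.model import (ModelParams, refine_mu, sample_edge_arrays,
                          sample_hidden_degrees)
from netdim.cycles import phase_point_from_edges


def _phase(ct, cs, cp):
    return CyclePhasePoint(C_t=ct, C_s=cs, C_p=cp, C=0.0, n_edges_eligible=1)


def _records(X, y):
    return [SurrogateRecord(D=int(d), beta=float(d) + 1.0,
                            phase=_phase(*row), seed=0)
            for row, d in zip(X, y)]


def brute_force_vote(query, X, y, K):
    """Independent recomputation of the distance-weighted frequency f(D)."""
    d = np.sqrt(np.sum((X - query) ** 2, axis=1))
    order = np.argsort(d, kind="stable")[:K]
    dk, yk = d[order], y[order]
    if np.any(dk == 0):
        w = (dk == 0).astype(float)
    else:
        w = 1.0 / dk
    w /= w.sum()
    f = {}
    for wi, di in zip(w, yk):
        f[int(di)] = f.get(int(di), 0.0) + wi
    return f


class TestClassify:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_vote_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        X = rng.random((n, 3))
        y = rng.integers(1, 4, size=n)
        if np.unique(y).size < 2:
            return
        K = int(rng.integers(1, n + 1))
        query = rng.random(3)
        est = classify_dimension(_phase(*query), _records(X, y), K)
        expected = brute_force_vote(query, X, y, K)
        for d, val in expected.items():
            assert est.f.get(d, 0.0) == pytest.approx(val, abs=1e-9)
        assert sum(est.f.values()) == pytest.approx(1.0, abs=1e-12)
        top = max(expected.values())
        assert est.D_star == min(d for d, v in expected.items()
                                 if np.isclose(v, top))

    def test_k1_returns_nearest_label(self):
        X = np.array([[0.1, 0.1, 0.1], [0.9, 0.9, 0.9]])
        y = np.array([2, 3])
        est = classify_dimension(_phase(0.2, 0.2, 0.2), _records(X, y), 1)
        assert est.D_star == 2 and est.f[2] == 1.0

    def test_coincident_surrogate_takes_all_weight(self):
        X = np.array([[0.3, 0.2, 0.1], [0.31, 0.2, 0.1], [0.5, 0.5, 0.5]])
        y = np.array([4, 1, 2])
        est = classify_dimension(_phase(0.3, 0.2, 0.1), _records(X, y), 3)
        assert est.D_star == 4
        assert est.f[4] == pytest.approx(1.0)

    def test_vote_invariant_under_distance_rescaling(self):
        rng = np.random.default_rng(40)
        X = rng.random((12, 3))
        y = rng.integers(1, 4, size=12)
        q = np.array([0.4, 0.3, 0.2])
        f1 = classify_dimension(_phase(*q), _records(X, y), 5).f
        # scale all surrogates radially around the query by a constant
        X2 = q + 3.0 * (X - q)
        f2 = classify_dimension(_phase(*q), _records(X2, y), 5).f
        for d in f1:
            assert f1[d] == pytest.approx(f2[d], abs=1e-12)

    def test_k_larger_than_ensemble_rejected(self):
        X = np.array([[0.1, 0.1, 0.1], [0.2, 0.2, 0.2]])
        with pytest.raises(ValueError):
            classify_dimension(_phase(0, 0, 0), _records(X, [1, 2]), 3)


class TestKSelection:
    def test_separated_clusters_reach_perfect_accuracy(self):
        rng = np.random.default_rng(41)
        X = np.vstack([rng.normal(0.2, 0.005, (15, 3)),
                       rng.normal(0.8, 0.005, (15, 3))])
        y = np.array([1] * 15 + [2] * 15)
        recs = _records(X, y)
        k, accs = optimize_k(recs)
        assert accs[k] == 1.0
        assert k == min(kk for kk, a in accs.items() if a == 1.0)
        assert estimate_accuracy(recs, k) == 1.0

    def test_random_labels_on_identical_points_near_chance(self):
        rng = np.random.default_rng(42)
        X = np.full((60, 3), 0.5) + rng.normal(0, 1e-12, (60, 3))
        y = np.tile([1, 2, 3], 20)
        acc = estimate_accuracy(_records(X, y), 7)
        assert 0.1 < acc < 0.6

    def test_selected_k_maximizes_loo_accuracy(self):
        rng = np.random.default_rng(43)
        X = rng.random((25, 3))
        y = rng.integers(1, 4, size=25)
        recs = _records(X, y)
        k, accs = optimize_k(recs)
        # exhaustive check over the same grid with per-point brute force
        for kk in default_k_grid(24):
            correct = 0
            for i in range(25):
                mask = np.arange(25) != i
                f = brute_force_vote(X[i], X[mask], y[mask], kk)
                top = max(f.values())
                pred = min(d for d, v in f.items() if np.isclose(v, top))
                correct += pred == y[i]
            assert accs[kk] == pytest.approx(correct / 25)
        assert accs[k] == max(accs.values())

    def test_single_label_ensemble_warns(self):
        X = np.random.default_rng(44).random((8, 3))
        with pytest.warns(UserWarning):
            k, _ = optimize_k(_records(X, [2] * 8))
        assert k == 1


class TestEnsemble:
    def test_ensemble_contract_on_synthetic_graph(self):
        rng = np.random.default_rng(45)
        N = 400
        k = sample_hidden_degrees(N, 2.7, 10.0, seed=rng)
        p = refine_mu(k, ModelParams(N=N, D=1, beta=3.0, mean_degree=10.0))
        eu, ev, _ = sample_edge_arrays(p, k, seed=rng)
        degs = np.bincount(np.concatenate([eu, ev]), minlength=N)
        keep = degs > 0
        relabel = np.cumsum(keep) - 1
        phase = phase_point_from_edges(int(keep.sum()), relabel[eu], relabel[ev])
        ens = build_surrogate_ensemble(degs[keep], phase, n_per_dim=8,
                                       d_cap=3, n_reals_dmax=4, seed=46)
        assert 0 < len(ens.records) <= ens.d_max * 8
        for rec in ens.records:
            assert rec.beta > rec.D
            assert 0 <= rec.phase.C_t <= 1
        cts = np.array([r.phase.C_t for r in ens.records])
        # surrogate clustering concentrates in the sampled window
        assert abs(np.median(cts) - phase.C_t) < 0.15

    def test_triangle_free_graph_shortcuts_to_dimension_one(self):
        phase = CyclePhasePoint(0.0, 0.3, 0.1, 0.0, 10)
        with pytest.warns(UserWarning):
            ens = build_surrogate_ensemble(np.array([2] * 50), phase, seed=0)
        assert ens.anomalous and ens.d_max == 1 and not ens.records


class TestPhaseSpace:
    def test_clustering_grows_with_beta_and_curves_separate(self):
        scan = phase_space_scan(2.7, [1, 3], [1.4, 1.8, 2.5, 3.5, 5.0],
                                N=1000, n_reals=5, seed=47)
        for D in (1, 3):
            sub = scan[scan.D == D].sort_values("beta")
            cts = sub["C_t"].to_numpy()
            sems = sub["C_t_sem"].to_numpy()
            slack = 2 * np.sqrt(sems[1:] ** 2 + sems[:-1] ** 2)
            assert np.all(np.diff(cts) > -slack)
        # at matched C_t = 0.4 the square density differs across dimensions
        interp, sems = {}, {}
        for D in (1, 3):
            sub = scan[scan.D == D].sort_values("C_t")
            interp[D] = np.interp(0.4, sub["C_t"], sub["C_s"])
            sems[D] = np.interp(0.4, sub["C_t"], sub["C_s_sem"])
        gap = abs(interp[1] - interp[3])
        assert gap > 2 * np.hypot(sems[1], sems[3])
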