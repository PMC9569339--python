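"""Scikit-learn style estimator wrapping the full inference pipeline."""

from __future__ import annotations

import numpy as np
import networkx as nx
from sklearn.base import BaseEstimator

from .cycles import phase_point, phase_point_from_edges
from .inference import (build_surrogate_ensemble, classify_dimension,
                        estimate_accuracy, optimize_k)

__all__ = ["LatentDimensionKNN"]


class LatentDimensionKNN(BaseEstimator):
    """Infer the latent similarity dimension of an undirected network.

    ``fit`` takes a single graph: it measures the graph's chordless-cycle
    phase point, builds a degree-matched S^D surrogate ensemble across the
    feasible (D, beta) range, selects K by leave-one-out accuracy and
    stores the distance-weighted K-NN vote.  ``predict`` classifies further
    graphs against the fitted ensemble (their phase points are computed and
    voted on with the fitted K).

    Parameters
    ----------
    n_surrogates_per_dim : surrogates generated per candidate dimension.
    delta_ct : half-width of the clustering window sampled around the
        observed edge-triangle density.
    tolerance : convergence threshold of the hidden-degree iteration.
    max_iter : iteration cap of the hidden-degree fixed point.
    d_cap : hard cap on the scanned dimension.
    n_reals_dmax : realizations per dimension in the max-dimension scan.
    k_grid : neighbour counts tried during K selection (default odd 1..25).
    random_state : seed for every stochastic stage.

    Attributes
    ----------
    dimension_ : inferred dimension D*.
    frequencies_ : weighted K-NN frequency profile f(D), summing to 1.
    k_ : selected neighbour count.
    accuracy_ : leave-one-out surrogate accuracy at ``k_``.
    d_max_ : largest dimension able to reproduce the observed clustering.
    phase_point_ : the input graph's (C_t, C_s, C_p, C) summary.
    ensemble_ : the EnsembleResult with all surrogate records.
    anomalous_ : True when the cycle statistics are unreachable by the
        model in any dimension (dimension_ is then 1).
    """

    def __init__(self, n_surrogates_per_dim: int = 50, delta_ct: float = 0.1,
                 tolerance: float = 1.0, max_iter: int = 200, d_cap: int = 12,
                 n_reals_dmax: int = 10, k_grid=None, random_state=None):
        self.n_surrogates_per_dim = n_surrogates_per_dim
        self.delta_ct = delta_ct
        self.tolerance = tolerance
        self.max_iter = max_iter
        self.d_cap = d_cap
        self.n_reals_dmax = n_reals_dmax
        self.k_grid = k_grid
        self.random_state = random_state

    @staticmethod
    def _as_edges(G) -> tuple[int, np.ndarray, np.ndarray]:
        if isinstance(G, nx.Graph):
            nodes = list(G.nodes())
            relabel = {u: i for i, u in enumerate(nodes)}
            eu = np.fromiter((relabel[u] for u, _ in G.edges()), dtype=np.int64,
                             count=G.number_of_edges())
            ev = np.fromiter((relabel[v] for _, v in G.edges()), dtype=np.int64,
                             count=G.number_of_edges())
            return len(nodes), eu, ev
        n, eu, ev = G
        return int(n), np.asarray(eu, np.int64), np.asarray(ev, np.int64)

    def fit(self, G, y=None) -> "LatentDimensionKNN":
        """Run the full pipeline on one graph (networkx or (n, eu, ev))."""
        n, eu, ev = self._as_edges(G)
        degrees = np.bincount(np.concatenate([eu, ev]), minlength=n)
        keep = degrees > 0
        if not keep.all():
            relabel = np.cumsum(keep) - 1
            eu, ev = relabel[eu], relabel[ev]
            degrees = degrees[keep]
            n = int(keep.sum())
        self.n_nodes_ = n
        self.phase_point_ = phase_point_from_edges(n, eu, ev)
        self.ensemble_ = build_surrogate_ensemble(
            degrees, self.phase_point_,
            n_per_dim=self.n_surrogates_per_dim, delta_ct=self.delta_ct,
            tolerance=self.tolerance, max_iter=self.max_iter,
            d_cap=self.d_cap, n_reals_dmax=self.n_reals_dmax,
            seed=self.random_state)
        self.d_max_ = self.ensemble_.d_max
        self.anomalous_ = self.ensemble_.anomalous
        if self.anomalous_:
            self.dimension_ = 1
            self.frequencies_ = {1: 1.0}
            self.k_ = 1
            self.accuracy_ = float("nan")
            return self
        self.k_, self.k_accuracies_ = optimize_k(self.ensemble_,
                                                 k_grid=self.k_grid)
        est = classify_dimension(self.phase_point_, self.ensemble_, self.k_)
        self.accuracy_ = estimate_accuracy(self.ensemble_, self.k_)
        self.dimension_ = est.D_star
        self.frequencies_ = est.f
        self.distances_ = est.distances
        return self

    def predict(self, graphs) -> np.ndarray:
        """Dimension labels for further graphs, voted on the fitted ensemble."""
        if not hasattr(self, "ensemble_"):
            raise RuntimeError("estimator is not fitted")
        if self.anomalous_:
            raise RuntimeError("anomalous fit: no surrogate ensemble available")
        if isinstance(graphs, nx.Graph):
            graphs = [graphs]
        out = []
        for G in graphs:
            if isinstance(G, nx.Graph):
                pp = phase_point(G)
            else:
                n, eu, ev = self._as_edges(G)
                pp = phase_point_from_edges(n, eu, ev)
            out.append(classify_dimension(pp, self.ensemble_, self.k_).D_star)
        return np.asarray(out)

    def report(self) -> dict:
        """JSON-serializable summary of a fitted estimator."""
        if not hasattr(self, "dimension_"):
            raise RuntimeError("estimator is not fitted")
        pp = self.phase_point_
        return {
            "dimension": int(self.dimension_),
            "frequencies": {str(k): float(v)
                            for k, v in sorted(self.frequencies_.items())},
            "K": int(self.k_),
            "accuracy": None if np.isnan(self.accuracy_)
            else float(self.accuracy_),
            "d_max": int(self.d_max_),
            "anomalous": bool(self.anomalous_),
            "phase_point": {"C_t": pp.C_t, "C_s": pp.C_s, "C_p": pp.C_p,
                            "C": pp.C,
                            "n_edges_eligible": pp.n_edges_eligible},
            "n_nodes": int(self.n_nodes_),
            "ensemble_size": len(self.ensemble_.records),
        }
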