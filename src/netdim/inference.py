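"""Dimension inference via surrogate ensembles and distance-weighted K-NN.

The input graph is reduced to its chordless-cycle phase point
(C_t, C_s, C_p).  An ensemble of S^D surrogates with matched degrees is
generated across candidate dimensions and a clustering window around the
observed C_t; a K-nearest-neighbour vote in phase space, with weights
inversely proportional to distance, yields the inferred dimension

    D* = argmax_D f(D),    f(D) = sum_{i=1}^K w_i * delta(D_i, D).

K is chosen by maximizing leave-one-out accuracy on the surrogates, and
the same LOO accuracy at the chosen K quantifies how discernible the
dimension is.  Experiment drivers reproduce the synthetic benchmarks:
confusion matrices on S^D test networks, clustering-vs-dimension sweeps
at beta = inf, and phase-space curves across beta.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier

from .calibration import (BETA_MARGIN, CtCurveFit, FitError, fit_ct_curve,
                          estimate_max_dimension, sample_beta_range,
                          sample_s1_ct_curve)
from .cycles import CyclePhasePoint, phase_point_from_edges
from .hidden_degrees import infer_hidden_degrees
from .model import (ModelParams, refine_mu, sample_edge_arrays,
                    sample_hidden_degrees)

__all__ = [
    "SurrogateRecord",
    "DimensionEstimate",
    "EnsembleResult",
    "build_surrogate_ensemble",
    "optimize_k",
    "classify_dimension",
    "estimate_accuracy",
    "evaluate_confusion",
    "phase_space_scan",
    "attainable_ct_sweep",
    "CT_INTERVALS_D1",
    "default_k_grid",
]

# Clustering windows (C_t for D = 1) delimiting the low/high-clustering
# regimes of the synthetic benchmark, per heterogeneity exponent gamma.
CT_INTERVALS_D1 = {
    2.1: {"low": (0.28, 0.55), "high": (0.43, 0.77)},
    2.7: {"low": (0.18, 0.39), "high": (0.27, 0.69)},
    3.5: {"low": (0.14, 0.35), "high": (0.23, 0.65)},
}


@dataclass
class SurrogateRecord:
    """One surrogate network's dimension label and phase point."""

    D: int
    beta: float
    phase: CyclePhasePoint
    seed: int


@dataclass
class DimensionEstimate:
    """Outcome of the K-NN vote for one query network."""

    D_star: int
    f: dict[int, float]
    K: int
    accuracy: float | None
    distances: np.ndarray
    anomalous: bool = False


@dataclass
class EnsembleResult:
    """Surrogate ensemble plus the calibration context it was built in."""

    records: list[SurrogateRecord]
    phase: CyclePhasePoint
    d_max: int
    anomalous: bool
    curve_fit: CtCurveFit | None
    mean_ct_by_D: dict[int, float] = field(default_factory=dict)

    def features(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.array([[r.phase.C_t, r.phase.C_s, r.phase.C_p]
                      for r in self.records])
        y = np.array([r.D for r in self.records])
        return X, y

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"D": [r.D for r in self.records],
             "beta": [r.beta for r in self.records],
             "C_t": [r.phase.C_t for r in self.records],
             "C_s": [r.phase.C_s for r in self.records],
             "C_p": [r.phase.C_p for r in self.records],
             "C": [r.phase.C for r in self.records],
             "seed": [r.seed for r in self.records]})


def default_k_grid(n: int | None = None) -> list[int]:
    """Odd neighbour counts 1, 3, ..., 25, capped at the ensemble size."""
    grid = list(range(1, 26, 2))
    if n is not None:
        grid = [k for k in grid if k <= n] or [1]
    return grid


def _derive_int_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def build_surrogate_ensemble(degree_sequence, phase: CyclePhasePoint,
                             n_per_dim: int = 50, delta_ct: float = 0.1,
                             tolerance: float = 1.0, max_iter: int = 200,
                             d_cap: int = 12, n_reals_dmax: int = 10,
                             seed=None) -> EnsembleResult:
    """Generate the degree-matched S^D surrogate ensemble for one graph.

    For each candidate dimension up to the clustering-limited maximum,
    ``n_per_dim`` betas are sampled in the observed clustering window and
    one surrogate is generated per beta, re-inferring hidden degrees each
    time (warm-started along the beta path).
    """
    ks = np.asarray(degree_sequence, dtype=np.int64)
    mean_degree = float(ks.mean())
    rng = np.random.default_rng(seed)
    if phase.C_t <= 0:
        warnings.warn("graph has no triangles; dimension defaults to 1")
        return EnsembleResult([], phase, 1, True, None)
    d_max, anomalous, mean_ct = estimate_max_dimension(
        ks, phase.C_t, mean_degree=mean_degree, n_reals=n_reals_dmax,
        d_cap=d_cap, tolerance=tolerance, max_iter=max_iter, seed=rng)
    if anomalous:
        return EnsembleResult([], phase, 1, True, None, mean_ct)
    fit = None
    for beta_hi in (15.0, 30.0):  # widen the sampling range on a poor fit
        samples = sample_s1_ct_curve(None, ks.size, mean_degree,
                                     beta_range=(1.0, beta_hi), seed=rng,
                                     degree_sequence=ks, tolerance=tolerance,
                                     max_iter=max_iter)
        try:
            fit = fit_ct_curve(samples, delta_ct=delta_ct)
        except FitError:
            continue
        if fit.ct_max_1 > phase.C_t:
            break
    if fit is None or fit.ct_max_1 <= phase.C_t:
        raise RuntimeError(
            "could not fit the clustering-vs-beta curve above the observed "
            "C_t; the graph's clustering is not representable at D = 1")
    records: list[SurrogateRecord] = []
    warm_prev_dim = None
    for D in range(1, d_max + 1):
        betas = sample_beta_range(phase.C_t, D, fit, n_networks=n_per_dim,
                                  seed=rng)
        if betas.size == 0:
            continue
        # warm-start the kappa fixed point from the neighbouring dimension:
        # cold starts need many iterations at high D, where expected degrees
        # respond only weakly to kappa
        warm = warm_prev_dim
        for beta in np.sort(betas):
            params = ModelParams(N=ks.size, D=D, beta=float(beta),
                                 mean_degree=mean_degree)
            table = infer_hidden_degrees(ks, params, tolerance=tolerance,
                                         max_iter=max_iter, seed=rng,
                                         initial_kappas=warm)
            if warm is warm_prev_dim or warm is None:
                warm_prev_dim = table.kappas
            warm = table.kappas
            kappas = table.per_node_kappas(ks)
            gseed = _derive_int_seed(rng)
            eu, ev, _ = sample_edge_arrays(params, kappas, seed=gseed)
            rec_phase = phase_point_from_edges(ks.size, eu, ev)
            records.append(SurrogateRecord(D=D, beta=float(beta),
                                           phase=rec_phase, seed=gseed))
    if not records:
        raise RuntimeError("empty surrogate ensemble: all dimensions skipped")
    return EnsembleResult(records, phase, d_max, False, fit, mean_ct)


# ---------------------------------------------------------------------------
# K-NN classification in (C_t, C_s, C_p) space
# ---------------------------------------------------------------------------

def _knn(K: int) -> KNeighborsClassifier:
    return KNeighborsClassifier(n_neighbors=K, weights="distance",
                                algorithm="brute")


def _loo_accuracies(X: np.ndarray, y: np.ndarray, k_list) -> dict[int, float]:
    """Leave-one-out accuracy of the distance-weighted vote for each K.

    Vectorized over the whole ensemble: each point is classified by its K
    nearest other points, weighted by inverse distance (coincident points
    absorb all weight), ties resolved towards the smallest dimension.
    """
    n = X.shape[0]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")
    dist = np.sqrt(np.take_along_axis(d2, order, axis=1))
    classes, y_idx = np.unique(y, return_inverse=True)
    neigh_cls = y_idx[order]
    rows = np.arange(n)
    out = {}
    for K in k_list:
        k = min(int(K), n - 1)
        d = dist[:, :k]
        zero = d == 0
        has0 = zero.any(axis=1)
        w = np.empty_like(d)
        with np.errstate(divide="ignore"):
            w[~has0] = 1.0 / d[~has0]
        w[has0] = zero[has0]
        votes = np.zeros((n, classes.size))
        np.add.at(votes, (np.repeat(rows, k), neigh_cls[:, :k].ravel()),
                  w.ravel())
        pred = classes[np.argmax(votes, axis=1)]
        out[int(K)] = float(np.mean(pred == y))
    return out


def optimize_k(ensemble, k_grid=None) -> tuple[int, dict[int, float]]:
    """K maximizing leave-one-out accuracy on the ensemble (smallest on ties)."""
    X, y = _features(ensemble)
    if np.unique(y).size < 2:
        warnings.warn("single-dimension ensemble: classification is trivial")
        return 1, {1: 1.0}
    if k_grid is None:
        k_grid = default_k_grid(X.shape[0] - 1)
    accuracies = _loo_accuracies(X, y, k_grid)
    best = max(accuracies.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    return int(best), accuracies


def _features(ensemble) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(ensemble, EnsembleResult):
        return ensemble.features()
    X = np.array([[r.phase.C_t, r.phase.C_s, r.phase.C_p] for r in ensemble])
    y = np.array([r.D for r in ensemble])
    return X, y


def classify_dimension(phase: CyclePhasePoint, ensemble, K: int) -> DimensionEstimate:
    """Distance-weighted K-NN vote on the surrogate phase points.

    Weights are proportional to inverse distance, normalized to sum to
    one; coincident surrogates (zero distance) absorb all the weight.
    Argmax ties resolve to the smallest dimension (parsimony).
    """
    X, y = _features(ensemble)
    if K > X.shape[0]:
        raise ValueError(f"K={K} exceeds ensemble size {X.shape[0]}")
    q = phase.as_array()[None, :]
    clf = _knn(K).fit(X, y)
    proba = clf.predict_proba(q)[0]
    classes = clf.classes_
    f = {int(d): float(p) for d, p in zip(classes, proba)}
    top = proba.max()
    d_star = int(classes[np.isclose(proba, top)].min())
    distances, _ = clf.kneighbors(q)
    return DimensionEstimate(D_star=d_star, f=f, K=K, accuracy=None,
                             distances=distances[0])


def estimate_accuracy(ensemble, K: int) -> float:
    """Leave-one-out accuracy of the K-NN vote over the ensemble."""
    X, y = _features(ensemble)
    if np.unique(y).size < 2:
        return 1.0
    return _loo_accuracies(X, y, [K])[int(K)]


# ---------------------------------------------------------------------------
# Synthetic benchmarks
# ---------------------------------------------------------------------------

def infer_dimension_from_edges(n: int, eu: np.ndarray, ev: np.ndarray,
                               n_per_dim: int = 50, delta_ct: float = 0.1,
                               tolerance: float = 1.0, max_iter: int = 200,
                               d_cap: int = 12, n_reals_dmax: int = 10,
                               k_grid=None, seed=None
                               ) -> tuple[DimensionEstimate, EnsembleResult]:
    """Full pipeline on raw edge arrays: ensemble, K choice, vote, accuracy."""
    degrees = np.bincount(np.concatenate([eu, ev]), minlength=n)
    keep = degrees > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} isolated nodes")
        relabel = np.cumsum(keep) - 1
        eu, ev = relabel[eu], relabel[ev]
        degrees = degrees[keep]
        n = int(keep.sum())
    phase = phase_point_from_edges(n, eu, ev)
    ensemble = build_surrogate_ensemble(
        degrees, phase, n_per_dim=n_per_dim, delta_ct=delta_ct,
        tolerance=tolerance, max_iter=max_iter, d_cap=d_cap,
        n_reals_dmax=n_reals_dmax, seed=seed)
    if ensemble.anomalous:
        est = DimensionEstimate(D_star=1, f={1: 1.0}, K=1, accuracy=None,
                                distances=np.empty(0), anomalous=True)
        return est, ensemble
    K, _ = optimize_k(ensemble, k_grid=k_grid)
    est = classify_dimension(phase, ensemble, K)
    est.accuracy = estimate_accuracy(ensemble, K)
    return est, ensemble


def evaluate_confusion(gamma: float, clustering_regime: str, D_values,
                       n_tests: int, N: int = 1000, mean_degree: float = 10.0,
                       seed=None, n_per_dim: int = 50, d_cap: int = 12,
                       tolerance: float = 1.0) -> pd.DataFrame:
    """Row-normalized confusion matrix on S^D test networks.

    Test betas are drawn by sampling C_t values in the regime's D = 1
    clustering window and mapping them through a fitted clustering curve
    scaled to the test dimension; each test network then runs the full
    inference pipeline.
    """
    if clustering_regime not in ("low", "high"):
        raise ValueError("clustering_regime must be 'low' or 'high'")
    interval = CT_INTERVALS_D1[gamma][clustering_regime]
    rng = np.random.default_rng(seed)
    # clustering curve of the generator itself (Pareto hidden degrees, D=1)
    kappas1 = sample_hidden_degrees(N, gamma, mean_degree, seed=rng)
    samples = sample_s1_ct_curve(kappas1, N, mean_degree, seed=rng)
    gen_fit = fit_ct_curve(samples)
    D_values = sorted(int(d) for d in D_values)
    counts: dict[int, dict[int, int]] = {d: {} for d in D_values}
    for D in D_values:
        for _ in range(n_tests):
            xi = rng.uniform(*interval)
            xi = min(xi, gen_fit.ct_max_1 * (1 - 1e-6))
            beta = D * (gen_fit.beta0
                        - math.log(1.0 - xi / gen_fit.ct_max_1) / gen_fit.a)
            beta = max(beta, D + BETA_MARGIN)
            kappas = sample_hidden_degrees(N, gamma, mean_degree, seed=rng)
            params = refine_mu(kappas, ModelParams(
                N=N, D=D, beta=float(beta), mean_degree=mean_degree))
            eu, ev, _ = sample_edge_arrays(params, kappas, seed=rng)
            est, _ = infer_dimension_from_edges(
                N, eu, ev, n_per_dim=n_per_dim, d_cap=d_cap,
                tolerance=tolerance, seed=_derive_int_seed(rng))
            counts[D][est.D_star] = counts[D].get(est.D_star, 0) + 1
    cols = sorted({d for row in counts.values() for d in row} | set(D_values))
    mat = pd.DataFrame(0.0, index=D_values, columns=cols)
    for D, row in counts.items():
        total = sum(row.values())
        for d_star, c in row.items():
            mat.loc[D, d_star] = c / total
    mat.index.name = "D"
    mat.columns.name = "D_star"
    return mat


def phase_space_scan(gamma: float, D_values, beta_grid, N: int = 1000,
                     n_reals: int = 10, mean_degree: float = 10.0,
                     seed=None, refine: bool = True) -> pd.DataFrame:
    """Mean cycle densities across (D, beta): the phase-space curves.

    ``beta_grid`` maps each D to its list of betas, or is a list of
    beta/D multipliers applied to every D.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for D in D_values:
        betas = beta_grid[D] if isinstance(beta_grid, dict) else \
            [m * D for m in beta_grid]
        for beta in betas:
            if not math.isinf(beta) and beta <= D:
                raise ValueError(f"beta={beta} must exceed D={D}")
            pts = np.empty((n_reals, 4))
            for r in range(n_reals):
                kappas = sample_hidden_degrees(N, gamma, mean_degree, seed=rng)
                params = ModelParams(N=N, D=int(D), beta=float(beta),
                                     mean_degree=mean_degree)
                if refine:
                    params = refine_mu(kappas, params)
                eu, ev, _ = sample_edge_arrays(params, kappas, seed=rng)
                pp = phase_point_from_edges(N, eu, ev)
                pts[r] = (pp.C_t, pp.C_s, pp.C_p, pp.C)
            mean = pts.mean(axis=0)
            sem = pts.std(axis=0, ddof=1) / math.sqrt(n_reals) if n_reals > 1 \
                else np.zeros(4)
            rows.append({"D": int(D), "beta": float(beta),
                         "C_t": mean[0], "C_s": mean[1], "C_p": mean[2],
                         "C": mean[3], "C_t_sem": sem[0], "C_s_sem": sem[1],
                         "C_p_sem": sem[2], "C_sem": sem[3],
                         "n_reals": n_reals})
    return pd.DataFrame(rows)


def attainable_ct_sweep(gamma: float, D_values, N: int = 1000,
                        n_reals: int = 10, mean_degree: float = 10.0,
                        seed=None, pentagons: bool = False) -> pd.DataFrame:
    """Maximum attainable cycle densities (beta = inf) versus dimension.

    Generates ``n_reals`` zero-temperature S^D networks per dimension with
    mu refined to the target mean degree, and reports per-D means of C_t
    (and the realized mean degree).  This is the clustering-vs-dimension
    sweep that bounds the candidate dimension of real networks.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for D in D_values:
        vals = np.empty((n_reals, 2))
        for r in range(n_reals):
            kappas = sample_hidden_degrees(N, gamma, mean_degree, seed=rng)
            params = refine_mu(kappas, ModelParams(
                N=N, D=int(D), beta=math.inf, mean_degree=mean_degree))
            eu, ev, _ = sample_edge_arrays(params, kappas, seed=rng)
            if pentagons:
                ct = phase_point_from_edges(N, eu, ev).C_t
            else:
                ct = phase_point_from_edges(N, eu, ev, pentagons=False).C_t
            vals[r] = (ct, 2 * eu.size / N)
        rows.append({"D": int(D), "gamma": gamma,
                     "C_t": vals[:, 0].mean(),
                     "C_t_sem": vals[:, 0].std(ddof=1) / math.sqrt(n_reals)
                     if n_reals > 1 else 0.0,
                     "mean_degree": vals[:, 1].mean(),
                     "mean_degree_sem": vals[:, 1].std(ddof=1)
                     / math.sqrt(n_reals) if n_reals > 1 else 0.0,
                     "n_reals": n_reals})
    return pd.DataFrame(rows)
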