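"""Inverse-temperature calibration for the surrogate ensemble.

The edge-triangle density of S^1 graphs grows with beta roughly as a
saturating exponential,

    C_t(beta) = C_t_max * (1 - exp(-a (beta - beta0))),

fitted on a small sample of S^1 surrogates.  Inverting the fit maps a
target clustering value onto beta, and the approximate scaling relation
C_t^D(beta/D) / C_t_max^D ~= C_t^1(beta) / C_t_max^1 extrapolates the map
to higher dimensions: beta(xi, D) = D * [beta0 - ln(1 - xi/C_t_max) / a].
Surrogate betas are then drawn by sampling the clustering window
(C_t* - dCt, C_t* + dCt) uniformly, with beta clipped below at D + 0.25.

The module also bounds the candidate dimension: the maximum attainable
C_t occurs at beta = inf and decreases with D, so the scan stops at the
first dimension that cannot reach the observed clustering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .cycles import mean_triangle_density_from_edges
from .model import ModelParams, sample_edge_arrays
from .hidden_degrees import DegreeClassTable, infer_hidden_degrees

__all__ = [
    "CtCurveFit",
    "FitError",
    "fit_ct_curve",
    "beta_from_ct",
    "sample_beta_range",
    "estimate_max_dimension",
    "sample_s1_ct_curve",
]

BETA_MARGIN = 0.25  # minimum allowed beta is D + BETA_MARGIN


class FitError(RuntimeError):
    """Raised when the clustering-vs-beta fit cannot be performed."""


@dataclass
class CtCurveFit:
    """Fitted saturating-exponential clustering curve for D = 1."""

    ct_max_1: float
    a: float
    beta0: float
    delta_ct: float = 0.1

    def ct(self, beta):
        """Evaluate C_t(beta); zero below beta0."""
        beta = np.asarray(beta, dtype=float)
        return self.ct_max_1 * np.maximum(1.0 - np.exp(-self.a * (beta - self.beta0)),
                                          0.0)


def _curve(beta, ct_max, a, beta0):
    return ct_max * (1.0 - np.exp(-a * (beta - beta0)))


def fit_ct_curve(graph_stats, delta_ct: float = 0.1) -> CtCurveFit:
    """Least-squares fit of the clustering curve on (beta, C_t) samples."""
    pts = np.asarray(graph_stats, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise FitError("need at least 5 (beta, C_t) sample points")
    betas, cts = pts[:, 0], pts[:, 1]
    if np.any((cts < 0) | (cts >= 1)):
        raise FitError("C_t samples must lie in [0, 1)")
    if np.ptp(cts) < 1e-12:
        raise FitError("degenerate sample: all C_t values equal")
    p0 = (min(max(cts.max() * 1.05, 1e-3), 1.0 - 1e-9), 0.5, min(1.0, betas.min()))
    try:
        popt, _ = curve_fit(_curve, betas, cts, p0=p0,
                            bounds=([1e-9, 1e-9, -np.inf], [1.0, np.inf, np.inf]),
                            maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise FitError(f"clustering-curve fit failed: {exc}") from exc
    return CtCurveFit(ct_max_1=float(popt[0]), a=float(popt[1]),
                      beta0=float(popt[2]), delta_ct=delta_ct)


def beta_from_ct(ct_target: float, fit: CtCurveFit, D: int) -> float:
    """Invert the fitted curve (scaled to dimension D) at a C_t value."""
    if not 0 < ct_target < fit.ct_max_1:
        raise ValueError(
            f"ct_target must lie in (0, {fit.ct_max_1:.4g}), got {ct_target}")
    return float(D * (fit.beta0 - math.log(1.0 - ct_target / fit.ct_max_1) / fit.a))


def sample_beta_range(ct_observed: float, D: int, fit: CtCurveFit,
                      n_networks: int = 50, seed=None) -> np.ndarray:
    """Draw surrogate betas by sampling the clustering window uniformly.

    xi ~ U(ct_observed - dCt, ct_observed + dCt), window intersected with
    the representable range (0, ct_max_1); each xi maps through the
    inverted curve and is clipped below at D + 0.25.  Returns an empty
    array when the whole window is unreachable (the dimension is skipped).
    """
    if not 0 < ct_observed < 1:
        raise ValueError("ct_observed must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    eps = 1e-6
    lo = max(ct_observed - fit.delta_ct, eps)
    hi = min(ct_observed + fit.delta_ct, fit.ct_max_1 * (1.0 - eps))
    if hi <= lo:
        return np.empty(0)
    xi = rng.uniform(lo, hi, size=n_networks)
    betas = D * (fit.beta0 - np.log(1.0 - xi / fit.ct_max_1) / fit.a)
    return np.maximum(betas, D + BETA_MARGIN)


def sample_s1_ct_curve(table_kappas: np.ndarray | None, N: int,
                       mean_degree: float, n_samples: int = 20,
                       beta_range: tuple[float, float] = (1.0, 15.0),
                       seed=None, degree_sequence=None, tolerance: float = 1.0,
                       max_iter: int = 200) -> np.ndarray:
    """(beta, C_t) samples from S^1 surrogates for the curve fit.

    When ``degree_sequence`` is given, hidden degrees are re-inferred at
    each sampled beta (warm-started along the sorted beta path) so the
    surrogates match the input graph's degrees; otherwise ``table_kappas``
    is used as-is for every sample.
    """
    rng = np.random.default_rng(seed)
    # stratified uniform draws: marginally U(lo, hi), but guaranteed to
    # cover the steep low-beta region the inversion relies on
    lo, hi = beta_range
    betas = lo + (hi - lo) * (np.arange(n_samples) + rng.random(n_samples)) \
        / n_samples
    betas = np.maximum(betas, 1.0 + 1e-3)  # beta must exceed D = 1
    out = np.empty((n_samples, 2))
    warm = None
    for idx, beta in enumerate(betas):
        params = ModelParams(N=N, D=1, beta=float(beta), mean_degree=mean_degree)
        if degree_sequence is not None:
            table = infer_hidden_degrees(degree_sequence, params,
                                         tolerance=tolerance, max_iter=max_iter,
                                         seed=rng, initial_kappas=warm)
            warm = table.kappas
            kappas = table.per_node_kappas(np.asarray(degree_sequence))
        else:
            kappas = np.asarray(table_kappas, dtype=float)
        eu, ev, _ = sample_edge_arrays(params, kappas, seed=rng)
        out[idx] = (beta, mean_triangle_density_from_edges(N, eu, ev))
    return out


def estimate_max_dimension(degree_sequence, ct_observed: float,
                           mean_degree: float | None = None,
                           n_reals: int = 10, d_cap: int = 12,
                           tolerance: float = 1.0, max_iter: int = 200,
                           seed=None) -> tuple[int, bool, dict[int, float]]:
    """Largest dimension whose zero-temperature surrogates reach C_t*.

    For each D (ascending, up to ``d_cap``) hidden degrees are re-inferred
    at beta = inf and ``n_reals`` surrogates are generated; the scan stops
    at the first D whose mean C_t falls below ``ct_observed``.  Returns
    ``(d_max, anomalous, mean_ct_by_D)``; ``anomalous`` is True when even
    D = 1 cannot reach the observed clustering (the pipeline then reports
    dimension 1).
    """
    ks = np.asarray(degree_sequence, dtype=np.int64)
    if not 0 < ct_observed < 1:
        raise ValueError("ct_observed must lie in (0, 1)")
    if mean_degree is None:
        mean_degree = float(ks.mean())
    rng = np.random.default_rng(seed)
    mean_ct: dict[int, float] = {}
    d_max = 1
    anomalous = False
    warm = None
    for D in range(1, d_cap + 1):
        params = ModelParams(N=ks.size, D=D, beta=math.inf, mean_degree=mean_degree)
        table = infer_hidden_degrees(ks, params, tolerance=tolerance,
                                     max_iter=max_iter, seed=rng,
                                     initial_kappas=warm)
        warm = table.kappas
        kappas = table.per_node_kappas(ks)
        cts = np.empty(n_reals)
        for r in range(n_reals):
            eu, ev, _ = sample_edge_arrays(params, kappas, seed=rng)
            cts[r] = mean_triangle_density_from_edges(ks.size, eu, ev)
        mean_ct[D] = float(cts.mean())
        if mean_ct[D] < ct_observed:
            if D == 1:
                anomalous = True
                warnings.warn(
                    "anomalous clustering: even D=1 cannot reach the observed "
                    "edge-triangle density; reporting D=1")
            break
        d_max = D
    return d_max, anomalous, mean_ct
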