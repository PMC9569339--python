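"""The S^D geometric soft configuration model.

Nodes live on a D-dimensional sphere (embedded in D+1 ambient dimensions)
with density one, and each node carries a hidden degree ``kappa`` equal to
its expected degree in the ensemble.  A pair of nodes at angular distance
``dtheta`` connects independently with the gravity-law probability

    p_ij = 1 / (1 + chi_ij**beta),   chi_ij = R*dtheta / (mu*k_i*k_j)**(1/D)

where ``beta > D`` (the inverse temperature) couples topology to geometry
and ``mu`` fixes the mean degree.  ``beta = inf`` is first class: the
connection law becomes a sharp step at chi = 1 and ``mu`` takes its
zero-temperature limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq
from scipy.special import betainc, gammaln

__all__ = [
    "ModelParams",
    "NodeState",
    "compute_radius",
    "compute_mu",
    "sample_positions",
    "angular_distance",
    "connection_probability",
    "sample_hidden_degrees",
    "generate_network",
    "ensemble_mean_degree",
    "refine_mu",
]

_GL_NODES, _GL_WEIGHTS = leggauss(64)


def _validate_nd(N: int, D: int) -> None:
    if not (isinstance(N, (int, np.integer)) and isinstance(D, (int, np.integer))):
        raise ValueError(f"N and D must be integers, got N={N!r}, D={D!r}")
    if N < 2 or D < 1:
        raise ValueError(f"require N >= 2 and D >= 1, got N={N}, D={D}")


def compute_radius(N: int, D: int) -> float:
    """Radius of the similarity D-sphere at unit node density.

    R = [N * Gamma((D+1)/2) / (2 * pi**((D+1)/2))]**(1/D), i.e. the sphere
    whose surface area equals N.  For D=1 this is the circle with
    circumference N, R = N / (2*pi).
    """
    _validate_nd(N, D)
    log_r = (math.log(N) + gammaln((D + 1) / 2) - math.log(2)
             - (D + 1) / 2 * math.log(math.pi)) / D
    return float(math.exp(log_r))


def compute_mu(beta: float, D: int, mean_degree: float) -> float:
    """Closed-form density parameter fixing the target mean degree.

    mu = beta * Gamma(D/2) * sin(D*pi/beta) / (2 * pi**(1+D/2) * <k>)
    for finite beta > D; its beta -> inf limit is
    Gamma(D/2 + 1) / (pi**(D/2) * <k>).

    This is a thermodynamic-limit value; see :func:`refine_mu` for the
    finite-size correction.
    """
    if D < 1:
        raise ValueError(f"D must be >= 1, got {D}")
    if mean_degree <= 0:
        raise ValueError(f"mean_degree must be positive, got {mean_degree}")
    if math.isinf(beta):
        return float(math.exp(gammaln(D / 2 + 1)) / (math.pi ** (D / 2) * mean_degree))
    if beta <= D:
        raise ValueError(f"beta must exceed D (or be inf), got beta={beta}, D={D}")
    return float(beta * math.exp(gammaln(D / 2)) * math.sin(D * math.pi / beta)
                 / (2 * math.pi ** (1 + D / 2) * mean_degree))


@dataclass
class ModelParams:
    """Parameter bundle of the S^D ensemble.

    ``mu`` and ``R`` are derived from the other fields when omitted.
    ``gamma`` may be None for workflows that supply hidden degrees
    directly (e.g. degrees inferred from an observed network).
    ``beta = math.inf`` selects the zero-temperature step law.
    """

    N: int
    D: int
    beta: float
    mean_degree: float
    gamma: float | None = None
    mu: float = field(default=None)  # type: ignore[assignment]
    R: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _validate_nd(self.N, self.D)
        self.beta = float(self.beta)
        if not math.isinf(self.beta) and self.beta <= self.D:
            raise ValueError(
                f"beta must be > D or infinite, got beta={self.beta}, D={self.D}")
        if self.gamma is not None and self.gamma <= 2:
            raise ValueError(f"gamma must exceed 2, got {self.gamma}")
        if self.mean_degree <= 0:
            raise ValueError("mean_degree must be positive")
        if self.R is None:
            self.R = compute_radius(self.N, self.D)
        if self.mu is None:
            self.mu = compute_mu(self.beta, self.D, self.mean_degree)
        if self.mu <= 0 or self.R <= 0:
            raise ValueError("mu and R must be positive")

    @property
    def small_world(self) -> bool:
        """True when beta < 2D (the small-world phase boundary)."""
        return self.beta < 2 * self.D

    def with_mu(self, mu: float) -> "ModelParams":
        return ModelParams(N=self.N, D=self.D, beta=self.beta,
                           mean_degree=self.mean_degree, gamma=self.gamma,
                           mu=mu, R=self.R)


@dataclass
class NodeState:
    """Hidden degree and position of one node on the similarity sphere."""

    kappa: float
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        self.position = np.asarray(self.position, dtype=float)
        if abs(np.linalg.norm(self.position) - 1.0) > 1e-12:
            raise ValueError("position must be a unit vector")


def sample_positions(N: int, D: int, seed=None) -> np.ndarray:
    """N points uniform on the D-sphere, as unit vectors in R^(D+1).

    Isotropic Gaussian vectors normalised to unit length; rotation
    invariance of the Gaussian guarantees uniformity on the sphere.
    """
    if N < 1 or D < 1:
        raise ValueError(f"require N >= 1 and D >= 1, got N={N}, D={D}")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((N, D + 1))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    return x


def angular_distance(v1: np.ndarray, v2: np.ndarray) -> float:
    """Great-circle angle between two unit vectors, in [0, pi]."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError(f"dimension mismatch: {v1.shape} vs {v2.shape}")
    return float(np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0)))


def connection_probability(kappa_i: float, kappa_j: float, dtheta: float,
                           params: ModelParams) -> float:
    """Gravity-law connection probability for one pair."""
    if kappa_i <= 0 or kappa_j <= 0:
        raise ValueError("hidden degrees must be positive")
    if not 0 <= dtheta <= math.pi + 1e-12:
        raise ValueError(f"dtheta must lie in [0, pi], got {dtheta}")
    chi = params.R * dtheta / (params.mu * kappa_i * kappa_j) ** (1 / params.D)
    if math.isinf(params.beta):
        if chi < 1:
            return 1.0
        if chi > 1:
            return 0.0
        return 0.5
    return 1.0 / (1.0 + chi ** params.beta)


def sample_hidden_degrees(N: int, gamma: float, mean_degree: float,
                          seed=None) -> np.ndarray:
    """I.i.d. hidden degrees from a Pareto law with the requested mean.

    Density rho(kappa) = (gamma-1) * kappa0**(gamma-1) * kappa**(-gamma) on
    [kappa0, inf), with kappa0 = <k>(gamma-2)/(gamma-1) so the mean is <k>.
    """
    if gamma <= 2:
        raise ValueError(f"gamma must exceed 2 (finite mean), got {gamma}")
    if mean_degree <= 0:
        raise ValueError("mean_degree must be positive")
    rng = np.random.default_rng(seed)
    kappa0 = mean_degree * (gamma - 2) / (gamma - 1)
    u = rng.random(N)
    return kappa0 * (1.0 - u) ** (-1.0 / (gamma - 1))


# ---------------------------------------------------------------------------
# Expected-degree machinery (angular average of the connection law)
# ---------------------------------------------------------------------------

def sin_power_integral(x, D: int):
    """Integral of sin(theta)**(D-1) from 0 to x, for x in [0, pi].

    Evaluated through the regularized incomplete beta function.
    """
    x = np.asarray(x, dtype=float)
    total = math.exp(0.5 * math.log(math.pi) + gammaln(D / 2) - gammaln((D + 1) / 2))
    s2 = np.clip(np.sin(x) ** 2, 0.0, 1.0)
    half = 0.5 * total * betainc(D / 2, 0.5, s2)
    return np.where(x <= math.pi / 2, half, total - half)


def _angular_prefactor(D: int) -> float:
    # Gamma((D+1)/2) / (sqrt(pi) Gamma(D/2)) -- normalizer of sin^(D-1)
    return math.exp(gammaln((D + 1) / 2) - 0.5 * math.log(math.pi) - gammaln(D / 2))


def fermi_marginal(c, R: float, beta: float, D: int, grid: bool | None = None):
    """Integral of sin(theta)**(D-1) / (1 + (R*theta/c)**beta) over [0, pi].

    ``c = (mu*k_i*k_j)**(1/D)`` is the characteristic connection scale of a
    pair.  For beta = inf the Fermi factor is a step at theta = c/R.  The
    integrand is split at that angle and each piece handled by 64-node
    Gauss-Legendre quadrature; for large inputs the function is tabulated on
    a dense log grid in c and interpolated (it is smooth in log c).
    """
    c = np.atleast_1d(np.asarray(c, dtype=float))
    if math.isinf(beta):
        return sin_power_integral(np.minimum(c / R, math.pi), D)
    if grid is None:
        grid = c.size > 768
    if grid:
        lo, hi = c.min(), c.max()
        if lo == hi:
            return np.full(c.shape, _fermi_exact(np.array([lo]), R, beta, D)[0])
        cg = np.exp(np.linspace(math.log(lo), math.log(hi), 768))
        gg = _fermi_exact(cg, R, beta, D)
        return np.interp(np.log(c), np.log(cg), gg)
    return _fermi_exact(c, R, beta, D)


class FermiInterpolator:
    """Cached log-grid interpolator for the angular connection integral.

    Iterative callers (the hidden-degree fixed point) evaluate the same
    (R, beta, D) integral for slowly drifting argument ranges; the grid is
    rebuilt, with half-decade margins, only when the range is exceeded.
    """

    def __init__(self, R: float, beta: float, D: int, n_grid: int = 768):
        self.R, self.beta, self.D, self.n_grid = R, beta, D, n_grid
        self._log_lo = self._log_hi = None
        self._grid = self._values = None

    def _rebuild(self, log_lo: float, log_hi: float) -> None:
        self._log_lo, self._log_hi = log_lo, log_hi
        self._grid = np.linspace(log_lo, log_hi, self.n_grid)
        self._values = _fermi_exact(np.exp(self._grid), self.R, self.beta,
                                    self.D)

    def __call__(self, c: np.ndarray) -> np.ndarray:
        c = np.atleast_1d(np.asarray(c, dtype=float))
        if math.isinf(self.beta):
            return sin_power_integral(np.minimum(c / self.R, math.pi), self.D)
        logc = np.log(c)
        lo, hi = float(logc.min()), float(logc.max())
        if self._grid is None or lo < self._log_lo or hi > self._log_hi:
            margin = math.log(3.0)
            old_lo = lo if self._log_lo is None else self._log_lo + margin
            old_hi = hi if self._log_hi is None else self._log_hi - margin
            self._rebuild(min(lo, old_lo) - margin, max(hi, old_hi) + margin)
        return np.interp(logc, self._grid, self._values)


def _fermi_exact(c: np.ndarray, R: float, beta: float, D: int) -> np.ndarray:
    theta_star = np.minimum(c / R, math.pi)
    out = np.zeros_like(c)
    x, w = _GL_NODES, _GL_WEIGHTS
    with np.errstate(over="ignore", divide="ignore"):
        # [0, theta*]
        h1 = theta_star / 2.0
        t1 = h1[:, None] * (x + 1.0)
        f1 = np.sin(t1) ** (D - 1) / (1.0 + (R * t1 / c[:, None]) ** beta)
        out += h1 * (f1 @ w)
        # [theta*, pi]
        h2 = (math.pi - theta_star) / 2.0
        t2 = theta_star[:, None] + h2[:, None] * (x + 1.0)
        f2 = np.sin(t2) ** (D - 1) / (1.0 + (R * t2 / c[:, None]) ** beta)
        out += h2 * (f2 @ w)
    return out


_TRIU_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _triu(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _TRIU_CACHE:
        _TRIU_CACHE.clear()  # keep at most one (they are large)
        _TRIU_CACHE[n] = np.triu_indices(n, 1)
    return _TRIU_CACHE[n]


def ensemble_mean_degree(kappas: np.ndarray, params: ModelParams,
                         exact: bool | None = None) -> float:
    """Ensemble-average degree for a fixed hidden-degree sequence.

    Positions are marginalized analytically: each pair contributes the
    angular average of the connection law.  For large N the hidden degrees
    are binned on a dense log grid (bin means preserved) before the pair
    sum; the error is second order in the bin width and far below the
    refinement tolerance.
    """
    kappas = np.asarray(kappas, dtype=float)
    n = kappas.size
    pref = _angular_prefactor(params.D)
    if exact is None:
        exact = n <= 512
    if exact:
        iu, ju = _triu(n)
        c = (params.mu * kappas[iu] * kappas[ju]) ** (1.0 / params.D)
        g = fermi_marginal(c, params.R, params.beta, params.D)
        return float(2.0 * pref * g.sum() / n)
    nbins = 600
    logk = np.log(kappas)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, nbins + 1)
    idx = np.clip(np.searchsorted(edges, logk, side="right") - 1, 0, nbins - 1)
    counts = np.bincount(idx, minlength=nbins)
    sums = np.bincount(idx, weights=kappas, minlength=nbins)
    keep = counts > 0
    counts = counts[keep].astype(float)
    reps = sums[keep] / counts
    kk = np.multiply.outer(reps, reps)
    c = (params.mu * kk) ** (1.0 / params.D)
    g = fermi_marginal(c.ravel(), params.R, params.beta, params.D).reshape(c.shape)
    w = np.outer(counts, counts)
    np.fill_diagonal(w, counts * (counts - 1.0))
    total = 0.5 * float((w * g).sum())
    return float(2.0 * pref * total / n)


def refine_mu(kappas: np.ndarray, params: ModelParams, target: float | None = None,
              tol: float = 0.01) -> ModelParams:
    """Adjust mu so the ensemble mean degree matches the target.

    Root-finds on the exact expected mean degree for the given hidden-degree
    draw, correcting the finite-size bias of the closed-form mu.  ``tol`` is
    on the mean degree.
    """
    target = params.mean_degree if target is None else target
    mu0 = params.mu

    def f(log_mu: float) -> float:
        return ensemble_mean_degree(kappas, params.with_mu(math.exp(log_mu))) - target

    lo, hi = math.log(mu0) - math.log(4), math.log(mu0) + math.log(4)
    flo, fhi = f(lo), f(hi)
    for _ in range(20):
        if flo < 0:
            break
        lo -= math.log(4)
        flo = f(lo)
    for _ in range(20):
        if fhi > 0:
            break
        hi += math.log(4)
        fhi = f(hi)
    if flo > 0 or fhi < 0:
        raise RuntimeError("could not bracket mu for the requested mean degree")
    # xtol on log mu: d<k>/dlogmu ~ <k>/D, so this comfortably beats `tol`
    log_mu = brentq(f, lo, hi, xtol=tol * params.D / (10 * target))
    return params.with_mu(math.exp(log_mu))


# ---------------------------------------------------------------------------
# Graph generation
# ---------------------------------------------------------------------------

def sample_edge_arrays(params: ModelParams, kappas: np.ndarray, seed=None,
                       positions: np.ndarray | None = None
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fast path: sample one graph, returning (edges_u, edges_v, positions)."""
    kappas = np.asarray(kappas, dtype=float)
    if kappas.size != params.N:
        raise ValueError(f"need {params.N} hidden degrees, got {kappas.size}")
    if np.any(kappas <= 0):
        raise ValueError("hidden degrees must be positive")
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = sample_positions(params.N, params.D, rng)
    iu, ju = _triu(params.N)
    pos32 = positions.astype(np.float32)
    dots = pos32 @ pos32.T
    theta = np.arccos(np.clip(dots[iu, ju], np.float32(-1.0), np.float32(1.0)))
    c = (params.mu * kappas[iu] * kappas[ju]).astype(np.float32) \
        ** np.float32(1.0 / params.D)
    chi = np.float32(params.R) * theta / c
    if math.isinf(params.beta):
        p = np.where(chi < 1.0, 1.0, 0.0)
        p[chi == 1.0] = 0.5
    else:
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + chi ** np.float32(params.beta))
    mask = rng.random(p.size) < p
    return iu[mask].astype(np.int64), ju[mask].astype(np.int64), positions


def generate_network(params: ModelParams, kappas: Sequence[float], seed=None,
                     refine: bool = False) -> nx.Graph:
    """Sample one S^D graph; nodes 0..N-1 keep `kappa` and `position` attrs.

    With ``refine=True`` mu is first recalibrated against the exact expected
    mean degree for this hidden-degree draw (see :func:`refine_mu`).
    """
    kappas = np.asarray(kappas, dtype=float)
    if refine:
        params = refine_mu(kappas, params)
    eu, ev, pos = sample_edge_arrays(params, kappas, seed)
    g = nx.Graph()
    g.add_nodes_from(range(params.N))
    g.add_edges_from(zip(eu.tolist(), ev.tolist()))
    for i in range(params.N):
        g.nodes[i]["kappa"] = float(kappas[i])
        g.nodes[i]["position"] = pos[i]
    g.graph["params"] = params
    return g
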