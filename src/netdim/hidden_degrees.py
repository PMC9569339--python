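"""Hidden-degree inference: match model expected degrees to observed degrees.

The S^D ensemble average degree of a node with hidden degree kappa is

    kbar(kappa) = Gamma((D+1)/2) / (sqrt(pi) Gamma(D/2))
                  * sum_{j != i} int_0^pi sin(theta)**(D-1) dtheta
                                 / (1 + (R theta / (mu kappa kappa_j)**(1/D))**beta)

Nodes sharing an observed degree share a hidden degree, so the sum runs
over degree classes weighted by multiplicity (a node's own class counts
multiplicity - 1).  The fixed point kbar(kappa_k) = k for every class k is
reached by a damped stochastic iteration:

    kappa <- | kappa + (k - kbar(kappa)) * u |,   u ~ U(0, 1)

with the best iterate tracked, until the maximal deviation epsilon_max
drops below the tolerance (default 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model import (FermiInterpolator, ModelParams, _angular_prefactor,
                    fermi_marginal)

__all__ = ["DegreeClassTable", "expected_degree", "infer_hidden_degrees"]


@dataclass
class DegreeClassTable:
    """Per-degree-class hidden degrees and convergence state."""

    degrees: np.ndarray      # distinct observed degrees, ascending
    kappas: np.ndarray       # inferred hidden degree per class
    counts: np.ndarray       # class multiplicities
    epsilon_max: float
    converged: bool
    n_iter: int

    @property
    def n_nodes(self) -> int:
        return int(self.counts.sum())

    def kappa_of_degree(self, k: int) -> float:
        idx = np.searchsorted(self.degrees, k)
        if idx == self.degrees.size or self.degrees[idx] != k:
            raise KeyError(f"no degree class {k}")
        return float(self.kappas[idx])

    def per_node_kappas(self, degree_sequence: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.degrees, degree_sequence)
        return self.kappas[idx]


def _class_expected_degrees(kappas: np.ndarray, counts: np.ndarray,
                            params: ModelParams,
                            fermi=None) -> np.ndarray:
    """kbar for every degree class, vectorized over class pairs."""
    kk = np.multiply.outer(kappas, kappas)
    c = (params.mu * kk) ** (1.0 / params.D)
    flat = c.ravel()
    if fermi is not None:
        g = fermi(flat).reshape(c.shape)
    else:
        g = fermi_marginal(flat, params.R, params.beta,
                           params.D).reshape(c.shape)
    pref = _angular_prefactor(params.D)
    # own class contributes multiplicity - 1 (no self pair)
    return pref * (g @ counts - np.diag(g))


def expected_degree(kappa: float, table: DegreeClassTable,
                    params: ModelParams, own_class: int | None = None) -> float:
    """Model expected degree of a node with hidden degree ``kappa``.

    ``own_class`` (an observed degree value) marks the class the node
    belongs to, whose multiplicity is reduced by one; None means the node
    is external to the table.
    """
    if table.counts.size == 0:
        raise ValueError("empty degree-class table")
    counts = table.counts.astype(float).copy()
    if own_class is not None:
        idx = np.searchsorted(table.degrees, own_class)
        counts[idx] -= 1.0
    c = (params.mu * kappa * table.kappas) ** (1.0 / params.D)
    g = fermi_marginal(c, params.R, params.beta, params.D, grid=False)
    return float(_angular_prefactor(params.D) * (g @ counts))


def infer_hidden_degrees(degree_sequence, params: ModelParams,
                         tolerance: float = 1.0, seed=None, max_iter: int = 200,
                         initial_kappas: np.ndarray | None = None,
                         group_classes: bool = True) -> DegreeClassTable:
    """Infer hidden degrees from an observed degree sequence.

    Parameters
    ----------
    degree_sequence : observed degrees, all >= 1 (drop isolated nodes first).
    params : ensemble parameters; ``params.mean_degree`` should be the
        observed mean degree of the input graph (it sets mu).
    tolerance : convergence threshold on the max |kbar - k| deviation.
    initial_kappas : optional warm start aligned with the class table
        (e.g. the solution at a neighbouring beta).
    group_classes : with False every node is its own class (slower;
        grouping is an optimization only).
    """
    ks = np.asarray(degree_sequence, dtype=np.int64)
    if ks.size == 0:
        raise ValueError("empty degree sequence")
    if np.any(ks < 1):
        raise ValueError("degrees must be >= 1 (drop isolated nodes upstream)")
    if ks.size != params.N:
        raise ValueError(f"degree sequence length {ks.size} != params.N {params.N}")
    rng = np.random.default_rng(seed)
    if group_classes:
        degrees, counts = np.unique(ks, return_counts=True)
    else:
        order = np.argsort(ks, kind="stable")
        degrees = ks[order].astype(np.int64)
        counts = np.ones_like(degrees)
    target = degrees.astype(float)
    kappas = target.copy() if initial_kappas is None else \
        np.asarray(initial_kappas, dtype=float).copy()
    if kappas.size != degrees.size:
        raise ValueError("initial_kappas does not match the class table")

    best_kappas = kappas.copy()
    best_eps = math.inf
    n_iter = 0
    fermi = FermiInterpolator(params.R, params.beta, params.D)
    counts_f = counts.astype(float)
    for n_iter in range(1, max_iter + 1):
        kbar = _class_expected_degrees(kappas, counts_f, params, fermi=fermi)
        eps = float(np.abs(kbar - target).max())
        if eps < best_eps:
            best_eps = eps
            best_kappas = kappas.copy()
        if eps <= tolerance:
            break
        u = rng.random(kappas.size)
        kappas = np.abs(kappas + (target - kbar) * u)
        np.maximum(kappas, 1e-10, out=kappas)
    converged = best_eps <= tolerance
    if not converged:
        warnings.warn(
            f"hidden-degree inference did not reach tolerance {tolerance} "
            f"after {max_iter} iterations (best epsilon_max={best_eps:.3g})")
    return DegreeClassTable(degrees=degrees, kappas=best_kappas, counts=counts,
                            epsilon_max=best_eps, converged=converged,
                            n_iter=n_iter)
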