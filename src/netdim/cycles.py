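"""Chordless-cycle census: per-edge triangle, square and pentagon densities.

For an edge (i, j) the census counts cycles through the edge whose vertex
set induces no chord, and normalizes each count by a degree-based maximum:

* triangles:  T_ij = |N(i) & N(j)|, max m_t = min(k_i, k_j) - 1;
* chordless squares i-a-b-j: a adjacent to i only, b adjacent to j only,
  (a, b) an edge; max m_s = (k_i - 1 - T_ij) * (k_j - 1 - T_ij), i.e. each
  square consumes one non-triangle neighbour on each side;
* chordless pentagons i-a-c-b-j: the density counts (a, b) pairs not yet
  consumed by triangles or squares that are joined by an admissible
  2-path a-c-b (c adjacent to neither i nor j), over the remaining pool
  m_p = (k_i - 1 - T_ij - s_i) * (k_j - 1 - T_ij - s_j), where s_i / s_j
  are the side neighbours already matched in chordless squares.  Pair
  participation (rather than the raw 5-cycle count, which is exposed by
  :func:`edge_chordless_pentagon_count`) keeps the density in [0, 1]: many
  pentagons can share one (a, b) pair, so the raw count has no
  degree-determined maximum.

Per-edge ratios are averaged over edges whose endpoints both have degree
greater than one and whose denominator is positive.  Longer chordless
cycles are not computed: their frequency in small-world graphs is
negligible.  The mean local node clustering C (nodes of degree >= 2) is
reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from numba import njit

__all__ = [
    "CyclePhasePoint",
    "edge_triangle_count",
    "edge_chordless_square_count",
    "edge_chordless_pentagon_count",
    "phase_point",
    "phase_point_from_edges",
    "mean_triangle_density_from_edges",
]


@dataclass
class CyclePhasePoint:
    """Normalized mean chordless-cycle densities of one graph."""

    C_t: float
    C_s: float
    C_p: float
    C: float
    n_edges_eligible: int
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.C_t, self.C_s, self.C_p])


def _check_edge(graph: nx.Graph, edge) -> tuple:
    i, j = edge
    if not graph.has_edge(i, j):
        raise ValueError(f"edge {edge!r} not in graph")
    return i, j


def edge_triangle_count(graph: nx.Graph, edge) -> int:
    """Number of triangles through an edge: |N(i) & N(j)|."""
    i, j = _check_edge(graph, edge)
    return len(set(graph[i]) & set(graph[j]))


def edge_chordless_square_count(graph: nx.Graph, edge) -> int:
    """Number of chordless 4-cycles i-a-b-j through edge (i, j)."""
    i, j = _check_edge(graph, edge)
    ni, nj = set(graph[i]), set(graph[j])
    a_pool = ni - nj - {j}
    b_pool = nj - ni - {i}
    return sum(len(b_pool & set(graph[a])) for a in a_pool)


def edge_chordless_pentagon_count(graph: nx.Graph, edge) -> int:
    """Number of chordless 5-cycles i-a-c-b-j through edge (i, j)."""
    i, j = _check_edge(graph, edge)
    ni, nj = set(graph[i]), set(graph[j])
    a_pool = ni - nj - {j}
    b_pool = nj - ni - {i}
    forbidden = ni | nj | {i, j}
    count = 0
    for a in a_pool:
        na = set(graph[a])
        for b in b_pool - na:  # (a, b) must not be an edge
            count += len((na & set(graph[b])) - forbidden)
    return count


_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)
_U1 = np.uint64(1)
_U2 = np.uint64(2)
_U4 = np.uint64(4)
_U56 = np.uint64(56)
_U63 = np.uint64(63)


@njit(cache=True, inline="always")
def _popcount(x):  # pragma: no cover
    x = x - ((x >> _U1) & _M1)
    x = (x & _M2) + ((x >> _U2) & _M2)
    x = (x + (x >> _U4)) & _M4
    return np.int64((x * _H01) >> _U56)


@njit(cache=True)
def _census_kernel_bitset(n, indptr, indices, eu, ev,
                          want_pentagons, want_squares):  # pragma: no cover
    # Dense-bitset counting.  Per edge (i, j) with side pools
    # A = N(i) \ (N(j) u {j}) and B = N(j) \ (N(i) u {i}):
    #   triangles   = popcount(adj[i] & adj[j])
    #   squares     = sum over a in A of popcount(adj[a] & B)
    #   pentagon pair participation: for each square-free a, OR the
    #   adjacency rows of its admissible middles (c not adjacent to i or j)
    #   and popcount the reach against the square-free part of B.
    m = eu.size
    W = (n + 63) // 64
    tri = np.zeros(m, np.int64)
    sq = np.zeros(m, np.int64)
    pent_pairs = np.zeros(m, np.int64)
    s_i = np.zeros(m, np.int64)
    s_j = np.zeros(m, np.int64)
    adj = np.zeros((n, W), np.uint64)
    for e in range(m):
        u = eu[e]
        v = ev[e]
        adj[u, v >> 6] |= _U1 << np.uint64(v & 63)
        adj[v, u >> 6] |= _U1 << np.uint64(u & 63)
    bmask = np.zeros(W, np.uint64)
    bused = np.zeros(W, np.uint64)
    allowed = np.zeros(W, np.uint64)
    reach = np.zeros(W, np.uint64)
    kmax = 0
    for u in range(n):
        if indptr[u + 1] - indptr[u] > kmax:
            kmax = indptr[u + 1] - indptr[u]
    na_list = np.empty(kmax, np.int64)
    na_sq = np.empty(kmax, np.int64)
    for e in range(m):
        i = eu[e]
        j = ev[e]
        t = 0
        for w in range(W):
            t += _popcount(adj[i, w] & adj[j, w])
        tri[e] = t
        if not want_squares:
            continue
        # side pool A as a list, side pool B as a bitmask
        na_n = 0
        for idx in range(indptr[i], indptr[i + 1]):
            a = indices[idx]
            if a != j and (adj[j, a >> 6] >> np.uint64(a & 63)) & _U1 == 0:
                na_list[na_n] = a
                na_n += 1
        for w in range(W):
            bmask[w] = 0
            bused[w] = 0
        for idx in range(indptr[j], indptr[j + 1]):
            b = indices[idx]
            if b != i and (adj[i, b >> 6] >> np.uint64(b & 63)) & _U1 == 0:
                bmask[b >> 6] |= _U1 << np.uint64(b & 63)
        # squares: adjacent (a, b) pairs; track participants on both sides
        sq_e = 0
        s_i_e = 0
        for ai in range(na_n):
            a = na_list[ai]
            cnt = 0
            for w in range(W):
                hit = adj[a, w] & bmask[w]
                cnt += _popcount(hit)
                bused[w] |= hit
            na_sq[ai] = cnt
            sq_e += cnt
            if cnt > 0:
                s_i_e += 1
        sq[e] = sq_e
        s_i[e] = s_i_e
        sj = 0
        for w in range(W):
            sj += _popcount(bused[w])
        s_j[e] = sj
        if not want_pentagons:
            continue
        # admissible middles: not adjacent to i or j, not i or j themselves
        for w in range(W):
            allowed[w] = ~(adj[i, w] | adj[j, w])
        allowed[i >> 6] &= ~(_U1 << np.uint64(i & 63))
        allowed[j >> 6] &= ~(_U1 << np.uint64(j & 63))
        for w in range(W):
            bmask[w] &= ~bused[w]  # square-free part of B
        pairs = 0
        for ai in range(na_n):
            if na_sq[ai] > 0:
                continue
            a = na_list[ai]
            for w in range(W):
                reach[w] = 0
            for idx in range(indptr[a], indptr[a + 1]):
                c = indices[idx]
                if (allowed[c >> 6] >> np.uint64(c & 63)) & _U1:
                    for w in range(W):
                        reach[w] |= adj[c, w]
            for w in range(W):
                pairs += _popcount(reach[w] & bmask[w] & ~adj[a, w])
        pent_pairs[e] = pairs
    return tri, sq, pent_pairs, s_i, s_j


@njit(cache=True)
def _census_kernel_sparse(n, indptr, indices, eu, ev,
                          want_pentagons, want_squares):  # pragma: no cover
    # Mark-array fallback for graphs too large for per-node bitsets.
    m = eu.size
    tri = np.zeros(m, np.int64)
    sq = np.zeros(m, np.int64)
    pent_pairs = np.zeros(m, np.int64)
    s_i = np.zeros(m, np.int64)
    s_j = np.zeros(m, np.int64)
    in_i = np.zeros(n, np.uint8)
    in_j = np.zeros(n, np.uint8)
    in_b = np.zeros(n, np.uint8)
    mark_a = np.zeros(n, np.uint8)
    a_used = np.zeros(n, np.uint8)
    b_used = np.zeros(n, np.uint8)
    kmax = 0
    for v in range(n):
        if indptr[v + 1] - indptr[v] > kmax:
            kmax = indptr[v + 1] - indptr[v]
    na_list = np.empty(kmax, np.int64)
    nb_list = np.empty(kmax, np.int64)
    for e in range(m):
        i = eu[e]
        j = ev[e]
        for idx in range(indptr[i], indptr[i + 1]):
            in_i[indices[idx]] = 1
        for idx in range(indptr[j], indptr[j + 1]):
            in_j[indices[idx]] = 1
        t = 0
        for idx in range(indptr[j], indptr[j + 1]):
            if in_i[indices[idx]]:
                t += 1
        tri[e] = t
        if want_squares:
            na_n = 0
            for idx in range(indptr[i], indptr[i + 1]):
                a = indices[idx]
                if a != j and in_j[a] == 0:
                    na_list[na_n] = a
                    na_n += 1
            nb_n = 0
            for idx in range(indptr[j], indptr[j + 1]):
                b = indices[idx]
                if b != i and in_i[b] == 0:
                    nb_list[nb_n] = b
                    nb_n += 1
                    in_b[b] = 1
            # squares: scan each a's neighbourhood for members of B
            sq_e = 0
            for ai in range(na_n):
                a = na_list[ai]
                for idx in range(indptr[a], indptr[a + 1]):
                    b = indices[idx]
                    if in_b[b] == 0:
                        continue
                    sq_e += 1
                    if a_used[a] == 0:
                        a_used[a] = 1
                        s_i[e] += 1
                    if b_used[b] == 0:
                        b_used[b] = 1
                        s_j[e] += 1
            sq[e] = sq_e
            # pentagon pair participation among square-free side pairs
            if want_pentagons:
                for ai in range(na_n):
                    a = na_list[ai]
                    if a_used[a] == 1:
                        continue
                    # mark_a = 2 flags admissible middles adjacent to a
                    for idx in range(indptr[a], indptr[a + 1]):
                        c = indices[idx]
                        if in_i[c] == 0 and in_j[c] == 0 and c != i and c != j:
                            mark_a[c] = 2
                        else:
                            mark_a[c] = 1
                    for bi in range(nb_n):
                        b = nb_list[bi]
                        if b_used[b] == 1 or mark_a[b] != 0:
                            continue
                        for idx in range(indptr[b], indptr[b + 1]):
                            if mark_a[indices[idx]] == 2:
                                pent_pairs[e] += 1
                                break
                    for idx in range(indptr[a], indptr[a + 1]):
                        mark_a[indices[idx]] = 0
            for ai in range(na_n):
                a_used[na_list[ai]] = 0
            for bi in range(nb_n):
                b_used[nb_list[bi]] = 0
                in_b[nb_list[bi]] = 0
        for idx in range(indptr[i], indptr[i + 1]):
            in_i[indices[idx]] = 0
        for idx in range(indptr[j], indptr[j + 1]):
            in_j[indices[idx]] = 0
    return tri, sq, pent_pairs, s_i, s_j


# above this size the per-node bitset table gets too large; fall back to
# mark arrays
_BITSET_MAX_NODES = 32768


def _census_kernel(n, indptr, indices, eu, ev, want_pentagons, want_squares):
    if n <= _BITSET_MAX_NODES:
        return _census_kernel_bitset(n, indptr, indices, eu, ev,
                                     want_pentagons, want_squares)
    return _census_kernel_sparse(n, indptr, indices, eu, ev,
                                 want_pentagons, want_squares)


def _csr_fast(n: int, eu: np.ndarray, ev: np.ndarray):
    both = np.concatenate([eu, ev])
    other = np.concatenate([ev, eu])
    deg = np.bincount(both, minlength=n).astype(np.int64)
    order = np.argsort(both, kind="stable")
    indices = other[order].astype(np.int32)
    indptr = np.zeros(n + 1, np.int64)
    np.cumsum(deg, out=indptr[1:])
    return deg, indptr, indices


def phase_point_from_edges(n: int, eu: np.ndarray, ev: np.ndarray,
                           pentagons: bool = True,
                           squares: bool = True) -> CyclePhasePoint:
    """Census from raw edge arrays (nodes 0..n-1, each edge listed once)."""
    eu = np.asarray(eu, dtype=np.int64)
    ev = np.asarray(ev, dtype=np.int64)
    if eu.size == 0:
        warnings.warn("graph has no edges; densities reported as 0")
        return CyclePhasePoint(0.0, 0.0, 0.0, 0.0, 0, degenerate=True)
    if pentagons and not squares:
        raise ValueError("pentagon counting requires the square stage")
    deg, indptr, indices = _csr_fast(n, eu, ev)
    tri, sq, pent_pairs, s_i, s_j = _census_kernel(
        n, indptr, indices, eu.astype(np.int32), ev.astype(np.int32),
        pentagons, squares)
    ki, kj = deg[eu], deg[ev]
    eligible = (ki > 1) & (kj > 1)
    m_t = np.minimum(ki, kj) - 1
    free_i = ki - 1 - tri
    free_j = kj - 1 - tri
    m_s = free_i * free_j
    m_p = (free_i - s_i) * (free_j - s_j)

    def _avg(counts, denom):
        ok = eligible & (denom > 0)
        if not ok.any():
            return 0.0
        ratio = counts[ok] / denom[ok]
        return float(ratio.mean())

    c_t = _avg(tri, m_t)
    c_s = _avg(sq, m_s) if squares else 0.0
    c_p = _avg(pent_pairs, m_p) if pentagons else 0.0
    # local node clustering over nodes with degree >= 2
    node_tri = np.zeros(n, dtype=np.float64)
    np.add.at(node_tri, eu, tri)
    np.add.at(node_tri, ev, tri)
    node_tri /= 2.0
    nodes_ok = deg >= 2
    if nodes_ok.any():
        denom = deg[nodes_ok] * (deg[nodes_ok] - 1) / 2.0
        c_node = float((node_tri[nodes_ok] / denom).mean())
    else:
        c_node = 0.0
    n_eligible = int(eligible.sum())
    degenerate = n_eligible == 0
    if degenerate:
        warnings.warn("no eligible edges (all endpoints of degree <= 1)")
    return CyclePhasePoint(c_t, c_s, c_p, c_node, n_eligible, degenerate)


def mean_triangle_density_from_edges(n: int, eu: np.ndarray, ev: np.ndarray) -> float:
    """C_t only (cheap path for calibration sweeps)."""
    return phase_point_from_edges(n, eu, ev, pentagons=False, squares=False).C_t


def _graph_to_edges(graph: nx.Graph) -> tuple[int, np.ndarray, np.ndarray]:
    nodes = list(graph.nodes())
    relabel = {u: idx for idx, u in enumerate(nodes)}
    m = graph.number_of_edges()
    eu = np.empty(m, np.int64)
    ev = np.empty(m, np.int64)
    for e, (u, v) in enumerate(graph.edges()):
        eu[e] = relabel[u]
        ev[e] = relabel[v]
    return len(nodes), eu, ev


def phase_point(graph: nx.Graph) -> CyclePhasePoint:
    """Cycle-density phase point (C_t, C_s, C_p) plus node clustering C."""
    if graph.is_directed() or graph.is_multigraph():
        raise ValueError("phase_point requires a simple undirected graph")
    n, eu, ev = _graph_to_edges(graph)
    return phase_point_from_edges(n, eu, ev)
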