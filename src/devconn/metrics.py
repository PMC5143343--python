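"""Graph metrics for binary and weighted structural connectomes.

Conventions (Rubinov & Sporns framework):

* Degree of a node: number of distinct neighbors; strength: sum of incident
  edge weights.  Network-level values are means over nodes.
* Path length: hop count for binary networks; for weighted networks each step
  has length 1/weight (stronger connections are "shorter"), and the path
  length is the minimal sum of step lengths.
* Global efficiency E = mean over ordered node pairs i != j of 1/d(i, j);
  disconnected pairs contribute 0.  Under uniform weight scaling w -> c*w the
  weighted efficiency scales as c*E.
* Local efficiency: mean over nodes of the global efficiency of the subgraph
  induced by the node's neighbors (the node itself excluded, original weights
  retained); nodes with fewer than 2 neighbors contribute 0.
* Clustering: binary C_i = 2 t_i / (k_i (k_i - 1)) with t_i the triangle
  count at i; weighted clustering is the Onnela geometric-mean triangle
  intensity computed on the raw weights, which are assumed to lie in [0, 1]
  (FA and FA-normalized weights do).  With all weights equal to 1 every
  weighted metric equals its binary counterpart exactly.
"""

from __future__ import annotations

import numba
import numpy as np

from .core import Connectome

#: Column order of the per-subject metric table (Table-style inventory:
#: 4 binary + 4 FA-weighted + 3 FA-normalized values).
METRIC_COLUMNS = [
    "binary_degree",
    "binary_global_efficiency",
    "binary_local_efficiency",
    "binary_clustering",
    "faw_strength",
    "faw_global_efficiency",
    "faw_local_efficiency",
    "faw_clustering",
    "fan_global_efficiency",
    "fan_local_efficiency",
    "fan_clustering",
]

__all__ = [
    "METRIC_COLUMNS",
    "average_degree",
    "average_strength",
    "mean_edge_weight",
    "global_efficiency",
    "local_efficiency",
    "average_clustering",
    "compute_metric_table",
]


def _matrix(connectome) -> np.ndarray:
    if isinstance(connectome, Connectome):
        return connectome.matrix
    m = np.asarray(connectome, dtype=float)
    return m


def _is_weighted(connectome) -> bool:
    if isinstance(connectome, Connectome):
        return connectome.variant != "binary"
    return bool((~np.isin(np.asarray(connectome), (0.0, 1.0))).any())


def average_degree(connectome) -> float:
    """Mean over nodes of the number of distinct neighbors.

    Uses the non-zero pattern, so it is identical for all variants built from
    the same streamline set.
    """
    m = _matrix(connectome)
    return float((m > 0).sum(axis=1).mean()) if m.size else 0.0

def average_strength(connectome) -> float:
    """Mean over nodes of the summed incident edge weights."""
    m = _matrix(connectome)
    return float(m.sum(axis=1).mean()) if m.size else 0.0

def mean_edge_weight(connectome) -> float:
    """Average nodal strength divided by (n - 1).

    Equivalently the mean weight over all possible node pairs; reported
    alongside :func:`average_strength` because both normalizations of
    "network strength" appear in the literature.
    """
    m = _matrix(connectome)
    n = m.shape[0]
    if n < 2:
        return 0.0
    return average_strength(m) / (n - 1)


@numba.njit(cache=True)
def _fw_inplace(L):  # pragma: no cover - exercised via wrappers
    """Floyd-Warshall on a step-length matrix (inf = no edge), in place."""
    n = L.shape[0]
    for k in range(n):
        for i in range(n):
            lik = L[i, k]
            if lik == np.inf:
                continue
            for j in range(n):
                v = lik + L[k, j]
                if v < L[i, j]:
                    L[i, j] = v


@numba.njit(cache=True)
def _efficiency_from_lengths(L):  # pragma: no cover
    n = L.shape[0]
    _fw_inplace(L)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and L[i, j] < np.inf:
                total += 1.0 / L[i, j]
    return total / (n * (n - 1))


@numba.njit(cache=True)
def _local_efficiency_kernel(m, weighted):  # pragma: no cover
    n = m.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(m[i])
        k = nbrs.size
        if k < 2:
            continue
        L = np.empty((k, k))
        for a in range(k):
            L[a, a] = 0.0
            for b in range(k):
                if a == b:
                    continue
                w = m[nbrs[a], nbrs[b]]
                if w > 0.0:
                    L[a, b] = 1.0 / w if weighted else 1.0
                else:
                    L[a, b] = np.inf
        total += _efficiency_from_lengths(L)
    return total / n


def _length_matrix(m: np.ndarray, weighted: bool) -> np.ndarray:
    n = m.shape[0]
    L = np.full((n, n), np.inf)
    pos = m > 0
    L[pos] = 1.0 / m[pos] if weighted else 1.0
    np.fill_diagonal(L, 0.0)
    return L


def _efficiency_from_matrix(m: np.ndarray, weighted: bool) -> float:
    """Mean inverse shortest-path distance over ordered pairs."""
    n = m.shape[0]
    if n < 2:
        return 0.0
    return float(_efficiency_from_lengths(_length_matrix(m, weighted)))


def global_efficiency(connectome, weighted: bool | None = None) -> float:
    """Global efficiency: mean over ordered pairs (i != j) of 1/d(i, j).

    Binary networks use hop-count distances; weighted networks use minimal
    sums of inverse weights.  Disconnected pairs contribute 0.
    """
    if weighted is None:
        weighted = _is_weighted(connectome)
    return _efficiency_from_matrix(_matrix(connectome), weighted)


def local_efficiency(connectome, weighted: bool | None = None) -> float:
    """Mean over nodes of the efficiency of the neighbor-induced subgraph.

    The subgraph excludes the node itself and keeps original weights; nodes
    with fewer than 2 neighbors contribute 0.
    """
    if weighted is None:
        weighted = _is_weighted(connectome)
    m = _matrix(connectome)
    if m.shape[0] == 0:
        return 0.0
    return float(_local_efficiency_kernel(np.ascontiguousarray(m), bool(weighted)))


def average_clustering(connectome, weighted: bool | None = None) -> float:
    """Mean clustering coefficient over all nodes.

    Binary: fraction of closed triangles around each node.  Weighted: Onnela
    geometric-mean triangle intensity on the raw weights (assumed in [0, 1]),
    i.e. C_i = sum_{jk} (w_ij w_jk w_ki)^(1/3) / (k_i (k_i - 1)).  Nodes with
    fewer than 2 neighbors count 0.
    """
    if weighted is None:
        weighted = _is_weighted(connectome)
    m = _matrix(connectome)
    n = m.shape[0]
    if n == 0:
        return 0.0
    k = (m > 0).sum(axis=1)
    denom = k * (k - 1)
    if weighted:
        w = np.cbrt(m)
        tri2 = np.einsum("ij,jk,ki->i", w, w, w)
    else:
        a = (m > 0).astype(float)
        tri2 = np.einsum("ij,jk,ki->i", a, a, a)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri2 / np.where(denom > 0, denom, 1), 0.0)
    return float(c.mean())


def compute_metric_table(binary, fa_weighted, fa_normalized) -> dict:
    """The 11-value per-subject metric table.

    Binary: average degree, global efficiency, local efficiency, clustering.
    FA-weighted: average strength, global efficiency, local efficiency,
    clustering.  FA-normalized: global efficiency, local efficiency,
    clustering (its average nodal strength is 2/n by construction and its
    degree equals the binary degree, so neither is reported).

    Each entry equals the corresponding single-metric operation applied to
    the corresponding variant.
    """
    for conn, variant in ((binary, "binary"), (fa_weighted, "fa_weighted"),
                          (fa_normalized, "fa_normalized")):
        if conn is None:
            raise ValueError(f"missing {variant} connectome")
        if isinstance(conn, Connectome) and conn.variant != variant:
            raise ValueError(f"expected {variant} connectome, got {conn.variant}")
    return {
        "binary_degree": average_degree(binary),
        "binary_global_efficiency": global_efficiency(binary, weighted=False),
        "binary_local_efficiency": local_efficiency(binary, weighted=False),
        "binary_clustering": average_clustering(binary, weighted=False),
        "faw_strength": average_strength(fa_weighted),
        "faw_global_efficiency": global_efficiency(fa_weighted, weighted=True),
        "faw_local_efficiency": local_efficiency(fa_weighted, weighted=True),
        "faw_clustering": average_clustering(fa_weighted, weighted=True),
        "fan_global_efficiency": global_efficiency(fa_normalized, weighted=True),
        "fan_local_efficiency": local_efficiency(fa_normalized, weighted=True),
        "fan_clustering": average_clustering(fa_normalized, weighted=True),
    }
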