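"""Weighted graph topology of a connectivity matrix.

Conventions follow the weighted-network toolbox tradition used throughout
functional-connectivity work: connection lengths are inverse weights,
functional distances are Dijkstra shortest paths on those lengths, the
characteristic path length averages the finite off-diagonal distances,
clustering is the Onnela geometric-mean-of-triangles form on max-normalised
weights, and local efficiency is the cube-root-weighted harmonic mean of
inverse shortest-path lengths within each node's neighbourhood subgraph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra as _dijkstra


def _validate_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T):
        raise ValueError("weight matrix must be symmetric")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w


def node_strength(w: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node strength (sum of incident weights) and its network mean."""
    w = _validate_weights(w)
    s = w.sum(axis=1)
    return s, float(s.mean())


def weight_to_length(w: np.ndarray) -> np.ndarray:
    """Connection-length matrix: L = 1/w, infinite for absent edges."""
    w = _validate_weights(w)
    with np.errstate(divide="ignore"):
        length = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(length, 0.0)
    return length


def functional_distance(length: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths (Dijkstra) on a length matrix.

    Infinite entries mean the pair is unreachable.
    """
    length = np.asarray(length, dtype=float)
    if np.any(length < 0):
        raise ValueError("connection lengths must be nonnegative")
    adj = np.where(np.isfinite(length), length, 0.0)
    np.fill_diagonal(adj, 0.0)
    d = _dijkstra(adj, directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def characteristic_path_length(d: np.ndarray) -> float:
    """Mean of the finite off-diagonal distances (NaN if none).

    Computed over unordered pairs; for a symmetric distance matrix this
    equals the ordered-pair mean.
    """
    d = np.asarray(d, dtype=float)
    iu = np.triu_indices_from(d, k=1)
    vals = d[iu]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return float("nan")
    return float(finite.mean())


def clustering_coefficient(w: np.ndarray, normalize: bool = True,
                           ) -> np.ndarray:
    """Weighted clustering coefficient (Onnela triangle-intensity form).

    With w_hat = w / max(w),

        C_i = sum_{j,h} (w_hat_ij * w_hat_jh * w_hat_ih)**(1/3)
              / (k_i * (k_i - 1))

    where k_i counts strictly positive neighbours; C_i = 0 for k_i < 2.
    """
    w = _validate_weights(w)
    if normalize and w.max() > 0:
        w = w / w.max()
    a = np.cbrt(w)
    cyc = np.diag(a @ a @ a)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    return np.where(denom > 0, cyc / np.where(denom > 0, denom, 1), 0.0)


def local_efficiency(w: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Weighted local efficiency per node.

    For each node u with neighbours V (k = |V| >= 2):

        E_loc(u) = sum_{j,h in V, j != h}
                   (w_uj * w_uh)**(1/3) / d_jh(V) / (k * (k - 1))

    where d_jh(V) is the shortest path between j and h restricted to the
    neighbourhood subgraph, on connection lengths 1/w**(1/3). Nodes with
    fewer than two neighbours score 0.
    """
    w = _validate_weights(w)
    if normalize and w.max() > 0:
        w = w / w.max()
    n = w.shape[0]
    cw = np.cbrt(w)
    eff = np.zeros(n)
    for u in range(n):
        v = np.flatnonzero(w[u])
        k = v.size
        if k < 2:
            continue
        sub = cw[np.ix_(v, v)]
        with np.errstate(divide="ignore"):
            lengths = np.where(sub > 0, 1.0 / np.where(sub > 0, sub, 1.0), 0.0)
        d = _dijkstra(lengths, directed=False)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        np.fill_diagonal(inv, 0.0)
        eff[u] = float(np.sum(np.outer(cw[u, v], cw[u, v]) * inv)) \
            / (k * (k - 1))
    return eff


@dataclass
class GraphMetricsResult:
    """All weighted topology metrics of one connectivity matrix."""

    strength: np.ndarray
    mean_strength: float
    clustering: np.ndarray
    local_efficiency: np.ndarray
    distance: np.ndarray
    char_path_length: float


def graph_metrics(w: np.ndarray) -> GraphMetricsResult:
    """Compute the full metric set for one weight matrix."""
    strength, mean_strength = node_strength(w)
    lengths = weight_to_length(w)
    d = functional_distance(lengths)
    return GraphMetricsResult(
        strength=strength,
        mean_strength=mean_strength,
        clustering=clustering_coefficient(w),
        local_efficiency=local_efficiency(w),
        distance=d,
        char_path_length=characteristic_path_length(d),
    )
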