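"""Weighted global and local efficiency of FC-state graphs.

FC matrices are prepared by zeroing the diagonal and clipping negative
weights to zero (shortest-path lengths require non-negative weights; an
absolute-value alternative is exposed). Path length between adjacent nodes
is 1/weight; efficiency between two nodes is the inverse of their weighted
shortest-path distance, zero for disconnected pairs.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "prepare_fc_graph",
    "global_efficiency",
    "local_efficiency",
]


def prepare_fc_graph(fc: np.ndarray, negative: str = "clip") -> np.ndarray:
    """Non-negative, zero-diagonal weight matrix from an FC matrix.

    ``negative``: ``"clip"`` sets negative weights to 0 (default, standard
    brain-connectivity practice); ``"abs"`` takes absolute values.
    """
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError("fc must be square")
    if not np.allclose(fc, fc.T, atol=1e-8):
        raise ValueError("fc must be symmetric")
    if negative == "clip":
        w = np.where(fc > 0, fc, 0.0)
    elif negative == "abs":
        w = np.abs(fc)
    else:
        raise ValueError("negative must be 'clip' or 'abs'")
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w


def _pairwise_efficiency(weights: np.ndarray) -> np.ndarray:
    """Inverse weighted shortest-path distances (lengths = 1/weight)."""
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / weights, np.inf)
    np.fill_diagonal(lengths, 0.0)
    dist = shortest_path(lengths, method="D", directed=False)
    with np.errstate(divide="ignore"):
        eff = np.where(dist > 0, 1.0 / dist, 0.0)
    eff[np.isinf(dist)] = 0.0
    np.fill_diagonal(eff, 0.0)
    return eff

def global_efficiency(weights: np.ndarray) -> float:
    """Mean over node pairs of 1/(weighted shortest-path distance)."""
    n = weights.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    eff = _pairwise_efficiency(weights)
    return float(eff.sum() / (n * (n - 1)))


def local_efficiency(weights: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of the node's neighborhood.

    The neighborhood of a node is the subgraph induced on its positively
    weighted neighbors, keeping the original weights; nodes with fewer than
    two neighbors contribute 0.
    """
    n = weights.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes")
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(weights[i] > 0)
        if nbrs.size < 2:
            continue
        sub = weights[np.ix_(nbrs, nbrs)]
        total += global_efficiency(sub)
    return float(total / n)
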