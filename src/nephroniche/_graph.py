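"""Shared kNN-graph community detection (Louvain via igraph).

python-igraph draws its randomness from Python's ``random`` module; the
helper seeds and restores that state so clustering is deterministic given
the seed and does not disturb the caller's RNG.
"""

from __future__ import annotations

import random

import numpy as np
import igraph
from sklearn.neighbors import NearestNeighbors

__all__ = ["knn_louvain"]


def knn_louvain(features: np.ndarray, k: int = 15, seed: int = 0,
                resolution: float = 1.0) -> np.ndarray:
    """Louvain communities on a symmetrized kNN graph of row vectors.

    Returns an integer community id per row. Deterministic given
    (features, k, seed, resolution).
    """
    n = features.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} observations, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(features)
    _, idx = nn.kneighbors(features)
    src = np.repeat(np.arange(n), k)
    dst = idx[:, 1:].ravel()
    edges = {(min(a, b), max(a, b)) for a, b in zip(src, dst)}
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    state = random.getstate()
    try:
        random.seed(seed)
        part = g.community_multilevel(resolution=resolution)
    finally:
        random.setstate(state)
    return np.asarray(part.membership, dtype=int)
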