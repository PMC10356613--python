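"""Slide-seq-style bead classification and cell-type proximity enrichment.

Beads carrying per-type deconvolution weights are classified by a
hierarchical relative-weight threshold (40% at level 1; 30% or 50% at
level 2). A neighborhood network is built from the Delaunay triangulation
of bead positions keeping edges shorter than 50 µm, and cell-type pair
proximity is scored as observed over expected edge counts, where the
expectation comes from uniformly permuting the labels over all beads
(2,500 permutations by default). Per-region summaries average the
enrichment ratios across pucks and flag pairs below the display cutoff
(0.7 cortex, 0.8 medulla).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree

__all__ = [
    "classify_beads",
    "classify_beads_hierarchical",
    "build_network",
    "proximity_enrichment",
    "average_enrichment",
]

UNCLASSIFIED = "unclassified"


def classify_beads(weights: pd.DataFrame, threshold: float = 40.0) -> pd.Series:
    """Assign each bead the type whose relative weight meets the threshold.

    Weights are normalized to sum to 100 per bead; a bead is classified as
    the type with the (unique) maximum relative weight when that weight is
    >= ``threshold`` (percent). All-zero beads, and beads whose maximum is
    tied between two or more types, are left unclassified. The result is
    invariant to uniform rescaling of a bead's weight vector.
    """
    w = weights.to_numpy(dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    totals = w.sum(axis=1)
    out = np.full(len(weights), UNCLASSIFIED, dtype=object)
    ok = totals > 0
    rel = np.zeros_like(w)
    rel[ok] = w[ok] / totals[ok, None] * 100.0
    top = rel.max(axis=1)
    tied = (rel == top[:, None]).sum(axis=1) > 1
    assign = ok & (top >= threshold) & ~tied
    cols = np.asarray(weights.columns, dtype=object)
    out[assign] = cols[rel[assign].argmax(axis=1)]
    return pd.Series(out, index=weights.index, name="label")


def classify_beads_hierarchical(
    l1_weights: pd.DataFrame,
    l2_weights: pd.DataFrame,
    child_map: dict[str, list[str]],
    l1_threshold: float = 40.0,
    l2_threshold: float = 30.0,
) -> pd.DataFrame:
    """Two-level classification: level-1 first, then level-2 within the
    assigned parent. A level-2 label always implies its level-1 parent; a
    bead whose level-2 weights miss the cutoff keeps its level-1 label with
    no level-2 assignment."""
    if l2_threshold not in (30.0, 50.0):
        warnings.warn("level-2 threshold is conventionally 30 or 50")
    l1 = classify_beads(l1_weights, threshold=l1_threshold)
    l2 = pd.Series(UNCLASSIFIED, index=l1.index, dtype=object, name="label_l2")
    for parent, children in child_map.items():
        beads = l1.index[l1 == parent]
        cols = [c for c in children if c in l2_weights.columns]
        if len(beads) == 0 or not cols:
            continue
        sub = classify_beads(l2_weights.loc[beads, cols],
                             threshold=l2_threshold)
        l2.loc[beads] = sub
    return pd.DataFrame({"label_l1": l1, "label_l2": l2})


def build_network(beads: pd.DataFrame, max_dist: float = 50.0,
                  x: str = "x_um", y: str = "y_um") -> pd.DataFrame:
    """Delaunay edges between beads, keeping edges shorter than ``max_dist``.

    Returns an edge table (i, j, dist_um) with i/j positional indices into
    ``beads`` and i < j. Degenerate (collinear) geometries fall back to a
    2-nearest-neighbor graph before the distance filter.
    """
    pts = beads[[x, y]].to_numpy(dtype=float)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 beads to build a network")
    try:
        tri = Delaunay(pts)
        pairs = set()
        for simplex in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    i, j = sorted((int(simplex[a]), int(simplex[b])))
                    pairs.add((i, j))
        edges = np.array(sorted(pairs), dtype=int)
    except QhullError:
        tree = cKDTree(pts)
        _d, nbr = tree.query(pts, k=min(3, n))
        pairs = set()
        for i in range(n):
            for j in nbr[i][1:]:
                pairs.add(tuple(sorted((i, int(j)))))
        edges = np.array(sorted(pairs), dtype=int)
    if len(edges) == 0:
        return pd.DataFrame(columns=["i", "j", "dist_um"])
    dist = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    keep = dist < max_dist
    return pd.DataFrame({"i": edges[keep, 0], "j": edges[keep, 1],
                         "dist_um": dist[keep]}).reset_index(drop=True)


def _pair_counts(codes_u: np.ndarray, codes_v: np.ndarray,
                 n_labels: int) -> np.ndarray:
    """Counts per unordered label pair; supports stacked permutations.

    ``codes_u``/``codes_v`` are (..., E) label codes of the edge endpoints;
    returns (..., n_pairs) counts with pairs enumerated as (a<=b) in
    lexicographic order.
    """
    lo = np.minimum(codes_u, codes_v)
    hi = np.maximum(codes_u, codes_v)
    pair_id = lo * n_labels - (lo * (lo - 1)) // 2 + (hi - lo)
    n_pairs = n_labels * (n_labels + 1) // 2
    if pair_id.ndim == 1:
        return np.bincount(pair_id, minlength=n_pairs)
    flat = pair_id + (np.arange(pair_id.shape[0])[:, None] * n_pairs)
    return np.bincount(flat.ravel(),
                       minlength=n_pairs * pair_id.shape[0]
                       ).reshape(pair_id.shape[0], n_pairs)


def proximity_enrichment(network: pd.DataFrame, labels: pd.Series | np.ndarray,
                         n_perm: int = 2500, seed: int = 0,
                         pseudocount: bool = False,
                         block_size: int = 250) -> pd.DataFrame:
    """Observed/expected edge counts per unordered cell-type pair.

    ``labels`` must align positionally with the bead table the network was
    built from. Labels are permuted uniformly over all beads ``n_perm``
    times; expected counts are permutation means and the empirical p is
    two-sided around the permutation mean,
    p = (1 + #{|perm - mean| >= |obs - mean|}) / (1 + n_perm).
    Pairs with expected 0 get a missing ratio unless ``pseudocount`` adds
    0.5 to both observed and expected. The RNG is a counter-based Philox
    generator keyed by ``seed``.
    """
    labels = np.asarray(labels, dtype=object)
    levels, codes = np.unique(labels.astype(str), return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 distinct labels")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives coarse p-values")
    u = network["i"].to_numpy()
    v = network["j"].to_numpy()
    nl = len(levels)

    observed = _pair_counts(codes[u], codes[v], nl)
    rng = np.random.Generator(np.random.Philox(key=seed & 0xFFFFFFFF))
    perm_counts = np.empty((n_perm, len(observed)), dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(block_size, n_perm - done)
        perm = rng.permuted(np.tile(codes, (b, 1)), axis=1)
        perm_counts[done:done + b] = _pair_counts(perm[:, u], perm[:, v], nl)
        done += b

    expected = perm_counts.mean(axis=0)
    dev_obs = np.abs(observed - expected)
    dev_perm = np.abs(perm_counts - expected[None, :])
    p = (1.0 + (dev_perm >= dev_obs[None, :]).sum(axis=0)) / (1.0 + n_perm)
    if pseudocount:
        ratio = (observed + 0.5) / (expected + 0.5)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(expected > 0, observed / np.where(expected > 0,
                                                               expected, 1.0),
                             np.nan)
    ia, ib = np.triu_indices(nl)
    return pd.DataFrame({
        "type_a": levels[ia],
        "type_b": levels[ib],
        "observed": observed,
        "expected": expected,
        "ratio": ratio,
        "p": p,
        "n_perm": n_perm,
    })


def average_enrichment(tables: dict[str, pd.DataFrame] | list[pd.DataFrame],
                       display_cutoff: float = 0.7) -> pd.DataFrame:
    """Unweighted mean enrichment ratio per pair across pucks of one region.

    Pairs present in only some pucks are averaged over the pucks where they
    occur (``n_pucks`` reports how many). Pairs whose mean ratio does not
    exceed ``display_cutoff`` are flagged ``hidden`` (cortex convention
    0.7, medulla 0.8).
    """
    if isinstance(tables, dict):
        tables = list(tables.values())
    if len(tables) == 0:
        raise ValueError("need at least one enrichment table")
    cat = pd.concat(tables, ignore_index=True)
    cat = cat.dropna(subset=["ratio"])
    grp = cat.groupby(["type_a", "type_b"], as_index=False).agg(
        mean_ratio=("ratio", "mean"), n_pucks=("ratio", "size"))
    grp["hidden"] = ~(grp["mean_ratio"] > display_cutoff)
    return grp
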