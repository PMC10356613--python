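"""3D tissue-cytometry neighborhoods and niche communities.

For every cell, the neighborhood is the set of cells within a 25 µm
Euclidean radius (the index cell included). Per-class count (sum) and
fraction-of-total features are computed per neighborhood; monotypic
neighborhoods are removed; the sum features are Z-standardized and
clustered with Louvain on a kNN graph to detect recurrent niches;
pairwise class co-occurrence is tallied per neighborhood and Pearson
correlations between class counts (with two-sided t-test p-values)
summarize class co-abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from ._graph import knn_louvain

__all__ = [
    "NeighborhoodMatrix",
    "build_neighborhoods",
    "filter_monotypic",
    "detect_niches",
    "pairwise_interactions",
    "interaction_correlations",
]


@dataclass
class NeighborhoodMatrix:
    """Per-neighborhood class composition (index = index-cell id)."""

    counts: pd.DataFrame             # neighborhoods x classes, integer sums

    @property
    def total(self) -> pd.Series:
        return self.counts.sum(axis=1).rename("total")

    @property
    def fractions(self) -> pd.DataFrame:
        return self.counts.div(self.total, axis=0)


def build_neighborhoods(cells: pd.DataFrame, radius: float = 25.0,
                        include_index: bool = True,
                        id_col: str = "cell_id", class_col: str = "class",
                        coords: tuple[str, str, str] = ("x_um", "y_um", "z_um"),
                        ) -> NeighborhoodMatrix:
    """Count cells of each class within ``radius`` µm of every index cell."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if len(cells) == 0:
        raise ValueError("empty cell table")
    xyz = cells[list(coords)].to_numpy(dtype=float)
    classes = sorted(cells[class_col].astype(str).unique())
    code = cells[class_col].astype(str).map({c: i for i, c in enumerate(classes)})
    code = code.to_numpy()

    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    n = len(cells)
    counts = np.zeros((n, len(classes)), dtype=np.int64)
    if len(pairs):
        np.add.at(counts, (pairs[:, 0], code[pairs[:, 1]]), 1)
        np.add.at(counts, (pairs[:, 1], code[pairs[:, 0]]), 1)
    if include_index:
        np.add.at(counts, (np.arange(n), code), 1)
    ids = cells[id_col].astype(str) if id_col in cells.columns else cells.index
    return NeighborhoodMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(ids, name="neighborhood"),
                            columns=classes))


def filter_monotypic(nm: NeighborhoodMatrix) -> NeighborhoodMatrix:
    """Remove neighborhoods whose cells all carry a single class."""
    if len(nm.counts) == 0:
        raise ValueError("empty neighborhood matrix")
    n_classes_present = (nm.counts > 0).sum(axis=1)
    keep = n_classes_present > 1
    if not keep.any():
        warnings.warn("all neighborhoods are monotypic; empty result")
    return NeighborhoodMatrix(counts=nm.counts.loc[keep])


def detect_niches(nm: NeighborhoodMatrix, k: int = 30, seed: int = 0,
                  resolution: float = 0.3) -> pd.Series:
    """Louvain communities on Z-standardized per-class sum features.

    Zero-variance columns are dropped with a warning. The result is
    deterministic given the seed and invariant to row order (rows are
    canonicalized by neighborhood id before clustering).
    """
    counts = nm.counts.sort_index(kind="stable")
    sd = counts.std(axis=0, ddof=0)
    dead = sd[sd == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping zero-variance classes: {dead}")
        counts = counts.drop(columns=dead)
        sd = sd.drop(dead)
    if counts.shape[1] == 0:
        raise ValueError("no informative class columns left")
    z = (counts - counts.mean(axis=0)) / sd
    membership = knn_louvain(z.to_numpy(), k=k, seed=seed,
                             resolution=resolution)
    out = pd.Series(membership, index=counts.index, name="community")
    return out.loc[nm.counts.index]


def pairwise_interactions(nm: NeighborhoodMatrix,
                          per_cell_pair: bool = False) -> pd.DataFrame:
    """Tally class pair co-occurrence across neighborhoods.

    Default: each unordered class pair both present in a neighborhood
    contributes 1 (diagonal: neighborhoods where the class count is >= 2).
    With ``per_cell_pair`` each neighborhood contributes the number of
    distinct cell pairs instead (n_a * n_b off-diagonal, C(n_a, 2) on the
    diagonal).
    """
    c = nm.counts.to_numpy(dtype=np.int64)
    if per_cell_pair:
        m = c.T @ c
        np.fill_diagonal(m, ((c * (c - 1)) // 2).sum(axis=0))
    else:
        p = (c > 0).astype(np.int64)
        m = p.T @ p
        np.fill_diagonal(m, (c >= 2).sum(axis=0))
    return pd.DataFrame(m, index=nm.counts.columns, columns=nm.counts.columns)


def interaction_correlations(nm: NeighborhoodMatrix
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r between class-count columns, with two-sided t-test p.

    Constant columns yield missing r and p. Requires >= 3 neighborhoods
    (df = n - 2)."""
    n = len(nm.counts)
    if n < 3:
        raise ValueError("need at least 3 neighborhoods")
    x = nm.counts.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r[np.isnan(sd) | (sd == 0), :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, np.where(sd > 0, 1.0, np.nan))
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1 - r ** 2, 1e-300))
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    np.fill_diagonal(p, np.nan)
    cols = nm.counts.columns
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))
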