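"""Differentially accessible regions with depth-matched backgrounds.

A test cell group is compared against background cells sampled from the
rest of the dataset so that the background's per-cell depth (total
accessible peak count) distribution matches the test group's — this
removes the depth confound that otherwise inflates per-peak enrichment.
Per peak, accessibility is binarized and a one-sided hypergeometric
(Fisher) enrichment test is applied; Benjamini–Hochberg q-values are
computed across the group's peaks and DARs are selected at q < 0.01 and
natural-log fold change > 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from ._rng import stream_rng

__all__ = ["match_background", "test_dars", "filter_dars", "group_retained"]


def match_background(depths: pd.Series | np.ndarray,
                     test_mask: pd.Series | np.ndarray,
                     n_background: int = 10000,
                     n_bins: int = 25,
                     seed: int = 0) -> np.ndarray:
    """Sample background cells whose depth distribution matches the test's.

    The pooled depths are split into ``n_bins`` quantile bins; background
    cells are drawn from the non-test pool without replacement with
    per-bin allocations proportional to the test group's bin density
    (largest-remainder rounding; overflow beyond a bin's pool is
    redistributed to the remaining bins). Returns positional indices of
    the sampled background cells. Deterministic given the seed.
    """
    depths = np.asarray(depths, dtype=float)
    test_mask = np.asarray(test_mask, dtype=bool)
    pool_idx = np.where(~test_mask)[0]
    if len(pool_idx) == 0:
        raise ValueError("empty non-test pool")
    if n_background > len(pool_idx):
        warnings.warn(f"pool has only {len(pool_idx)} cells; reducing "
                      f"n_background from {n_background}")
        n_background = len(pool_idx)

    edges = np.quantile(depths, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    edges[0], edges[-1] = -np.inf, np.inf
    test_bin = np.digitize(depths[test_mask], edges[1:-1])
    pool_bin = np.digitize(depths[pool_idx], edges[1:-1])
    nb = len(edges) - 1

    test_density = np.bincount(test_bin, minlength=nb).astype(float)
    test_density /= test_density.sum()
    pool_counts = np.bincount(pool_bin, minlength=nb)

    # allocate per-bin sample sizes, redistributing overflow
    target = test_density.copy()
    alloc = np.zeros(nb, dtype=int)
    remaining = n_background
    active = pool_counts > 0
    while remaining > 0 and active.any():
        w = np.where(active, target, 0.0)
        if w.sum() == 0:
            w = active.astype(float)
        w = w / w.sum()
        ideal = w * remaining
        add = np.floor(ideal).astype(int)
        # largest remainders get the leftover units
        short = remaining - add.sum()
        if short > 0:
            order = np.argsort(-(ideal - add), kind="stable")
            add[order[:short]] += 1
        add = np.minimum(add, pool_counts - alloc)
        alloc += add
        active = (pool_counts - alloc) > 0
        remaining = n_background - alloc.sum()
        if add.sum() == 0 and remaining > 0:
            break

    rng = stream_rng(seed, "match_background")
    chosen = []
    for b in range(nb):
        if alloc[b] == 0:
            continue
        members = pool_idx[pool_bin == b]
        chosen.append(rng.choice(members, size=alloc[b], replace=False))
    return np.sort(np.concatenate(chosen)) if chosen else np.array([], int)


def test_dars(x, test_idx: np.ndarray, background_idx: np.ndarray,
              peak_names: list[str] | None = None) -> pd.DataFrame:
    """One-sided hypergeometric enrichment per peak, test vs background.

    ``x`` is peaks x cells or an AnnData-style cells x peaks matrix given
    as (cells x peaks); pass the matrix with peaks as COLUMNS (cells x
    peaks). Accessibility is binarized at count >= 1. The p-value is the
    upper hypergeometric tail for drawing ``a`` accessible cells in the
    test group out of ``a + b`` accessible overall; the natural-log fold
    change uses a pseudo-rate eps = 1/(n_test + n_bg). q-values are BH
    across the tested peaks; peaks accessible in neither group are
    reported untested.
    """
    test_idx = np.asarray(test_idx)
    background_idx = np.asarray(background_idx)
    if len(test_idx) == 0 or len(background_idx) == 0:
        raise ValueError("both cell sets must be nonempty")
    if np.intersect1d(test_idx, background_idx).size:
        raise ValueError("test and background cells must be disjoint")

    xb = x > 0
    if sparse.issparse(xb):
        a = np.ravel(xb[test_idx].sum(axis=0)).astype(int)
        b = np.ravel(xb[background_idx].sum(axis=0)).astype(int)
    else:
        xb = np.asarray(xb)
        a = xb[test_idx].sum(axis=0).astype(int)
        b = xb[background_idx].sum(axis=0).astype(int)
    n1, n2 = len(test_idx), len(background_idx)
    tested = (a + b) > 0

    p = np.full(len(a), np.nan)
    p[tested] = hypergeom.sf(a[tested] - 1, n1 + n2, (a + b)[tested], n1)
    eps = 1.0 / (n1 + n2)
    log_fc = np.log((a / n1 + eps) / (b / n2 + eps))
    q = np.full(len(a), np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]

    idx = (pd.Index(peak_names, name="peak") if peak_names is not None
           else pd.RangeIndex(len(a), name="peak"))
    return pd.DataFrame({
        "n_accessible_test": a,
        "n_accessible_background": b,
        "rate_test": a / n1,
        "rate_background": b / n2,
        "log_fc": log_fc,
        "p": p,
        "q": q,
        "tested": tested,
    }, index=idx)


def filter_dars(result: pd.DataFrame, q_max: float = 0.01,
                lfc_min: float = 1.0) -> pd.Index:
    """Peaks with q < ``q_max`` and log fold change > ``lfc_min``."""
    keep = result["tested"] & (result["q"] < q_max) & \
        (result["log_fc"] > lfc_min)
    return result.index[keep.fillna(False)]


def group_retained(result: pd.DataFrame, min_dars: int = 100,
                   q_max: float = 0.01) -> bool:
    """Retention rule for a cell grouping: more than ``min_dars`` peaks at
    q < ``q_max`` (applied before the fold-change filter)."""
    n = int((result["tested"] & (result["q"] < q_max)).sum())
    return n > min_dars
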