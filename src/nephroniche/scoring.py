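"""Cell-state scoring, conserved marker selection, and batch-mixing entropy.

Implements the altered-state scoring procedure used for kidney injury
states: library-size log-normalization, a correlation filter that keeps
only genes coherent with the averaged gene-set profile (minimum Pearson
correlation 0.1 by default), per-cell averaging of the retained genes,
a bulk composite average-Z score, conserved-marker intersection across
conditions and cell groupings, and a normalized batch-mixing entropy
weighted by subclass size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse
from scipy.stats import mannwhitneyu

__all__ = [
    "GeneSetScoreResult",
    "MarkerSet",
    "normalize_counts",
    "filter_gene_set",
    "score_cells",
    "score_gene_set",
    "composite_zscore",
    "conserved_state_markers",
    "mixing_entropy",
]


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x)


@dataclass
class GeneSetScoreResult:
    retained_genes: list[str]
    per_cell_score: pd.Series
    min_correlation: float


@dataclass
class MarkerSet:
    state: str
    genes: list[str]
    stats: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def normalize_counts(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """log(1 + scale * count / cell_total) per cell; returns a copy.

    Cells with zero total counts are an error (named in the message);
    all-zero genes stay exactly zero.
    """
    totals = np.ravel(adata.X.sum(axis=1))
    if np.any(totals == 0):
        bad = adata.obs_names[np.where(totals == 0)[0]].tolist()
        raise ValueError(f"cells with zero total counts: {bad[:5]}")
    out = adata.copy()
    if sparse.issparse(out.X):
        x = out.X.tocsr().astype(float)
        inv = scale / totals
        x = sparse.diags(inv) @ x
        x.data = np.log1p(x.data)
        out.X = x
    else:
        out.X = np.log1p(np.asarray(out.X, float) * (scale / totals)[:, None])
    return out


def filter_gene_set(adata: ad.AnnData, genes: list[str],
                    min_corr: float = 0.1) -> list[str]:
    """Keep genes whose Pearson correlation with the averaged whole-set
    profile (mean normalized expression over the FULL input set) is at
    least ``min_corr``. Constant genes are dropped (undefined correlation).

    The reference profile is always the full input set: the operation is a
    single pass and re-filtering the retained set against the original
    reference changes nothing.
    """
    present = [g for g in genes if g in adata.var_names]
    if len(present) < 2:
        raise ValueError(f"need >=2 genes present in matrix, got {len(present)}")
    x = _dense(adata[:, present].X)                   # cells x genes
    mean_profile = x.mean(axis=1)
    xm = x - x.mean(axis=0)
    pm = mean_profile - mean_profile.mean()
    denom = np.sqrt((xm ** 2).sum(axis=0) * (pm ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xm * pm[:, None]).sum(axis=0) / denom
    keep = np.isfinite(r) & (r >= min_corr)
    retained = [g for g, k in zip(present, keep) if k]
    if not retained:
        warnings.warn("correlation filter removed every gene in the set")
    return retained


def score_cells(adata: ad.AnnData, retained_genes: list[str]) -> pd.Series:
    """Per-cell score: mean normalized expression over the retained genes."""
    if not retained_genes:
        raise ValueError("empty gene set")
    x = _dense(adata[:, retained_genes].X)
    return pd.Series(x.mean(axis=1), index=adata.obs_names, name="score")


def score_gene_set(adata: ad.AnnData, genes: list[str],
                   min_corr: float = 0.1) -> GeneSetScoreResult:
    """Correlation-filter a gene set, then score every cell with it."""
    retained = filter_gene_set(adata, genes, min_corr=min_corr)
    score = (score_cells(adata, retained) if retained
             else pd.Series(np.nan, index=adata.obs_names, name="score"))
    return GeneSetScoreResult(retained, score, min_corr)


def composite_zscore(bulk: pd.DataFrame, genes: list[str]) -> pd.Series:
    """Bulk composite score: per-gene Z across samples, then the per-sample
    mean Z over the gene set. ``bulk`` is samples x genes. Zero-variance
    genes are dropped with a warning."""
    if bulk.shape[0] < 2:
        raise ValueError("need >=2 samples to compute Z scores")
    present = [g for g in genes if g in bulk.columns]
    if not present:
        raise ValueError("no gene of the set present in the bulk matrix")
    sub = bulk[present].astype(float)
    sd = sub.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping zero-variance genes: {constant[:5]}")
        sub = sub.drop(columns=constant)
        if sub.shape[1] == 0:
            raise ValueError("all genes in the set have zero variance")
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
    return z.mean(axis=1).rename("composite_z")


def conserved_state_markers(
    adata: ad.AnnData,
    state: str,
    reference_state: str = "reference",
    state_key: str = "state",
    group_key: str = "subclass",
    condition_key: str = "condition",
    min_groups: int = 4,
    p_max: float = 0.05,
    min_cells: int = 3,
    max_cells_per_ident: int | None = None,
    trim_vs_rest: bool = False,
    lfc_min: float = 0.6,
    seed: int = 0,
) -> MarkerSet:
    """Conserved markers of an altered state.

    Within every (condition x cell grouping) stratum, state cells are
    compared to reference cells with a two-sided Wilcoxon rank-sum test on
    normalized expression. A grouping *supports* a gene when the gene is
    enriched (p < ``p_max``, higher mean in the state) in that grouping in
    every condition; a gene is a conserved marker when at least
    ``min_groups`` groupings support it. Strata with fewer than
    ``min_cells`` cells on either side are skipped and reported in the
    provenance; a condition with no valid stratum at all makes the
    requirement unsatisfiable and yields an empty set.

    With ``trim_vs_rest``, the set is additionally trimmed to genes
    enriched in state cells versus all other cells with p < ``p_max`` and
    average log2 fold change > ``lfc_min`` (Seurat-style log2 ratio of
    mean expm1 normalized expression, pseudocount 1).

    ``max_cells_per_ident`` optionally down-samples each side of each
    stratum before testing (deterministic given ``seed``).
    """
    obs = adata.obs
    conditions = list(pd.unique(obs[condition_key]))
    groups = list(pd.unique(obs[group_key]))
    genes = list(adata.var_names)
    x = _dense(adata.X)
    rng = np.random.default_rng(seed)

    skipped: list[tuple[str, str]] = []
    # support[g_idx, gene] accumulated per grouping
    qualified = {}  # (condition, group) -> boolean vector over genes
    for cond in conditions:
        for grp in groups:
            stratum = (obs[condition_key] == cond) & (obs[group_key] == grp)
            s_idx = np.where(stratum & (obs[state_key] == state))[0]
            r_idx = np.where(stratum & (obs[state_key] == reference_state))[0]
            if len(s_idx) < min_cells or len(r_idx) < min_cells:
                skipped.append((str(cond), str(grp)))
                continue
            if max_cells_per_ident is not None:
                if len(s_idx) > max_cells_per_ident:
                    s_idx = rng.choice(s_idx, max_cells_per_ident, replace=False)
                if len(r_idx) > max_cells_per_ident:
                    r_idx = rng.choice(r_idx, max_cells_per_ident, replace=False)
            xs, xr = x[s_idx], x[r_idx]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # ties/constant columns
                res = mannwhitneyu(xs, xr, axis=0, alternative="two-sided")
            up = xs.mean(axis=0) > xr.mean(axis=0)
            qualified[(cond, grp)] = (res.pvalue < p_max) & up

    valid_conditions = {c for (c, _g) in qualified}
    provenance = {
        "rule": f"p<{p_max} in every condition, >= {min_groups} groupings",
        "skipped_strata": skipped,
        "conditions": [str(c) for c in conditions],
        "groups": [str(g) for g in groups],
    }
    if set(conditions) - valid_conditions:
        provenance["unsatisfiable_conditions"] = sorted(
            str(c) for c in set(conditions) - valid_conditions)
        return MarkerSet(state, [], pd.DataFrame(index=genes), provenance)

    n_support = np.zeros(len(genes), dtype=int)
    for grp in groups:
        ok = None
        complete = True
        for cond in conditions:
            q = qualified.get((cond, grp))
            if q is None:
                complete = False
                break
            ok = q if ok is None else (ok & q)
        if complete and ok is not None:
            n_support += ok.astype(int)
    keep = n_support >= min_groups
    stats = pd.DataFrame({"n_supporting_groups": n_support}, index=genes)

    if trim_vs_rest:
        s_mask = (obs[state_key] == state).to_numpy()
        xs, xr = x[s_mask], x[~s_mask]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mannwhitneyu(xs, xr, axis=0, alternative="two-sided")
        lfc = np.log2((np.expm1(xs).mean(axis=0) + 1)
                      / (np.expm1(xr).mean(axis=0) + 1))
        stats["p_vs_rest"] = res.pvalue
        stats["avg_log2FC_vs_rest"] = lfc
        keep = keep & (res.pvalue < p_max) & (lfc > lfc_min)
        provenance["trim"] = f"vs rest: p<{p_max} and avg log2FC>{lfc_min}"

    markers = [g for g, k in zip(genes, keep) if k]
    return MarkerSet(state, markers, stats.loc[stats.index.isin(markers) |
                                               (stats["n_supporting_groups"] > 0)],
                     provenance)


def mixing_entropy(subclass: pd.Series, batch: pd.Series,
                   covered_only: bool = False) -> float:
    """Normalized relative batch-mixing entropy weighted by subclass size.

    Per subclass, Shannon entropy (natural log) of its batch composition,
    divided by log of the overall number of batches; the returned value is
    the subclass-size-weighted mean, in [0, 1]. With ``covered_only`` only
    subclasses covered by more than one batch enter the average.
    """
    subclass = pd.Series(subclass).astype(str)
    batch = pd.Series(batch).astype(str)
    if len(subclass) != len(batch):
        raise ValueError("subclass and batch must align")
    n_batches = batch.nunique()
    if n_batches < 2:
        raise ValueError("mixing entropy undefined with a single batch")
    log_nb = np.log(n_batches)

    num = 0.0
    den = 0.0
    for _sub, idx in subclass.groupby(subclass).groups.items():
        b = batch.loc[idx]
        if covered_only and b.nunique() < 2:
            continue
        p = b.value_counts(normalize=True).to_numpy()
        h = -(p * np.log(p)).sum() / log_nb
        num += h * len(b)
        den += len(b)
    if den == 0:
        raise ValueError("no subclass covered by more than one batch")
    return float(num / den)
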