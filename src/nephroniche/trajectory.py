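"""Pseudotime association testing, smoothing, and co-expression modules.

Pseudotime is an input. Per gene, expression is modelled as a cubic-spline
function of pseudotime and compared to an intercept-only reduced model
with an F-test (BH-adjusted across genes). The smoothed expression matrix
(centered rolling mean over pseudotime-ordered cells) feeds weighted
co-expression module detection: signed adjacency ((1+r)/2)^softPower,
topological-overlap dissimilarity, average-linkage tree, static height
cut with a minimum module size, and eigengene-correlation merging.
Cells are assigned to modules via PCA + Louvain clustering and
best-correlated module activity; module labels transfer across datasets
by k-nearest-neighbor majority vote on a joint embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.interpolate import BSpline
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from ._graph import knn_louvain

__all__ = [
    "GamFitResult",
    "ModuleDetection",
    "spline_basis",
    "gam_association",
    "smooth_expression",
    "detect_modules",
    "assign_cells_to_modules",
    "transfer_modules",
    "loo_auc_screen",
]

GREY = "grey"
UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# GAM-style association
# ---------------------------------------------------------------------------

def spline_basis(t: np.ndarray, df: int = 5) -> np.ndarray:
    """Regression basis for pseudotime (without the intercept column).

    df = 1 gives the linear basis [t] (so the F-test reduces exactly to the
    simple linear-regression F); df = 2 a quadratic polynomial; df >= 3 a
    cubic B-spline basis with df columns and interior knots at quantiles
    of t.
    """
    t = np.asarray(t, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    if df == 1:
        return t[:, None]
    if df == 2:
        return np.column_stack([t, t ** 2])
    n_interior = df - 3
    lo, hi = t.min(), t.max()
    if hi <= lo:
        raise ValueError("pseudotime must be non-constant")
    interior = (np.quantile(t, np.linspace(0, 1, n_interior + 2)[1:-1])
                if n_interior > 0 else np.array([]))
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
    design = BSpline.design_matrix(t, knots, 3, extrapolate=True).toarray()
    # the cubic B-spline columns sum to 1; drop one to keep the intercept
    return design[:, 1:]


@dataclass
class GamFitResult:
    table: pd.DataFrame          # per gene: rss_full, rss_reduced, F, p, q
    spline_df: int


def gam_association(expr: pd.DataFrame, t: pd.Series | np.ndarray,
                    spline_df: int = 5) -> GamFitResult:
    """Per-gene F-test of a cubic-spline pseudotime model vs intercept only.

    ``expr`` is genes x cells; ``t`` aligns with the cells. Constant genes
    are recorded with F = 0, p = 1. q is BH across genes.
    """
    t = np.asarray(t, dtype=float)
    n = expr.shape[1]
    if len(t) != n:
        raise ValueError("pseudotime does not align with cells")
    if n < spline_df + 2:
        raise ValueError("need at least spline_df + 2 cells")
    basis = spline_basis(t, df=spline_df)
    X = np.column_stack([np.ones(n), basis])
    k1 = X.shape[1]

    Y = expr.to_numpy(dtype=float).T            # cells x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss_full = (resid ** 2).sum(axis=0)
    rss_reduced = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)

    dfn = k1 - 1
    dfd = n - k1
    with np.errstate(invalid="ignore", divide="ignore"):
        F = ((rss_reduced - rss_full) / dfn) / (rss_full / dfd)
    constant = rss_reduced <= 1e-300
    F = np.where(constant, 0.0, np.maximum(F, 0.0))
    p = np.where(constant, 1.0, stats.f.sf(F, dfn, dfd))
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({
        "rss_full": rss_full, "df_full": dfd,
        "rss_reduced": rss_reduced, "df_reduced": n - 1,
        "F": F, "p": p, "q": q,
    }, index=expr.index)
    return GamFitResult(table=table, spline_df=spline_df)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def smooth_expression(expr: pd.DataFrame, t: pd.Series | np.ndarray,
                      window_frac: float = 0.05
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Centered rolling mean over pseudotime-ordered cells.

    Returns (smoothed genes x cells with columns in pseudotime order,
    sorted pseudotime). Window = max(5, ceil(window_frac * n)) cells,
    clamped to n with a warning.
    """
    t = pd.Series(np.asarray(t, dtype=float), index=expr.columns)
    order = t.sort_values(kind="stable").index
    n = len(order)
    w = max(5, int(np.ceil(window_frac * n)))
    if w > n:
        warnings.warn(f"window {w} exceeds {n} cells; clamping")
        w = n
    smoothed = (expr[order].T
                .rolling(w, center=True, min_periods=1).mean()
                .T)
    return smoothed, t.loc[order]


# ---------------------------------------------------------------------------
# module detection (weighted co-expression network style)
# ---------------------------------------------------------------------------

def _tom_dissimilarity(adj: np.ndarray) -> np.ndarray:
    """Topological-overlap dissimilarity of a symmetric adjacency (diag 0)."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    L = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    return 1.0 - tom


def _eigengene(profiles: np.ndarray) -> np.ndarray:
    """First principal component of standardized gene profiles (genes x
    cells), sign-oriented to correlate positively with the mean profile."""
    z = (profiles - profiles.mean(axis=1, keepdims=True))
    sd = profiles.std(axis=1, keepdims=True)
    z = z / np.where(sd > 0, sd, 1.0)
    _u, _s, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    if np.corrcoef(e, z.mean(axis=0))[0, 1] < 0:
        e = -e
    return e


@dataclass
class ModuleDetection:
    gene_modules: pd.Series          # module name per gene ("grey" = none)
    eigengenes: pd.DataFrame         # cells x modules
    merge_log: list = field(default_factory=list)


def detect_modules(smoothed: pd.DataFrame, soft_power: int = 10,
                   min_module_size: int = 20, merge_height: float = 0.25,
                   cut_height: float = 0.9,
                   min_kme: float = 0.6) -> ModuleDetection:
    """Co-expression modules from the smoothed genes x cells matrix.

    Signed adjacency ((1 + r) / 2) ** soft_power over gene profiles,
    topological-overlap dissimilarity, average-linkage hierarchical tree
    cut at ``cut_height`` (fraction of the tallest merge); clusters
    smaller than ``min_module_size`` are greyed out, and genes whose
    module-membership correlation with their module's eigengene (kME)
    falls below ``min_kme`` are greyed out as well. Modules whose
    eigengene correlation exceeds 1 - ``merge_height`` are merged
    (logged). Constant genes are grey.
    """
    genes = smoothed.index
    if len(genes) < min_module_size:
        raise ValueError("too few genes for the requested minimum module size")
    x = smoothed.to_numpy(dtype=float)
    sd = x.std(axis=1)
    informative = sd > 0
    xi = x[informative]
    if informative.sum() < 2:
        raise ValueError("fewer than 2 non-constant genes")

    r = np.corrcoef(xi)
    adj = ((1.0 + r) / 2.0) ** soft_power
    diss = _tom_dissimilarity(adj)
    diss = (diss + diss.T) / 2.0
    np.fill_diagonal(diss, 0.0)
    Z = average(squareform(diss, checks=False))
    raw = fcluster(Z, t=cut_height * Z[:, 2].max(), criterion="distance")

    labels = np.full(len(genes), GREY, dtype=object)
    info_idx = np.where(informative)[0]
    sizes = pd.Series(raw).value_counts()
    keep_clusters = sizes[sizes >= min_module_size].index
    # name modules by decreasing size
    name_of = {c: f"M{i + 1}" for i, c in enumerate(keep_clusters)}
    for c in keep_clusters:
        labels[info_idx[raw == c]] = name_of[c]

    # eigengene-correlation merge
    merge_log: list[tuple[str, str, float]] = []
    while True:
        mods = [m for m in pd.unique(labels) if m != GREY]
        if len(mods) < 2:
            break
        eig = {m: _eigengene(x[labels == m]) for m in mods}
        best = None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                c = float(np.corrcoef(eig[mods[i]], eig[mods[j]])[0, 1])
                if c > 1.0 - merge_height and (best is None or c > best[2]):
                    best = (mods[i], mods[j], c)
        if best is None:
            break
        a, b, c = best
        labels[labels == b] = a
        merge_log.append((b, a, c))

    # module-membership (kME) filter: grey out weakly connected genes
    z_all = (x - x.mean(axis=1, keepdims=True)) / np.where(
        sd[:, None] > 0, sd[:, None], 1.0)
    for m in [m for m in pd.unique(labels) if m != GREY]:
        mask = labels == m
        e = _eigengene(x[mask])
        kme = z_all[mask] @ ((e - e.mean()) / (e.std() or 1.0)) / x.shape[1]
        weak = np.where(mask)[0][kme < min_kme]
        labels[weak] = GREY
        if mask.sum() - len(weak) < min_module_size:
            labels[mask] = GREY

    # stable final names ordered by size
    mods = [m for m in pd.unique(labels) if m != GREY]
    mods = sorted(mods, key=lambda m: -int((labels == m).sum()))
    rename = {m: f"M{i + 1}" for i, m in enumerate(mods)}
    labels = np.array([rename.get(m, GREY) for m in labels], dtype=object)

    eig_df = pd.DataFrame(
        {rename[m]: _eigengene(x[labels == rename[m]]) for m in mods},
        index=smoothed.columns)
    return ModuleDetection(
        gene_modules=pd.Series(labels, index=genes, name="module"),
        eigengenes=eig_df,
        merge_log=merge_log,
    )


# ---------------------------------------------------------------------------
# cell assignment and transfer
# ---------------------------------------------------------------------------

def assign_cells_to_modules(smoothed: pd.DataFrame, gene_modules: pd.Series,
                            n_pcs: int = 10, k: int = 15,
                            seed: int = 0) -> pd.Series:
    """Assign every cell to the module best matching its cluster's profile.

    Cells are clustered by PCA + Louvain on the (z-scored) smoothed matrix;
    each cluster is linked to the module whose mean standardized activity
    is highest in that cluster; clusters with no positively-active module
    are unassigned. Cells inherit their cluster's module.
    """
    mods = [m for m in pd.unique(gene_modules) if m != GREY]
    if not mods:
        raise ValueError("no modules to assign")
    x = smoothed.to_numpy(dtype=float)
    sd = x.std(axis=1, keepdims=True)
    z = (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)

    cells_x = z.T                                   # cells x genes
    n_pcs = min(n_pcs, min(cells_x.shape) - 1)
    pcs = PCA(n_components=n_pcs, svd_solver="full",
              random_state=seed).fit_transform(cells_x)
    clusters = knn_louvain(pcs, k=k, seed=seed)

    activity = np.column_stack([
        z[(gene_modules == m).to_numpy()].mean(axis=0) for m in mods])
    out = np.empty(len(smoothed.columns), dtype=object)
    for c in np.unique(clusters):
        mask = clusters == c
        mean_act = activity[mask].mean(axis=0)
        # a cluster below the population mean of EVERY module is unassigned;
        # with a single module there is no alternative and it takes the module
        if mean_act.max() <= 0 and len(mods) > 1:
            out[mask] = UNASSIGNED
        else:
            out[mask] = mods[int(mean_act.argmax())]
    return pd.Series(out, index=smoothed.columns, name="module")


def transfer_modules(ref_embedding: np.ndarray | pd.DataFrame,
                     ref_labels: pd.Series | np.ndarray,
                     query_embedding: np.ndarray | pd.DataFrame,
                     k: int = 30) -> np.ndarray:
    """k-nearest-neighbor majority-vote label transfer on a joint embedding.

    Ties between labels fall back to the single nearest neighbor's label;
    k is clamped to the reference size with a warning.
    """
    ref = np.asarray(ref_embedding, dtype=float)
    qry = np.asarray(query_embedding, dtype=float)
    if ref.shape[1] != qry.shape[1]:
        raise ValueError("embeddings must share dimensionality")
    labels = np.asarray(ref_labels, dtype=object)
    if k > len(ref):
        warnings.warn(f"k={k} exceeds reference size {len(ref)}; clamping")
        k = len(ref)
    nn = NearestNeighbors(n_neighbors=k).fit(ref)
    _, idx = nn.kneighbors(qry)
    out = np.empty(len(qry), dtype=object)
    for i, row in enumerate(idx):
        votes = pd.Series(labels[row]).value_counts()
        top = votes[votes == votes.iloc[0]]
        out[i] = labels[row[0]] if len(top) > 1 else top.index[0]
    return out


# ---------------------------------------------------------------------------
# condition screen utility
# ---------------------------------------------------------------------------

def loo_auc_screen(pseudobulk: pd.DataFrame, labels: pd.Series,
                   auc_min: float = 0.65) -> pd.DataFrame:
    """Leave-one-out logistic-regression AUC per gene on sample pseudobulk.

    ``pseudobulk`` is samples x genes (per-sample mean normalized
    expression); ``labels`` a binary condition per sample. Returns per-gene
    AUC and whether it clears ``auc_min``.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score

    y = pd.factorize(pd.Series(labels).loc[pseudobulk.index])[0]
    if len(np.unique(y)) != 2:
        raise ValueError("labels must be binary")
    n = len(y)
    aucs = {}
    for g in pseudobulk.columns:
        xg = pseudobulk[[g]].to_numpy(dtype=float)
        scores = np.empty(n)
        for i in range(n):
            mask = np.arange(n) != i
            if len(np.unique(y[mask])) < 2:
                scores[i] = 0.5
                continue
            clf = LogisticRegression().fit(xg[mask], y[mask])
            scores[i] = clf.predict_proba(xg[[i]])[0, 1]
        aucs[g] = roc_auc_score(y, scores)
    out = pd.DataFrame({"auc": pd.Series(aucs)})
    out["pass"] = out["auc"] > auc_min
    return out
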