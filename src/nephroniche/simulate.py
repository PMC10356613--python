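"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one data modality of the kidney injury-niche
workflow — multi-condition expression with planted altered-state marker
sets, Slide-seq-like bead fields with adjacency preferences, Visium-like
spot weight tables, 3D cell tables with planted niche communities, peak
count matrices with depth confounding and planted differentially
accessible peaks, and pseudotime trajectories with planted gene modules.
The planted truth is returned alongside the data so downstream stages can
be tested without any external download.

All generators are deterministic given (seed, config): each draws from its
own named RNG stream derived from the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import anndata as ad
from scipy import sparse
from scipy.spatial import cKDTree

from ._rng import stream_rng

__all__ = [
    "ExpressionConfig",
    "BeadConfig",
    "SpotConfig",
    "Cells3DConfig",
    "PeakConfig",
    "TrajectoryConfig",
    "ExpressionTruth",
    "BeadTruth",
    "SpotTruth",
    "Cells3DTruth",
    "PeakTruth",
    "TrajectoryTruth",
    "simulate_expression",
    "simulate_beads",
    "simulate_spots",
    "simulate_cells3d",
    "simulate_peaks",
    "simulate_trajectory",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionConfig:
    """Multi-condition snRNA-seq-like counts with planted state signatures.

    ``fold_change`` is the mean up-regulation of a state's planted marker
    genes in cells of that state (all conditions, all subclasses unless the
    marker is planted as partial). ``dispersion`` is the negative-binomial
    dispersion alpha (var = mu + alpha * mu^2).
    """

    seed: int = 0
    subclasses: tuple[str, ...] = ("PT", "TAL", "DCT")
    states: tuple[str, ...] = ("reference", "adaptive", "degenerative")
    conditions: tuple[str, ...] = ("reference", "AKI", "CKD")
    n_batches: int = 2
    cells_per_group: int = 60          # per (subclass, state, condition)
    n_genes: int = 1000
    markers_per_state: int = 30
    fold_change: float = 4.0
    dispersion: float = 0.5
    mean_library_size: float = 2500.0
    # optional partial markers: up-regulated only in these subclasses
    partial_marker_subclasses: tuple[str, ...] = ()
    n_partial_markers: int = 0

    def __post_init__(self):
        _require(len(self.subclasses) >= 2, "need >=2 subclasses")
        _require(len(self.states) >= 2, "need >=2 states")
        _require(len(self.conditions) >= 2, "need >=2 conditions")
        _require(self.fold_change > 0, "fold change must be > 0")
        _require(self.dispersion > 0, "dispersion must be > 0")
        for n in (self.n_batches, self.cells_per_group, self.n_genes,
                  self.markers_per_state):
            _require(n > 0, "all counts must be > 0")
        _require("reference" in self.states, "states must include 'reference'")


@dataclass
class ExpressionTruth:
    marker_sets: dict[str, list[str]]            # state -> planted marker genes
    partial_markers: list[str]
    partial_marker_subclasses: list[str]
    fold_change: float


def simulate_expression(config: ExpressionConfig) -> tuple[ad.AnnData, ExpressionTruth]:
    """Negative-binomial counts (cells x genes AnnData) with planted markers.

    Marker genes of an altered state are up-regulated by ``fold_change`` in
    cells of that state across every condition. Metadata columns
    ``subclass``, ``state``, ``condition``, ``batch`` are populated.
    """
    cfg = config
    rng = stream_rng(cfg.seed, "expression")
    altered = [s for s in cfg.states if s != "reference"]
    n_marker_genes = cfg.markers_per_state * len(altered) + cfg.n_partial_markers
    _require(cfg.n_genes >= n_marker_genes + 10,
             "n_genes too small for requested marker sets")

    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    marker_sets: dict[str, list[str]] = {}
    pos = 0
    for s in altered:
        marker_sets[s] = genes[pos:pos + cfg.markers_per_state]
        pos += cfg.markers_per_state
    partial = genes[pos:pos + cfg.n_partial_markers]
    pos += cfg.n_partial_markers

    # cell sheet
    rows = []
    for sub in cfg.subclasses:
        for st in cfg.states:
            for cond in cfg.conditions:
                rows += [(sub, st, cond)] * cfg.cells_per_group
    obs = pd.DataFrame(rows, columns=["subclass", "state", "condition"])
    n_cells = len(obs)
    obs.index = [f"C{i:06d}" for i in range(n_cells)]
    obs["batch"] = [f"B{b}" for b in rng.integers(0, cfg.n_batches, n_cells)]

    # baseline gene abundance profile (shared across subclasses; subclass
    # identity genes are not needed for any downstream contract)
    base = rng.lognormal(0.0, 1.0, cfg.n_genes)
    lib = rng.lognormal(math.log(cfg.mean_library_size), 0.3, n_cells)

    gene_idx = {g: i for i, g in enumerate(genes)}
    fold = np.ones((n_cells, cfg.n_genes))
    for s in altered:
        mask = (obs["state"] == s).to_numpy()
        cols = [gene_idx[g] for g in marker_sets[s]]
        fold[np.ix_(mask, cols)] = cfg.fold_change
    if partial:
        # partial markers: up in ALL altered states but only chosen subclasses
        mask = (obs["state"] != "reference").to_numpy() & obs["subclass"].isin(
            cfg.partial_marker_subclasses).to_numpy()
        cols = [gene_idx[g] for g in partial]
        fold[np.ix_(mask, cols)] = cfg.fold_change

    prob = base[None, :] * fold
    prob /= prob.sum(axis=1, keepdims=True)
    mu = prob * lib[:, None]
    shape = 1.0 / cfg.dispersion
    lam = rng.gamma(shape, mu * cfg.dispersion)
    counts = rng.poisson(lam).astype(np.int32)

    adata = ad.AnnData(
        X=sparse.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    truth = ExpressionTruth(
        marker_sets=marker_sets,
        partial_markers=list(partial),
        partial_marker_subclasses=list(cfg.partial_marker_subclasses),
        fold_change=cfg.fold_change,
    )
    return adata, truth


# ---------------------------------------------------------------------------
# beads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadConfig:
    """2D bead field with Potts-like sequential label assignment.

    ``preference[a][b]`` multiplies the odds of label *a* once per
    already-labelled neighbor of class *b* within ``radius`` µm; ratio 1
    everywhere gives an exchangeable (i.i.d.) label field.
    """

    seed: int = 0
    width: float = 1000.0
    height: float = 1000.0
    density: float = 0.0005           # beads per µm^2 (~500 beads by default)
    classes: tuple[str, ...] = ("A", "B", "C")
    base_freqs: tuple[float, ...] | None = None
    preference: tuple[tuple[float, ...], ...] | None = None   # classes x classes
    radius: float = 50.0

    def __post_init__(self):
        _require(len(self.classes) >= 2, "need >=2 classes")
        _require(self.density > 0 and self.width > 0 and self.height > 0,
                 "geometry must be positive")
        if self.preference is not None:
            p = np.asarray(self.preference, float)
            _require(p.shape == (len(self.classes),) * 2,
                     "preference must be classes x classes")
            _require(np.all(p > 0), "preference ratios must be > 0")
        if self.base_freqs is not None:
            f = np.asarray(self.base_freqs, float)
            _require(len(f) == len(self.classes) and np.all(f > 0),
                     "base_freqs must be positive, one per class")

    def preference_matrix(self) -> np.ndarray:
        if self.preference is None:
            return np.ones((len(self.classes),) * 2)
        return np.asarray(self.preference, float)


@dataclass
class BeadTruth:
    classes: list[str]
    base_freqs: list[float]
    preference: list[list[float]]
    radius: float


def simulate_beads(config: BeadConfig) -> tuple[pd.DataFrame, BeadTruth]:
    """Bead table (bead_id, x_um, y_um, label) with planted adjacency bias.

    Beads are placed uniformly; labels are drawn sequentially in random
    order with probability proportional to base frequency times the product
    of preference ratios over already-labelled neighbors within 50 µm.
    """
    cfg = config
    rng = stream_rng(cfg.seed, "beads")
    n = int(rng.poisson(cfg.density * cfg.width * cfg.height))
    _require(n >= 3, "field too sparse: fewer than 3 beads drawn")
    xy = rng.uniform(0, [cfg.width, cfg.height], size=(n, 2))

    k = len(cfg.classes)
    freqs = (np.full(k, 1.0 / k) if cfg.base_freqs is None
             else np.asarray(cfg.base_freqs, float) / np.sum(cfg.base_freqs))
    logpref = np.log(cfg.preference_matrix())

    tree = cKDTree(xy)
    neighbors = tree.query_ball_point(xy, r=cfg.radius)
    labels = np.full(n, -1, dtype=int)
    order = rng.permutation(n)
    logfreq = np.log(freqs)
    for i in order:
        counts = np.zeros(k)
        for j in neighbors[i]:
            if j != i and labels[j] >= 0:
                counts[labels[j]] += 1
        logw = logfreq + logpref @ counts
        w = np.exp(logw - logw.max())
        labels[i] = rng.choice(k, p=w / w.sum())

    df = pd.DataFrame({
        "bead_id": [f"bead{i:05d}" for i in range(n)],
        "x_um": xy[:, 0],
        "y_um": xy[:, 1],
        "label": [cfg.classes[c] for c in labels],
    })
    truth = BeadTruth(
        classes=list(cfg.classes),
        base_freqs=freqs.tolist(),
        preference=cfg.preference_matrix().tolist(),
        radius=cfg.radius,
    )
    return df, truth


# ---------------------------------------------------------------------------
# spots
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpotComponent:
    """One latent spot archetype: a Dirichlet alpha plus per-condition odds."""

    name: str
    alpha: tuple[float, ...]
    weight_by_condition: tuple[float, ...]   # relative odds, one per condition


@dataclass(frozen=True)
class SpotConfig:
    """Visium-like spot weight tables as Dirichlet mixtures of archetypes."""

    seed: int = 0
    n_spots: int = 1500
    subclasses: tuple[str, ...] = ("PT", "TAL", "aPT", "aTAL", "dPT", "dTAL",
                                   "IMM", "STR")
    conditions: tuple[str, ...] = ("reference", "AKI", "CKD")
    samples_per_condition: int = 2
    components: tuple[SpotComponent, ...] = ()
    state_map: tuple[tuple[str, str], ...] = (
        ("PT", "healthy"), ("TAL", "healthy"),
        ("aPT", "adaptive"), ("aTAL", "adaptive"),
        ("dPT", "degenerative"), ("dTAL", "degenerative"),
        ("IMM", "immune"), ("STR", "stromal"),
    )
    l1_map: tuple[tuple[str, str], ...] = ()   # subclass -> level-1 group

    def __post_init__(self):
        _require(self.n_spots > 0 and self.samples_per_condition > 0,
                 "counts must be > 0")
        for comp in self.components:
            _require(len(comp.alpha) == len(self.subclasses),
                     f"component {comp.name}: alpha length mismatch")
            _require(all(a > 0 for a in comp.alpha),
                     f"component {comp.name}: alphas must be > 0")
            _require(len(comp.weight_by_condition) == len(self.conditions),
                     f"component {comp.name}: needs one odds per condition")

    # -- presets ----------------------------------------------------------
    @classmethod
    def default(cls, seed: int = 0, n_spots: int = 1500,
                injury_odds: tuple[float, float, float] = (0.18, 1.2, 0.8),
                ) -> "SpotConfig":
        """Healthy/injury mixture with planted immune-adaptive co-occurrence.

        Injury spots carry elevated adaptive-epithelial AND immune/stromal
        weight, so immune presence co-occurs with adaptive-dominant spots;
        injury spots are more frequent in AKI/CKD than reference.
        """
        healthy = SpotComponent(
            "healthy", alpha=(8, 8, 1, 1, 1, 1, 1.5, 1.5),
            weight_by_condition=(1.0, 1.0, 1.0))
        injury = SpotComponent(
            "injury", alpha=(1.5, 1.5, 6, 6, 2, 2, 6, 4),
            weight_by_condition=injury_odds)
        return cls(seed=seed, n_spots=n_spots, components=(healthy, injury))

    @classmethod
    def null(cls, seed: int = 0, n_spots: int = 1500) -> "SpotConfig":
        """Single symmetric Dirichlet: no planted co-occurrence or condition
        effect; epithelial state categories are exchangeable."""
        flat = SpotComponent("null", alpha=(2,) * 8,
                             weight_by_condition=(1.0, 1.0, 1.0))
        return cls(seed=seed, n_spots=n_spots, components=(flat,))

    @classmethod
    def tal_niches(cls, seed: int = 0, n_spots: int = 1500) -> "SpotConfig":
        """Three planted TAL-niche archetypes plus a PT-dominant background."""
        subclasses = ("C-TAL", "M-TAL", "aTAL", "PT", "IMM", "STR")
        comps = (
            SpotComponent("tal_niche_1", (14, 1, 1, 1, 0.5, 5), (1, 1, 1)),
            SpotComponent("tal_niche_2", (1, 14, 1, 1, 5, 0.5), (1, 1, 1)),
            SpotComponent("tal_niche_3", (1.5, 1.5, 14, 1, 4, 4), (1, 1, 1)),
            SpotComponent("background", (0.5, 0.5, 0.5, 12, 2, 2), (2, 2, 2)),
        )
        return cls(
            seed=seed, n_spots=n_spots, subclasses=subclasses,
            components=comps,
            state_map=(("C-TAL", "healthy"), ("M-TAL", "healthy"),
                       ("aTAL", "adaptive"), ("PT", "healthy"),
                       ("IMM", "immune"), ("STR", "stromal")),
            l1_map=(("C-TAL", "TAL"), ("M-TAL", "TAL"), ("aTAL", "TAL"),
                    ("PT", "PT"), ("IMM", "IMM"), ("STR", "STR")),
        )


@dataclass
class SpotTruth:
    component: list[str]               # latent archetype per spot
    state_map: dict[str, str]
    l1_map: dict[str, str]
    components: list[str]


def simulate_spots(config: SpotConfig) -> tuple[pd.DataFrame, SpotTruth]:
    """Spot table: spot_id, x/y, sample, condition + one weight column per
    subclass (simplex per spot). Truth records each spot's latent archetype."""
    cfg = config
    _require(len(cfg.components) >= 1, "need at least one component")
    rng = stream_rng(cfg.seed, "spots")
    n = cfg.n_spots
    cond_idx = np.arange(n) % len(cfg.conditions)
    sample_idx = (np.arange(n) // len(cfg.conditions)) % cfg.samples_per_condition
    conditions = np.array(cfg.conditions)[cond_idx]
    samples = np.array([f"{c}_{s}" for c, s in zip(conditions, sample_idx)])

    odds = np.array([comp.weight_by_condition for comp in cfg.components], float)
    comp_ids = np.empty(n, dtype=int)
    for ci in range(len(cfg.conditions)):
        mask = cond_idx == ci
        p = odds[:, ci] / odds[:, ci].sum()
        comp_ids[mask] = rng.choice(len(cfg.components), size=mask.sum(), p=p)

    weights = np.empty((n, len(cfg.subclasses)))
    for k, comp in enumerate(cfg.components):
        mask = comp_ids == k
        if mask.any():
            weights[mask] = rng.dirichlet(comp.alpha, size=int(mask.sum()))

    df = pd.DataFrame(weights, columns=list(cfg.subclasses))
    df.insert(0, "spot_id", [f"spot{i:05d}" for i in range(n)])
    df.insert(1, "x_um", rng.uniform(0, 6500, n))
    df.insert(2, "y_um", rng.uniform(0, 6500, n))
    df.insert(3, "sample", samples)
    df.insert(4, "condition", conditions)
    df = df.set_index("spot_id")

    truth = SpotTruth(
        component=[cfg.components[k].name for k in comp_ids],
        state_map=dict(cfg.state_map),
        l1_map=dict(cfg.l1_map),
        components=[c.name for c in cfg.components],
    )
    return df, truth


# ---------------------------------------------------------------------------
# 3D cells
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cells3DConfig:
    """3D point cloud with planted ball-shaped niche communities.

    Cells inside a niche ball draw their class from that niche's frequency
    vector mixed with the background at the given ``contrast``; contrast 0
    removes the planted structure entirely.
    """

    seed: int = 0
    n_cells: int = 10000
    box: tuple[float, float, float] = (400.0, 400.0, 100.0)
    classes: tuple[str, ...] = ("PT", "TAL", "IMM", "STR", "ALT", "ND")
    background_freqs: tuple[float, ...] = (0.30, 0.30, 0.10, 0.10, 0.05, 0.15)
    n_niches: int = 3
    niche_radius: float = 130.0
    contrast: float = 0.92
    niche_freqs: tuple[tuple[float, ...], ...] = (
        (0.10, 0.05, 0.55, 0.05, 0.20, 0.05),   # immune-rich injury niche
        (0.05, 0.10, 0.05, 0.55, 0.20, 0.05),   # stroma-rich niche
        (0.45, 0.05, 0.10, 0.05, 0.30, 0.05),   # altered-epithelial niche
    )

    def __post_init__(self):
        _require(self.n_cells > 0, "n_cells must be > 0")
        _require(self.niche_radius > 0, "niche radius must be > 0")
        _require(0.0 <= self.contrast <= 1.0, "contrast in [0,1]")
        _require(self.n_niches <= len(self.niche_freqs),
                 "not enough niche frequency vectors")
        for f in (self.background_freqs, *self.niche_freqs):
            _require(len(f) == len(self.classes), "frequency length mismatch")


@dataclass
class Cells3DTruth:
    niche_id: list[int]                # 0 = background, 1..k = planted niches
    centers: list[list[float]]
    classes: list[str]


# deterministic niche center placement (fractions of the box footprint)
_CENTER_FRACTIONS = [(0.27, 0.27), (0.73, 0.27), (0.50, 0.76),
                     (0.73, 0.73), (0.27, 0.73)]


def simulate_cells3d(config: Cells3DConfig) -> tuple[pd.DataFrame, Cells3DTruth]:
    """3D cell table (cell_id, x/y/z_um, class, specimen) with planted niches."""
    cfg = config
    _require(cfg.n_niches <= len(_CENTER_FRACTIONS),
             "at most 5 planted niches supported")
    rng = stream_rng(cfg.seed, "cells3d")
    w, h, d = cfg.box
    xyz = rng.uniform(0, [w, h, d], size=(cfg.n_cells, 3))
    centers = np.array([[fx * w, fy * h, d / 2.0]
                        for fx, fy in _CENTER_FRACTIONS[:cfg.n_niches]])

    if cfg.n_niches:
        dist = np.linalg.norm(xyz[:, None, :] - centers[None, :, :], axis=2)
        nearest = np.argmin(dist, axis=1)
        inside = dist[np.arange(cfg.n_cells), nearest] <= cfg.niche_radius
        niche = np.where(inside, nearest + 1, 0)
    else:
        niche = np.zeros(cfg.n_cells, dtype=int)

    bg = np.asarray(cfg.background_freqs, float)
    bg = bg / bg.sum()
    labels = np.empty(cfg.n_cells, dtype=int)
    for nid in range(cfg.n_niches + 1):
        mask = niche == nid
        if not mask.any():
            continue
        if nid == 0:
            f = bg
        else:
            nf = np.asarray(cfg.niche_freqs[nid - 1], float)
            nf = nf / nf.sum()
            f = cfg.contrast * nf + (1 - cfg.contrast) * bg
        labels[mask] = rng.choice(len(cfg.classes), size=int(mask.sum()), p=f)

    df = pd.DataFrame({
        "cell_id": [f"cell{i:06d}" for i in range(cfg.n_cells)],
        "x_um": xyz[:, 0],
        "y_um": xyz[:, 1],
        "z_um": xyz[:, 2],
        "class": [cfg.classes[c] for c in labels],
        "specimen": "S1",
    })
    truth = Cells3DTruth(niche_id=niche.tolist(), centers=centers.tolist(),
                         classes=list(cfg.classes))
    return df, truth


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakConfig:
    """snATAC-like binary peak counts with depth confounding.

    Test cells draw a high per-cell depth factor; the remaining pool is a
    mixture of a low mode and the same high mode, so depth is confounded
    with group membership unless backgrounds are depth-matched. Planted
    differentially accessible peaks multiply their rate by ``dar_fold`` in
    test cells only.
    """

    seed: int = 0
    n_peaks: int = 5000
    n_cells: int = 2000
    n_test: int = 500
    n_dar: int = 200
    dar_fold: float = 6.0
    depth_log_offset: float = 0.8      # log-scale depth shift of the high mode
    depth_log_sd: float = 0.35
    high_frac_other: float = 0.5       # fraction of non-test cells in high mode
    base_rate: float = 0.04

    def __post_init__(self):
        _require(0 < self.n_test < self.n_cells, "0 < n_test < n_cells")
        _require(self.n_dar <= self.n_peaks, "n_dar <= n_peaks")
        _require(self.dar_fold > 0, "dar_fold must be > 0")
        _require(self.base_rate > 0, "base_rate must be > 0")


@dataclass
class PeakTruth:
    dar_peaks: list[int]               # row indices of planted DARs
    test_cells: list[str]
    depth_factor: list[float]


def simulate_peaks(config: PeakConfig) -> tuple[ad.AnnData, PeakTruth]:
    """Peaks x cells binary accessibility as AnnData (X: peaks in var axis?).

    Returns an AnnData with cells as obs and peaks as var (X is cells x
    peaks, sparse uint8), obs columns ``group`` ('test'/'other') and
    ``depth`` (column sum of the binarized matrix), and var columns
    ``chrom``/``start``/``end`` (0-based half-open).
    """
    cfg = config
    rng = stream_rng(cfg.seed, "peaks")
    test = np.zeros(cfg.n_cells, bool)
    test[:cfg.n_test] = True

    depth = np.empty(cfg.n_cells)
    depth[test] = rng.lognormal(cfg.depth_log_offset, cfg.depth_log_sd,
                                cfg.n_test)
    n_other = cfg.n_cells - cfg.n_test
    high = rng.random(n_other) < cfg.high_frac_other
    other_depth = np.where(
        high,
        rng.lognormal(cfg.depth_log_offset, cfg.depth_log_sd, n_other),
        rng.lognormal(0.0, cfg.depth_log_sd, n_other),
    )
    depth[~test] = other_depth

    q = rng.gamma(2.0, cfg.base_rate / 2.0, cfg.n_peaks)
    dar = rng.choice(cfg.n_peaks, size=cfg.n_dar, replace=False)
    fold = np.ones((cfg.n_cells, cfg.n_peaks))
    fold[np.ix_(test, dar)] = cfg.dar_fold

    p = 1.0 - np.exp(-q[None, :] * depth[:, None] * fold)
    x = (rng.random((cfg.n_cells, cfg.n_peaks)) < p).astype(np.uint8)

    obs = pd.DataFrame({
        "group": np.where(test, "test", "other"),
        "depth": x.sum(axis=1),
    }, index=[f"cell{i:05d}" for i in range(cfg.n_cells)])
    var = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(cfg.n_peaks) * 1000,
        "end": np.arange(cfg.n_peaks) * 1000 + 500,
    }, index=[f"peak{i:05d}" for i in range(cfg.n_peaks)])

    adata = ad.AnnData(X=sparse.csr_matrix(x), obs=obs, var=var)
    truth = PeakTruth(dar_peaks=sorted(int(i) for i in dar),
                      test_cells=list(obs.index[test]),
                      depth_factor=depth.tolist())
    return adata, truth


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def _profile_early(t):
    return 1.0 / (1.0 + np.exp((t - 0.35) / 0.07))


def _profile_transient(t):
    return np.exp(-((t - 0.5) / 0.10) ** 2)


def _profile_late(t):
    return 1.0 / (1.0 + np.exp(-(t - 0.65) / 0.07))


_PROFILES = {"early": _profile_early,
             "transient": _profile_transient,
             "late": _profile_late}


@dataclass(frozen=True)
class TrajectoryConfig:
    """Pseudotime expression with planted temporal gene modules.

    Module genes follow one of three smooth programs of pseudotime
    (declining sigmoid, transient bump, rising sigmoid) scaled by a
    per-gene amplitude; null genes are pure noise. A cell's true module is
    the program with the highest mean activity at its pseudotime.
    """

    seed: int = 0
    n_cells: int = 600
    genes_per_module: int = 30
    n_null_genes: int = 40
    modules: tuple[str, ...] = ("early", "transient", "late")
    noise_sd: float = 0.4
    amplitude: tuple[float, float] = (0.8, 1.25)

    def __post_init__(self):
        _require(self.n_cells > 0 and self.genes_per_module > 0,
                 "counts must be > 0")
        _require(self.noise_sd > 0, "noise sd must be > 0")
        for m in self.modules:
            _require(m in _PROFILES, f"unknown module profile {m!r}")


@dataclass
class TrajectoryTruth:
    gene_module: dict[str, str]        # gene -> module name or "null"
    cell_module: dict[str, str]        # cell -> dominant program at its t
    pseudotime: dict[str, float]


def simulate_trajectory(config: TrajectoryConfig
                        ) -> tuple[pd.DataFrame, pd.Series, TrajectoryTruth]:
    """Returns (expr genes x cells, pseudotime Series, truth).

    Expression is on a normalized (log-like, Gaussian-noise) scale, as the
    downstream association and module stages assume.
    """
    cfg = config
    rng = stream_rng(cfg.seed, "trajectory")
    t = np.sort(rng.uniform(0, 1, cfg.n_cells))
    cells = [f"C{i:05d}" for i in range(cfg.n_cells)]

    gene_rows = []
    names = []
    gene_module = {}
    for m in cfg.modules:
        prof = _PROFILES[m](t)
        for j in range(cfg.genes_per_module):
            g = f"{m}_{j:03d}"
            amp = rng.uniform(*cfg.amplitude)
            gene_rows.append(amp * prof + rng.normal(0, cfg.noise_sd, cfg.n_cells))
            names.append(g)
            gene_module[g] = m
    for j in range(cfg.n_null_genes):
        g = f"null_{j:03d}"
        gene_rows.append(rng.normal(0, cfg.noise_sd, cfg.n_cells))
        names.append(g)
        gene_module[g] = "null"

    expr = pd.DataFrame(np.array(gene_rows), index=names, columns=cells)
    pt = pd.Series(t, index=cells, name="pseudotime")

    activity = np.array([_PROFILES[m](t) for m in cfg.modules])
    cell_module = {c: cfg.modules[k] for c, k in zip(cells, activity.argmax(0))}
    truth = TrajectoryTruth(gene_module=gene_module, cell_module=cell_module,
                            pseudotime=dict(zip(cells, t.tolist())))
    return expr, pt, truth
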