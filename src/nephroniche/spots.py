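"""Visium-style spot analyses on deconvolution/label-transfer weights.

Per-spot cell-state proportions are the summed weights of the subclasses
mapped to each state; condition contrasts use Fisher's exact test on
state-dominant spot counts; epithelial spots are categorized
healthy/adaptive/degenerative by the highest epithelial state proportion;
stromal/immune colocalization uses a mean-exceedance presence rule and
odds ratios; and TAL niches are re-clustered from the weight vectors of
spots with more than 20% TAL signature.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from ._graph import knn_louvain

__all__ = [
    "ColocalizationResult",
    "NicheTable",
    "state_proportions",
    "compare_state_proportions",
    "assign_epithelial_state",
    "colocalization_odds",
    "find_tal_niches",
]

EPITHELIAL_STATES = ("healthy", "adaptive", "degenerative")


def _weight_columns(spots: pd.DataFrame, state_map: dict[str, str]) -> list[str]:
    cols = [c for c in spots.columns if c in state_map]
    unmapped = [c for c in spots.columns
                if c not in state_map
                and c not in ("x_um", "y_um", "sample", "condition", "spot_id")
                and pd.api.types.is_numeric_dtype(spots[c])]
    if unmapped:
        raise ValueError(f"subclass weight columns without a state mapping: "
                         f"{unmapped}")
    return cols


def state_proportions(spots: pd.DataFrame,
                      state_map: dict[str, str]) -> pd.DataFrame:
    """Per-spot state proportions: sum of the weights of the subclasses
    mapped to each state. Rows sum to 1 (the weights are a simplex)."""
    cols = _weight_columns(spots, state_map)
    if not cols:
        raise ValueError("no mapped subclass weight columns found")
    out = {}
    states = sorted(set(state_map[c] for c in cols))
    for s in states:
        members = [c for c in cols if state_map[c] == s]
        out[s] = spots[members].sum(axis=1)
    return pd.DataFrame(out, index=spots.index)


def _dominant_state(props: pd.DataFrame) -> pd.Series:
    """Argmax state per spot; ties and all-zero rows are unassigned (None)."""
    arr = props.to_numpy(dtype=float)
    top = arr.max(axis=1)
    tied = (arr == top[:, None]).sum(axis=1) > 1
    out = np.where(tied | (top == 0), None,
                   np.asarray(props.columns, object)[arr.argmax(axis=1)])
    return pd.Series(out, index=props.index, name="dominant_state")


def compare_state_proportions(spot_states: pd.DataFrame,
                              condition: pd.Series) -> pd.DataFrame:
    """Per state and condition pair, Fisher's exact test on the 2x2 table
    (spot dominated by the state or not) x (condition A vs B).

    Dominance: the state has the spot's maximum state proportion (ties
    excluded). Returns odds ratio, p, and the table counts per row.
    """
    condition = condition.loc[spot_states.index]
    conds = list(pd.unique(condition))
    if len(conds) < 2:
        raise ValueError("need at least 2 conditions")
    for c in conds:
        if (condition == c).sum() == 0:
            raise ValueError(f"empty condition {c!r}")
    dom = _dominant_state(spot_states)
    rows = []
    for state in spot_states.columns:
        is_dom = dom == state
        for ca, cb in itertools.combinations(conds, 2):
            ma, mb = condition == ca, condition == cb
            a = int((is_dom & ma).sum())
            b = int((~is_dom & ma).sum())
            c = int((is_dom & mb).sum())
            d = int((~is_dom & mb).sum())
            orr, p = fisher_exact([[a, b], [c, d]])
            rows.append({"state": state, "condition_a": ca, "condition_b": cb,
                         "dom_a": a, "nondom_a": b, "dom_b": c, "nondom_b": d,
                         "odds_ratio": orr, "p": p,
                         "direction": ca if (a / max(a + b, 1)) >
                         (c / max(c + d, 1)) else cb})
    return pd.DataFrame(rows)


def assign_epithelial_state(state_props: pd.DataFrame,
                            states: tuple[str, ...] = EPITHELIAL_STATES
                            ) -> pd.Series:
    """Categorize each spot by its highest epithelial state proportion.

    Ties, and spots with zero proportion in all three states, are left
    unassigned (None) and should be excluded downstream."""
    missing = [s for s in states if s not in state_props.columns]
    if missing:
        raise ValueError(f"missing epithelial state columns: {missing}")
    return _dominant_state(state_props[list(states)]).rename("epithelial_state")


@dataclass
class ColocalizationResult:
    partner: str
    table: pd.DataFrame          # one row per category pair with 2x2 counts
    n_selected: int
    degenerate: bool


def colocalization_odds(spots: pd.DataFrame, partner: str,
                        categories: pd.Series,
                        pairs: list[tuple[str, str]] | None = None
                        ) -> ColocalizationResult:
    """Odds ratio of partner-cell colocalization with epithelial categories.

    Selected spots are those with a strictly positive partner transfer
    score; the partner is *present* in a selected spot when its score
    strictly exceeds its mean over the selected spots. For each ordered
    category pair, the 2x2 table is presence x category; the odds ratio
    applies a Haldane–Anscombe 0.5 correction when any cell is zero (the
    p-value comes from the exact test on the raw table).
    """
    if partner not in spots.columns:
        raise ValueError(f"unknown partner column {partner!r}")
    categories = categories.loc[spots.index]
    score = spots[partner].astype(float)
    selected = score > 0
    n_sel = int(selected.sum())
    sel_scores = score[selected]
    degenerate = bool(n_sel == 0 or sel_scores.nunique() == 1)
    if degenerate:
        warnings.warn(f"partner {partner!r}: constant or empty scores on "
                      "selected spots; presence is degenerate")
    present = sel_scores > sel_scores.mean() if n_sel else sel_scores
    cat_sel = categories[selected]
    cats = [c for c in pd.unique(cat_sel.dropna())]
    if pairs is None:
        pairs = list(itertools.combinations(cats, 2))
    if len(cats) < 2:
        raise ValueError("need spots in at least 2 categories")

    rows = []
    for ca, cb in pairs:
        ma, mb = cat_sel == ca, cat_sel == cb
        a = int((present & ma).sum())
        b = int((~present & ma).sum())
        c = int((present & mb).sum())
        d = int((~present & mb).sum())
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        _, p = fisher_exact([[a, b], [c, d]])
        rows.append({"category_a": ca, "category_b": cb,
                     "present_a": a, "absent_a": b,
                     "present_b": c, "absent_b": d,
                     "odds_ratio": orr, "p": p})
    return ColocalizationResult(partner=partner, table=pd.DataFrame(rows),
                                n_selected=n_sel, degenerate=degenerate)


@dataclass
class NicheTable:
    niche: pd.Series             # niche id per selected spot
    niche_means: pd.DataFrame    # per-niche mean transfer score per component
    zscores: pd.DataFrame        # per-component z across niches


def find_tal_niches(spots: pd.DataFrame, l1_map: dict[str, str],
                    target_l1: str = "TAL",
                    signature_threshold: float = 0.20,
                    k: int = 15, resolution: float = 0.3,
                    seed: int = 0, min_spots: int = 20) -> NicheTable:
    """Recluster TAL-signature spots on their transfer-score vectors.

    Selection: spots whose summed TAL-subclass weight exceeds
    ``signature_threshold`` AND whose highest level-1 signature is TAL.
    The selected spots' level-2 weight vectors are clustered with Louvain
    on a kNN graph; per-niche mean weights and per-component z-scores
    across niches are reported. Spot order does not affect the result
    (spots are canonicalized by id before clustering).
    """
    weight_cols = [c for c in spots.columns if c in l1_map]
    if not weight_cols:
        raise ValueError("no weight columns present in the l1 map")
    l1_groups = sorted(set(l1_map[c] for c in weight_cols))
    l1_scores = pd.DataFrame(
        {g: spots[[c for c in weight_cols if l1_map[c] == g]].sum(axis=1)
         for g in l1_groups}, index=spots.index)
    dominant = _dominant_state(l1_scores)
    selected = (l1_scores[target_l1] > signature_threshold) & \
        (dominant == target_l1)
    sel = spots.index[selected].sort_values()
    if len(sel) < min_spots:
        raise ValueError(f"only {len(sel)} spots selected; need "
                         f">= {min_spots} to cluster")
    feats = spots.loc[sel, weight_cols].to_numpy(dtype=float)
    membership = knn_louvain(feats, k=k, seed=seed, resolution=resolution)
    niche = pd.Series(membership, index=sel, name="niche")
    means = spots.loc[sel, weight_cols].groupby(niche).mean()
    sd = means.std(axis=0, ddof=1).replace(0, np.nan)
    z = (means - means.mean(axis=0)) / sd
    return NicheTable(niche=niche, niche_means=means, zscores=z)
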