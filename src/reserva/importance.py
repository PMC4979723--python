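"""Oil-block importance index.

Each block is scored on four variables — species diversity (a combination
of mean total richness and mean priority-species richness), ecosystem
count, land preservation (natural-vegetation fraction), and overlap with
priority conservation areas or protected zones.  Blocks are ranked into
quartiles per variable (score 1 = bottom quartile, 4 = top), and the index
is the sum of the four scores (4–16)."""

from __future__ import annotations

from math import ceil

import numpy as np
import pandas as pd

from .landscape import Landscape, PlanningUnitSet
from .richness import RichnessMap

__all__ = ["block_metrics", "quartile_scores", "importance_index"]


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi <= lo:
        return np.zeros_like(v, dtype=float)
    return (v - lo) / (hi - lo)


def _iter_blocks(landscape: Landscape):
    for layer in ("operative_blocks", "southern_blocks"):
        arr = getattr(landscape, layer)
        if arr is None:
            continue
        labels = landscape.zone_labels.get(layer, {})
        prefix = "op" if layer == "operative_blocks" else "south"
        for zid in np.unique(arr[arr > 0]):
            name = labels.get(int(zid), f"{prefix}_{int(zid)}")
            yield name, (arr == int(zid)) & landscape.study_mask


def block_metrics(
    landscape: Landscape,
    richness_all: RichnessMap,
    richness_priority: RichnessMap,
    priority_cell_mask: np.ndarray,
    pus: PlanningUnitSet | None = None,
) -> pd.DataFrame:
    """Per-block zonal metrics.

    ``species_diversity`` is the mean of the min–max-normalized (across
    blocks) zonal averages of total and priority-species richness.
    ``preservation`` is the non-deforested fraction of the block;
    ``conservation_overlap`` the fraction inside priority areas or
    protected zones.
    """
    pz = landscape.protected_zones_mask
    important = np.asarray(priority_cell_mask, dtype=bool) | pz
    defo = landscape.deforested_mask
    rows = []
    for name, bm in _iter_blocks(landscape):
        n = int(bm.sum())
        if n == 0:
            continue
        eco = landscape.ecosystems[bm] if landscape.ecosystems is not None else np.array([])
        rows.append({
            "block_id": name,
            "area_km2": n * landscape.grid.cell_area,
            "mean_total_richness": float(richness_all.values[bm].mean()),
            "mean_priority_richness": float(richness_priority.values[bm].mean()),
            "n_ecosystems": int(np.unique(eco[eco > 0]).size),
            "preservation": float((bm & ~defo).sum()) / n,
            "conservation_overlap": float((bm & important).sum()) / n,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["species_diversity"] = 0.5 * (
            _minmax(df["mean_total_richness"].to_numpy())
            + _minmax(df["mean_priority_richness"].to_numpy())
        )
    return df


def quartile_scores(values: np.ndarray) -> np.ndarray:
    """Nearest-rank quartile score in {1..4} per value.

    Cut q is the ceil(q·n/4)-th smallest value; a value's score is the
    first quartile whose cut it does not exceed, so ties share the lower
    score and all-equal inputs score 1.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 4:
        raise ValueError("need at least 4 blocks for quartile scoring; rank directly")
    s = np.sort(v)
    cuts = [s[ceil(q * n / 4) - 1] for q in (1, 2, 3, 4)]
    scores = np.empty(n, dtype=int)
    for i, x in enumerate(v):
        scores[i] = next(q for q, c in zip((1, 2, 3, 4), cuts) if x <= c)
    return scores


def importance_index(metrics: pd.DataFrame) -> pd.DataFrame:
    """Quartile scores for the four variables and their sum (index 4–16)."""
    df = metrics.copy()
    df["q_species_diversity"] = quartile_scores(df["species_diversity"].to_numpy())
    df["q_n_ecosystems"] = quartile_scores(df["n_ecosystems"].to_numpy())
    df["q_preservation"] = quartile_scores(df["preservation"].to_numpy())
    df["q_conservation_overlap"] = quartile_scores(df["conservation_overlap"].to_numpy())
    df["importance"] = (
        df["q_species_diversity"] + df["q_n_ecosystems"]
        + df["q_preservation"] + df["q_conservation_overlap"]
    )
    return df.sort_values("importance", ascending=False).reset_index(drop=True)
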