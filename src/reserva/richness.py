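"""Stacked species-richness maps, upper-tertile masks, and the multi-group
richness center (the cells where the top diversity class of every taxonomic
group overlaps)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np

from .landscape import GridSpec, Landscape

__all__ = [
    "RichnessMap",
    "RichnessCenter",
    "presence_rasters",
    "stack_richness",
    "upper_tertile_mask",
    "richness_center",
    "center_vulnerability",
]


@dataclass
class RichnessMap:
    """Species count per cell for one taxonomic group (or "all")."""

    values: np.ndarray  # int raster; counts are 0 outside the mask
    mask: np.ndarray
    grid: GridSpec
    group: str = "all"


@dataclass
class RichnessCenter:
    mask: np.ndarray
    extent_km2: float


def presence_rasters(
    landscape: Landscape,
    species: list[str] | None = None,
    threshold: float = 0.5,
) -> dict[str, np.ndarray]:
    """Binarize suitability surfaces at ``threshold`` (presence iff ≥)."""
    names = species if species is not None else landscape.species()
    return {
        s: (np.where(landscape.study_mask, landscape.sdm_surfaces[s], 0.0) >= threshold)
        for s in names
    }


def stack_richness(
    presences: dict[str, np.ndarray] | list[np.ndarray],
    mask: np.ndarray,
    grid: GridSpec,
    group: str = "all",
) -> RichnessMap:
    """Cellwise sum of per-species presence rasters."""
    arrs = list(presences.values()) if isinstance(presences, dict) else list(presences)
    if not arrs:
        raise ValueError("at least one species presence raster is required")
    shape = np.asarray(mask).shape
    total = np.zeros(shape, dtype=np.int32)
    for a in arrs:
        if a.shape != shape:
            raise ValueError("presence rasters misaligned")
        total += np.asarray(a, dtype=bool)
    total[~np.asarray(mask, dtype=bool)] = 0
    return RichnessMap(values=total, mask=np.asarray(mask, dtype=bool),
                       grid=grid, group=group)


def upper_tertile_mask(r: RichnessMap, positive_only: bool = True) -> np.ndarray:
    """Cells in the top richness class (upper tertile), ties at the cut kept.

    The cut is the nearest-rank value below which two thirds of the cells
    fall; by default the quantile is taken over cells with richness > 0 so
    that large zero-richness fractions cannot drag zeros into the "highest
    diversity" class (``positive_only=False`` restores the all-cells
    quantile).
    """
    vals = r.values[r.mask]
    if positive_only:
        vals = vals[vals > 0]
    if vals.size == 0:
        warnings.warn("all-zero richness map: upper tertile is empty")
        return np.zeros_like(r.mask)
    if vals.size < 3:
        # degenerate map: everything positive is the top class
        cut = vals.min()
    else:
        m = ceil(vals.size / 3)  # cells in the top tertile before ties
        cut = np.sort(vals)[::-1][m - 1]
    out = (r.values >= cut) & r.mask
    if positive_only:
        out &= r.values > 0
    return out


def tertile_cut(r: RichnessMap, positive_only: bool = True) -> int:
    """The richness value at the upper-tertile boundary (0 if map empty)."""
    vals = r.values[r.mask]
    if positive_only:
        vals = vals[vals > 0]
    if vals.size == 0:
        return 0
    m = ceil(vals.size / 3)
    return int(np.sort(vals)[::-1][min(m, vals.size) - 1])


def richness_center(
    group_masks: dict[str, np.ndarray],
    grid: GridSpec,
    expected_groups: list[str] | None = None,
) -> RichnessCenter:
    """Intersection of all per-group upper-tertile masks."""
    if expected_groups is not None:
        missing = set(expected_groups) - set(group_masks)
        if missing:
            raise ValueError(f"missing group tertile masks: {sorted(missing)}")
    if not group_masks:
        raise ValueError("no group masks given")
    it = iter(group_masks.values())
    center = np.asarray(next(it), dtype=bool).copy()
    for m in it:
        center &= np.asarray(m, dtype=bool)
    return RichnessCenter(mask=center, extent_km2=float(center.sum()) * grid.cell_area)


def center_vulnerability(
    center: RichnessCenter,
    compromised_mask: np.ndarray,
    protected_mask: np.ndarray,
) -> tuple[float, float]:
    """Percent of the richness center inside (blocks ∪ deforested) and inside
    protected zones, rounded to one decimal.  Empty center -> (0.0, 0.0)."""
    n = int(center.mask.sum())
    if n == 0:
        warnings.warn("richness center is empty")
        return (0.0, 0.0)
    pct_comp = 100.0 * int((center.mask & compromised_mask).sum()) / n
    pct_prot = 100.0 * int((center.mask & protected_mask).sum()) / n
    return (round(pct_comp, 1), round(pct_prot, 1))
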