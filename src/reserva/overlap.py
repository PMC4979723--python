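"""Extent and overlap accounting: zone extents as fractions of the study
area, reserve-by-reserve overlap with oil blocks, and per-ecosystem coverage.

All areas are computed on the cell raster (exact at grid resolution) and
reported at table precision: km² to the nearest integer and percentages to
the nearest integer by default (decimals on demand for small overlaps)."""

from __future__ import annotations

from math import floor

import numpy as np
import pandas as pd

from .landscape import Landscape

__all__ = [
    "area_of",
    "percent_cover",
    "table1",
    "table2",
    "ecosystem_coverage",
    "ecosystem_summary",
]


def _round_half_up(x: float, decimals: int = 0) -> float:
    f = 10.0 ** decimals
    r = floor(abs(x) * f + 0.5) / f
    r = -r if x < 0 else r
    return int(r) if decimals <= 0 else r


def area_of(mask: np.ndarray, cell_area: float = 1.0) -> float:
    """km² covered by a boolean cell mask."""
    return float(np.count_nonzero(mask)) * cell_area


def percent_cover(part_km2: float, whole_km2: float, decimals: int = 0) -> float:
    """100 × part/whole at table precision (nearest integer by default)."""
    if whole_km2 <= 0:
        raise ValueError("whole extent must be positive")
    if part_km2 < 0 or part_km2 > whole_km2 * (1 + 1e-9):
        raise ValueError("part extent must lie within [0, whole]")
    return _round_half_up(100.0 * part_km2 / whole_km2, decimals)


def _report_row(name_a: str, name_b: str, overlap: float, base: float,
                decimals: int = 0) -> dict:
    return {
        "element_a": name_a,
        "element_b": name_b,
        "overlap_km2": _round_half_up(overlap),
        "pct_of_a": percent_cover(min(overlap, base), base, decimals) if base > 0 else 0.0,
    }


def table1(landscape: Landscape, decimals: int = 0) -> pd.DataFrame:
    """Extents of PA, UA, protected zones, and oil blocks vs the study area."""
    ca = landscape.grid.cell_area
    study = area_of(landscape.study_mask, ca)
    pa = landscape._zone_mask("protected_areas")
    ua = landscape._zone_mask("untouchable_areas")
    op = landscape._zone_mask("operative_blocks")
    so = landscape._zone_mask("southern_blocks")
    rows = [
        ("PA", pa), ("UA", ua), ("Protected zones (PA + UA)", pa | ua),
        ("Operative oil blocks", op), ("Southern oil blocks", so),
        ("All oil blocks", op | so),
    ]
    return pd.DataFrame(
        [_report_row(name, "study_area", area_of(m, ca), study, decimals)
         for name, m in rows]
    )


def table2(landscape: Landscape, decimals: int = 0) -> pd.DataFrame:
    """Overlaps of oil blocks with protected zones, per category and per
    named reserve, plus the three-way partition of the study area."""
    ca = landscape.grid.cell_area
    study = area_of(landscape.study_mask, ca)
    pa = landscape._zone_mask("protected_areas")
    ua = landscape._zone_mask("untouchable_areas")
    op = landscape._zone_mask("operative_blocks")
    so = landscape._zone_mask("southern_blocks")
    pz = pa | ua
    blocks = op | so

    rows = [
        _report_row("PA", "operative blocks", area_of(pa & op, ca), area_of(pa, ca), decimals),
        _report_row("PA", "southern blocks", area_of(pa & so, ca), area_of(pa, ca), max(decimals, 2)),
        _report_row("UA", "operative blocks", area_of(ua & op, ca), area_of(ua, ca), decimals),
        _report_row("UA", "southern blocks", area_of(ua & so, ca), area_of(ua, ca), decimals),
        _report_row("Protected zones", "all blocks", area_of(pz & blocks, ca), area_of(pz, ca), decimals),
    ]
    # each named reserve (PA then UA layers) against all blocks
    for layer, arr in (("protected_areas", landscape.protected_areas),
                       ("untouchable_areas", landscape.untouchable_areas)):
        if arr is None:
            continue
        labels = landscape.zone_labels.get(layer, {})
        for zid in np.unique(arr[arr > 0]):
            zm = arr == zid
            name = labels.get(int(zid), f"{layer}_{int(zid)}")
            rows.append(_report_row(name, "all blocks",
                                    area_of(zm & blocks, ca), area_of(zm, ca), decimals))
    rows += [
        _report_row("Study area", "all blocks", area_of(blocks & landscape.study_mask, ca),
                    study, decimals),
        _report_row("Study area", "protected zones without blocks",
                    area_of(pz & ~blocks & landscape.study_mask, ca), study, decimals),
        _report_row("Study area", "without protected zones and oil blocks",
                    area_of(landscape.study_mask & ~pz & ~blocks, ca), study, decimals),
    ]
    return pd.DataFrame(rows)


def ecosystem_coverage(landscape: Landscape, decimals: int = 0) -> pd.DataFrame:
    """Per-ecosystem percent inside oil blocks, and percent inside protected
    zones free of blocks and deforestation (the effectively protected part)."""
    if landscape.ecosystems is None:
        raise ValueError("landscape has no ecosystem layer")
    ca = landscape.grid.cell_area
    blocks = landscape.all_blocks_mask
    effective = (landscape.protected_zones_mask & ~blocks
                 & ~landscape.deforested_mask)
    rows = []
    for k in landscape.ecosystem_ids():
        em = (landscape.ecosystems == k) & landscape.study_mask
        ext = area_of(em, ca)
        rows.append({
            "ecosystem_id": k,
            "extent_km2": _round_half_up(ext),
            "pct_in_blocks": percent_cover(area_of(em & blocks, ca), ext, decimals),
            "pct_protected_free": percent_cover(area_of(em & effective, ca), ext, decimals),
        })
    return pd.DataFrame(rows)


def ecosystem_summary(coverage: pd.DataFrame) -> dict:
    """Counts of ecosystems above block-cover thresholds / with no protection."""
    return {
        "n_ecosystems": int(len(coverage)),
        "n_in_blocks": int((coverage["pct_in_blocks"] > 0).sum()),
        "n_over_50pct_blocks": int((coverage["pct_in_blocks"] > 50).sum()),
        "n_over_95pct_blocks": int((coverage["pct_in_blocks"] > 95).sum()),
        "n_unprotected": int((coverage["pct_protected_free"] == 0).sum()),
    }
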