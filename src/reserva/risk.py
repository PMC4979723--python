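"""Environmental Risk Surface (ERS).

Threat layers — point sources (oil wells, dams, airports), polylines
(roads) and continuous fields (population, agriculture, mining) — are
turned into per-cell footprints with a distance-decay kernel, then combined
into a single 0–100 impact raster.  The ERS serves two roles downstream:
its per-PU mean is the planning-unit cost (favoring intact areas), and
cells above the impact threshold are excluded from selection.

Default weights, kernels and decay radii are declared stand-ins exposed in
configuration; they are not calibrated against any particular threat
inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.draw import line as _draw_line

from .landscape import Landscape, PlanningUnitSet, ThreatLayer

__all__ = [
    "ThreatSpec",
    "ERS",
    "DEFAULT_THREAT_SPECS",
    "threat_footprint",
    "compose_ers",
    "high_impact_mask",
    "pu_cost",
]

#: minimum PU cost so pristine units still carry positive cost (a zero-cost
#: PU makes the minimum-set objective degenerate)
COST_EPSILON = 0.01


@dataclass(frozen=True)
class ThreatSpec:
    name: str
    weight: float = 1.0
    decay_radius_km: float = 0.0  # 0 => pass-through field
    kernel: str = "linear"  # "linear" | "exponential"

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("threat weight must be nonnegative")
        if self.decay_radius_km < 0:
            raise ValueError("decay radius must be nonnegative")
        if self.kernel not in ("linear", "exponential"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


# equal weights, linear decay; radii per threat type
DEFAULT_THREAT_SPECS: dict[str, ThreatSpec] = {
    "population": ThreatSpec("population"),
    "agriculture": ThreatSpec("agriculture"),
    "mining": ThreatSpec("mining", decay_radius_km=2.0),
    "oil_wells": ThreatSpec("oil_wells", decay_radius_km=1.0),
    "dams": ThreatSpec("dams", decay_radius_km=5.0),
    "roads": ThreatSpec("roads", decay_radius_km=2.0),
    "airports": ThreatSpec("airports", decay_radius_km=5.0),
}


@dataclass
class ERS:
    """Composite 0–100 impact raster; cells strictly above ``threshold`` are
    treated as highly impacted."""

    values: np.ndarray
    threshold: float = 32.0
    specs: dict[str, ThreatSpec] = field(default_factory=dict)


def rasterize_sources(layer: ThreatLayer, shape: tuple[int, int]) -> np.ndarray:
    """Boolean raster of source cells for a point or line layer."""
    src = np.zeros(shape, dtype=bool)
    if layer.kind == "points" and layer.points is not None and len(layer.points):
        pts = np.asarray(layer.points, dtype=int)
        ok = (pts[:, 0] >= 0) & (pts[:, 0] < shape[0]) & (pts[:, 1] >= 0) & (pts[:, 1] < shape[1])
        src[pts[ok, 0], pts[ok, 1]] = True
    elif layer.kind == "lines" and layer.lines:
        for verts in layer.lines:
            v = np.asarray(verts, dtype=int)
            for (r0, c0), (r1, c1) in zip(v[:-1], v[1:]):
                rr, cc = _draw_line(int(r0), int(c0), int(r1), int(c1))
                ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
                src[rr[ok], cc[ok]] = True
    return src


def threat_footprint(landscape: Landscape, layer: ThreatLayer, spec: ThreatSpec) -> np.ndarray:
    """Per-cell intensity in [0, 1] for one threat.

    Point/line sources decay with distance to the nearest source (so the
    multi-source footprint equals the cellwise max over single sources for
    any monotone kernel), and are exactly zero beyond the decay radius.
    Fields pass through normalized to [0, 1] by their in-mask maximum.
    """
    shape = landscape.grid.shape
    if layer.kind == "field":
        f = np.where(landscape.study_mask, np.asarray(layer.field, dtype=float), 0.0)
        f = np.clip(f, 0.0, None)
        top = f.max()
        out = f / top if top > 0 else f
    else:
        src = rasterize_sources(layer, shape)
        if not src.any():
            return np.zeros(shape)
        d = distance_transform_edt(~src) * landscape.grid.cell_size
        r = spec.decay_radius_km
        if r <= 0:
            out = src.astype(float)
        elif spec.kernel == "linear":
            out = np.clip(1.0 - d / r, 0.0, 1.0)
        else:
            out = np.where(d <= r, np.exp(-d / r), 0.0)
    out = np.where(landscape.study_mask, out, 0.0)
    return out


def compose_ers(
    footprints: dict[str, np.ndarray],
    specs: dict[str, ThreatSpec],
    threshold: float = 32.0,
) -> ERS:
    """Weighted sum of normalized footprints rescaled to 0–100.

    The affine rescaling maps zero threat to 0 and the theoretical maximum
    (every footprint at 1) to 100; values are clipped to [0, 100].
    """
    total_w = sum(specs[name].weight for name in footprints)
    if total_w <= 0:
        raise ValueError("threat weights are all zero")
    acc = None
    for name, fp in footprints.items():
        term = specs[name].weight * np.asarray(fp, dtype=float)
        acc = term if acc is None else acc + term
    values = np.clip(100.0 * acc / total_w, 0.0, 100.0)
    return ERS(values=values, threshold=threshold, specs=dict(specs))


def build_ers(
    landscape: Landscape,
    specs: dict[str, ThreatSpec] | None = None,
    threshold: float = 32.0,
) -> ERS:
    """Footprint + composition convenience for a landscape's threat layers."""
    specs = dict(specs) if specs is not None else dict(DEFAULT_THREAT_SPECS)
    fps = {}
    for name, layer in landscape.threat_layers.items():
        spec = specs.get(name, ThreatSpec(name))
        specs[name] = spec
        fps[name] = threat_footprint(landscape, layer, spec)
    if not fps:
        return ERS(values=np.zeros(landscape.grid.shape), threshold=threshold, specs=specs)
    return compose_ers(fps, specs, threshold=threshold)


def high_impact_mask(ers: ERS) -> np.ndarray:
    """Cells with impact strictly greater than the threshold."""
    return ers.values > ers.threshold


def pu_cost(ers: ERS, pus: PlanningUnitSet, epsilon: float = COST_EPSILON) -> np.ndarray:
    """Mean ERS over each PU's member cells, floored at ``epsilon``."""
    valid = pus.pu_index >= 0
    idx = pus.pu_index[valid]
    counts = np.bincount(idx, minlength=pus.n_pus).astype(float)
    sums = np.bincount(idx, weights=ers.values[valid], minlength=pus.n_pus)
    return np.maximum(sums / counts, epsilon)
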