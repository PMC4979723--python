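"""Landscape and result I/O.

Rasters are stored as single-band ESRI ASCII grids (.asc) — a plain-text
format every GIS reads — with no-data honored and exact value round-trip.
Zone layers travel as GeoJSON polygon collections (rasterized onto the
grid by cell-center containment) or as integer rasters; tables as CSV.
A landscape directory is self-describing via ``landscape.yaml``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely import contains_xy
from shapely.geometry import mapping, shape

from .landscape import GridSpec, Landscape, PlanningUnitSet, ThreatLayer

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "zones_to_geojson",
    "geojson_to_zones",
    "write_landscape",
    "read_landscape",
    "write_pu_table",
]

NODATA = -9999.0


def write_ascii_grid(path: str | Path, values: np.ndarray, grid: GridSpec,
                     nodata_mask: np.ndarray | None = None) -> None:
    """Write one raster as an ESRI ASCII grid with full float precision."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("raster shape does not match grid")
    out = values.copy()
    if nodata_mask is not None:
        out[np.asarray(nodata_mask, dtype=bool)] = NODATA
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin[0]!r}\n"
        f"yllcorner {grid.origin[1]!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.17g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid -> (values, grid, nodata_mask)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {values.shape} does not match header")
    grid = GridSpec(n_rows, n_cols, cell_area=header["cellsize"] ** 2,
                    origin=(header["xllcorner"], header["yllcorner"]))
    nodata = values == header.get("nodata_value", NODATA)
    return values, grid, nodata


def _check_grid(name: str, got: GridSpec, want: GridSpec) -> None:
    if got != want:
        raise ValueError(
            f"layer {name!r} grid {got.shape}/{got.cell_area} does not match "
            f"expected {want.shape}/{want.cell_area}")


# -- zone polygons ----------------------------------------------------------


def zones_to_geojson(path: str | Path, zone_raster: np.ndarray, grid: GridSpec,
                     labels: dict[int, str] | None = None) -> None:
    """Write each zone id as a (multi)polygon feature in grid coordinates.

    Zones are emitted as unions of cell squares via shapely, which keeps the
    raster -> polygon -> raster round trip exact at grid resolution.
    """
    from shapely.geometry import box
    from shapely.ops import unary_union

    cs = grid.cell_size
    x0, y0 = grid.origin
    feats = []
    labels = labels or {}
    for zid in np.unique(zone_raster[zone_raster > 0]):
        rows, cols = np.nonzero(zone_raster == zid)
        cells = [
            box(x0 + c * cs, y0 + (grid.n_rows - r - 1) * cs,
                x0 + (c + 1) * cs, y0 + (grid.n_rows - r) * cs)
            for r, c in zip(rows, cols)
        ]
        geom = unary_union(cells)
        feats.append({
            "type": "Feature",
            "properties": {"id": int(zid), "label": labels.get(int(zid), str(int(zid)))},
            "geometry": mapping(geom),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def geojson_to_zones(path: str | Path, grid: GridSpec) -> tuple[np.ndarray, dict[int, str]]:
    """Rasterize a GeoJSON polygon collection by cell-center containment."""
    with open(path) as fh:
        fc = json.load(fh)
    x, y = grid.cell_centers()
    zones = np.zeros(grid.shape, dtype=np.int32)
    labels: dict[int, str] = {}
    for feat in fc.get("features", []):
        geom = shape(feat["geometry"])
        zid = int(feat["properties"]["id"])
        labels[zid] = str(feat["properties"].get("label", zid))
        inside = contains_xy(geom, x.ravel(), y.ravel()).reshape(grid.shape)
        zones[inside] = zid
    return zones, labels


# -- whole landscapes -------------------------------------------------------

_ZONE_LAYERS = ("protected_areas", "untouchable_areas",
                "operative_blocks", "southern_blocks")


def write_landscape(landscape: Landscape, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "sdm").mkdir(parents=True, exist_ok=True)
    g = landscape.grid
    inv = ~landscape.study_mask
    write_ascii_grid(out / "study_mask.asc", landscape.study_mask.astype(float), g)
    if landscape.ecosystems is not None:
        write_ascii_grid(out / "ecosystems.asc", landscape.ecosystems.astype(float), g,
                         nodata_mask=inv)
    if landscape.deforested is not None:
        write_ascii_grid(out / "deforested.asc", landscape.deforested.astype(float), g)
    for name in _ZONE_LAYERS:
        arr = getattr(landscape, name)
        if arr is not None:
            zones_to_geojson(out / f"{name}.geojson", arr, g,
                             landscape.zone_labels.get(name))
    for sp, surf in landscape.sdm_surfaces.items():
        write_ascii_grid(out / "sdm" / f"{sp}.asc", surf, g, nodata_mask=inv)
    pd.DataFrame({
        "species": list(landscape.sdm_surfaces),
        "group": [landscape.species_groups[s] for s in landscape.sdm_surfaces],
        "priority": [bool(landscape.priority_species.get(s, False))
                     for s in landscape.sdm_surfaces],
    }).to_csv(out / "species.csv", index=False)

    threats_meta = {}
    for name, layer in landscape.threat_layers.items():
        if layer.kind == "field":
            write_ascii_grid(out / f"threat_{name}.asc", layer.field, g)
            threats_meta[name] = {"kind": "field", "path": f"threat_{name}.asc"}
        elif layer.kind == "points":
            threats_meta[name] = {"kind": "points",
                                  "points": np.asarray(layer.points).tolist()}
        else:
            threats_meta[name] = {"kind": "lines",
                                  "lines": [np.asarray(l).tolist() for l in layer.lines]}
    meta = {
        "grid": {"n_rows": g.n_rows, "n_cols": g.n_cols, "cell_area": g.cell_area,
                 "origin": list(g.origin)},
        "threats": threats_meta,
    }
    with open(out / "landscape.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def read_landscape(in_dir: str | Path) -> Landscape:
    src = Path(in_dir)
    with open(src / "landscape.yaml") as fh:
        meta = yaml.safe_load(fh)
    gm = meta["grid"]
    grid = GridSpec(gm["n_rows"], gm["n_cols"], gm["cell_area"], tuple(gm["origin"]))

    mask_vals, mask_grid, _ = read_ascii_grid(src / "study_mask.asc")
    _check_grid("study_mask", mask_grid, grid)
    mask = mask_vals > 0.5

    eco = None
    if (src / "ecosystems.asc").exists():
        vals, eg, nodata = read_ascii_grid(src / "ecosystems.asc")
        _check_grid("ecosystems", eg, grid)
        eco = np.where(nodata, 0, vals).astype(np.int32)
    defo = None
    if (src / "deforested.asc").exists():
        vals, dg, _ = read_ascii_grid(src / "deforested.asc")
        _check_grid("deforested", dg, grid)
        defo = vals > 0.5

    zones = {}
    labels = {}
    for name in _ZONE_LAYERS:
        p = src / f"{name}.geojson"
        if p.exists():
            zones[name], labels[name] = geojson_to_zones(p, grid)

    surfaces: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    priority: dict[str, bool] = {}
    if (src / "species.csv").exists():
        spdf = pd.read_csv(src / "species.csv")
        for _, row in spdf.iterrows():
            sp = row["species"]
            vals, sg, nodata = read_ascii_grid(src / "sdm" / f"{sp}.asc")
            _check_grid(f"sdm:{sp}", sg, grid)
            surfaces[sp] = np.where(nodata, 0.0, vals)
            groups[sp] = row["group"]
            priority[sp] = bool(row["priority"])

    threats: dict[str, ThreatLayer] = {}
    for name, tm in (meta.get("threats") or {}).items():
        if tm["kind"] == "field":
            vals, tg, _ = read_ascii_grid(src / tm["path"])
            _check_grid(f"threat:{name}", tg, grid)
            threats[name] = ThreatLayer(kind="field", field=vals)
        elif tm["kind"] == "points":
            threats[name] = ThreatLayer(
                kind="points", points=np.asarray(tm["points"], dtype=int).reshape(-1, 2))
        else:
            threats[name] = ThreatLayer(
                kind="lines", lines=[np.asarray(l, dtype=int) for l in tm["lines"]])

    return Landscape(
        grid=grid, study_mask=mask, sdm_surfaces=surfaces,
        species_groups=groups, priority_species=priority, ecosystems=eco,
        deforested=defo, threat_layers=threats, zone_labels=labels,
        **{name: zones.get(name) for name in _ZONE_LAYERS},
    )


def write_pu_table(path: str | Path, pus: PlanningUnitSet) -> None:
    from .landscape import PUStatus

    pd.DataFrame({
        "pu_id": pus.ids,
        "area_km2": pus.area,
        "cost": pus.cost,
        "status": [PUStatus(s).name.lower() for s in pus.status],
    }).to_csv(path, index=False)
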