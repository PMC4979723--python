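"""Seeded synthetic landscapes with the statistical structure the planning
analysis assumes.

The generator emulates, at desk scale, the ingredients of an Amazonian
conservation-planning dataset: per-species suitability surfaces spanning a
controlled range-size spectrum across five taxonomic groups, a Voronoi
ecosystem partition, overlapping reserve and oil-block polygons (southern
blocks clustered in the southern half; reserve–block overlap configurable),
point/line/field threat sources, and deforestation concentrated around
roads and wells.  Species range centers are placed with a north-biased
density so a multi-group richness center exists by construction.

Every layer draws from a sub-stream keyed by (seed, stable hash of the
layer name), so adding one layer never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.spatial import cKDTree

from .landscape import GridSpec, Landscape, ThreatLayer

__all__ = ["SynthConfig", "generate_landscape", "make_paper_mimic"]

#: concession cap: no generated block exceeds 200,000 ha = 2,000 km²
MAX_BLOCK_AREA_KM2 = 2_000.0

#: species registry of the Ecuadorian-Amazon study this generator emulates:
#: amphibians, birds, heliconiine butterflies, medium/large terrestrial
#: mammals and vascular plants (745 species in total, joined by 25 ecosystems)
STUDY_GROUP_COUNTS = {
    "amphibian": 86,
    "bird": 267,
    "butterfly": 49,
    "mammal": 32,
    "plant": 311,
}

#: default desk-scale counts: the study registry scaled down tenfold
DEFAULT_GROUP_COUNTS = {
    g: max(1, round(c / 10)) for g, c in STUDY_GROUP_COUNTS.items()
}

DEFAULT_THREAT_CONFIG = {
    "oil_wells": {"kind": "points", "density_per_1000km2": 8.0, "in_blocks": True},
    "dams": {"kind": "points", "density_per_1000km2": 0.4},
    "airports": {"kind": "points", "density_per_1000km2": 0.3},
    "roads": {"kind": "lines", "n_roads": 4},
    "population": {"kind": "field", "smooth_km": 8.0},
    "agriculture": {"kind": "field", "smooth_km": 6.0},
    "mining": {"kind": "points", "density_per_1000km2": 0.6},
}


@dataclass
class SynthConfig:
    seed: int = 0
    grid: GridSpec = field(default_factory=lambda: GridSpec(100, 100, 1.0))
    n_species_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_COUNTS))
    range_size_spectrum: tuple[float, float, str] = (50.0, 6000.0, "loguniform")
    n_ecosystems: int = 25
    n_reserves: int = 5
    n_untouchable: int = 2
    n_operative_blocks: int = 8
    n_southern_blocks: int = 9
    max_block_area: float = MAX_BLOCK_AREA_KM2
    reserve_block_overlap: float = 0.3  # fraction of reserves seeded inside blocks
    priority_species_fraction: float = 0.2
    south_specialist_fraction: float = 0.0  # species confined to southern blocks
    richness_gradient: float = 2.0  # north-bias strength for range centers
    #: (row0, row1, col0, col1) cell window where ``hotspot_fraction`` of each
    #: group's species are centered, forcing a shared multi-group richness peak
    hotspot: tuple[int, int, int, int] | None = None
    hotspot_fraction: float = 0.0
    noise_amplitude: float = 0.03
    threat_config: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_THREAT_CONFIG.items()})
    deforestation_fraction: float = 0.08
    irregular_mask: bool = True

    def rng(self, layer: str) -> np.random.Generator:
        """Independent stream for one layer, stable under layer additions."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, zlib.crc32(layer.encode())]))


# ---------------------------------------------------------------------------
# layer builders


def _study_mask(cfg: SynthConfig) -> np.ndarray:
    g = cfg.grid
    if not cfg.irregular_mask:
        return np.ones(g.shape, dtype=bool)
    rng = cfg.rng("study_mask")
    noise = gaussian_filter(rng.standard_normal(g.shape), sigma=6.0, mode="nearest")
    noise = noise / max(noise.std(), 1e-12)
    rows, cols = np.indices(g.shape)
    # distance to the nearest border, normalized; carve only near edges
    edge = np.minimum.reduce([rows, cols, g.n_rows - 1 - rows, g.n_cols - 1 - cols])
    edge = edge / max(edge.max(), 1)
    mask = (noise + 4.0 * edge) > 0.3
    if not mask.any():
        mask = np.ones(g.shape, dtype=bool)
    return mask


def _voronoi_ecosystems(cfg: SynthConfig, mask: np.ndarray) -> np.ndarray:
    rng = cfg.rng("ecosystems")
    cells = np.argwhere(mask)
    if len(cells) < cfg.n_ecosystems:
        raise ValueError("study mask too small for the requested ecosystems")
    centers = cells[rng.choice(len(cells), size=cfg.n_ecosystems, replace=False)]
    tree = cKDTree(centers)
    _, lab = tree.query(cells)
    eco = np.zeros(mask.shape, dtype=np.int32)
    eco[cells[:, 0], cells[:, 1]] = lab + 1
    return eco


def _species_surface(
    rng: np.random.Generator,
    grid: GridSpec,
    mask: np.ndarray,
    center_rc: tuple[float, float],
    area_km2: float,
    noise_amplitude: float,
) -> np.ndarray:
    """Anisotropic Gaussian suitability bump calibrated so the cells with
    suitability ≥ 0.5 cover ~``area_km2`` (nearest-rank calibration of the
    Mahalanobis field against the requested cell count)."""
    rows, cols = np.indices(grid.shape)
    dr = (rows - center_rc[0]).astype(float)
    dc = (cols - center_rc[1]).astype(float)
    ratio = rng.uniform(1.0, 2.5)
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * dc + st * dr
    v = -st * dc + ct * dr
    # nominal sigmas from the requested ellipse area at the 0.5 contour
    c0 = 2.0 * np.log(2.0)
    n_cells_target = area_km2 / grid.cell_area
    sxsy = n_cells_target / (np.pi * c0)
    sx = np.sqrt(sxsy * ratio)
    sy = np.sqrt(sxsy / ratio)
    q = (u / sx) ** 2 + (v / sy) ** 2

    # calibrate the 0.5 contour against the mask so edge clipping cannot
    # shrink the realized extent: pick c as the nearest-rank quantile of q
    q_in = np.sort(q[mask])
    k = int(round(n_cells_target))
    k = min(max(k, 1), len(q_in))
    c = max(q_in[k - 1], 1e-9)

    suit = np.power(2.0, -q / c)  # equals 0.5 exactly on the calibrated contour
    if noise_amplitude > 0:
        noise = gaussian_filter(rng.standard_normal(grid.shape), sigma=2.0, mode="nearest")
        nmax = np.abs(noise).max()
        if nmax > 0:
            suit = suit + noise_amplitude * noise / nmax
    suit = np.clip(suit, 0.0, 1.0)
    return np.where(mask, suit, 0.0)


def _sample_center(
    rng: np.random.Generator,
    cells: np.ndarray,
    weights: np.ndarray,
) -> tuple[int, int]:
    i = rng.choice(len(cells), p=weights)
    return int(cells[i, 0]), int(cells[i, 1])


def _generate_species(cfg: SynthConfig, mask: np.ndarray,
                      southern: np.ndarray | None) -> tuple[dict, dict, dict]:
    lo, hi, dist = cfg.range_size_spectrum
    if dist != "loguniform":
        raise ValueError(f"unsupported range-size distribution {dist!r}")
    mask_area = mask.sum() * cfg.grid.cell_area
    hi = min(hi, 0.95 * mask_area)
    cells = np.argwhere(mask)
    w = np.exp(-cfg.richness_gradient * cells[:, 0] / cfg.grid.n_rows)
    w = w / w.sum()
    south_cells = None
    if southern is not None and southern.any():
        south_cells = np.argwhere(southern & mask)

    surfaces: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    priority: dict[str, bool] = {}
    hot_cells = None
    if cfg.hotspot is not None and cfg.hotspot_fraction > 0:
        r0, r1, c0, c1 = cfg.hotspot
        hot = np.zeros(mask.shape, dtype=bool)
        hot[r0:r1, c0:c1] = True
        hot_cells = np.argwhere(hot & mask)
    for group, count in cfg.n_species_per_group.items():
        rng = cfg.rng(f"species:{group}")
        n_south = int(round(cfg.south_specialist_fraction * count)) if south_cells is not None else 0
        n_hot = int(round(cfg.hotspot_fraction * count)) if hot_cells is not None and len(hot_cells) else 0
        for i in range(count):
            name = f"{group}_{i:03d}"
            if i < n_south:
                # range confined to (and calibrated within) the southern blocks
                j = rng.integers(len(south_cells))
                center = (int(south_cells[j, 0]), int(south_cells[j, 1]))
                south_area = len(south_cells) * cfg.grid.cell_area
                a_hi = min(hi, max(lo * 1.5, 0.5 * south_area))
                area = float(np.exp(rng.uniform(np.log(lo), np.log(a_hi))))
                surfaces[name] = _species_surface(
                    rng, cfg.grid, southern & mask, center, area, cfg.noise_amplitude)
            else:
                if i < n_south + n_hot:
                    # hotspot species: shared richness peak, but ranges wide
                    # enough to spill past the hotspot neighbourhood
                    j = rng.integers(len(hot_cells))
                    center = (int(hot_cells[j, 0]), int(hot_cells[j, 1]))
                    a_lo = min(max(lo, 0.1 * hi), hi)
                    area = float(np.exp(rng.uniform(np.log(a_lo), np.log(hi))))
                else:
                    center = _sample_center(rng, cells, w)
                    area = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                surfaces[name] = _species_surface(
                    rng, cfg.grid, mask, center, area, cfg.noise_amplitude)
            groups[name] = group
            priority[name] = bool(rng.random() < cfg.priority_species_fraction)
    return surfaces, groups, priority


def _place_rectangles(
    rng: np.random.Generator,
    mask: np.ndarray,
    n: int,
    area_range: tuple[float, float],
    cell_area: float,
    row_range: tuple[int, int],
    occupied: np.ndarray,
    max_tries: int = 2000,
) -> np.ndarray:
    """Non-overlapping axis-aligned rectangles as a zone-id raster.

    Each rectangle is jittered inside its own slot of a shuffled grid over
    the row band, which keeps same-category zones disjoint even at high
    packing density."""
    zones = np.zeros(mask.shape, dtype=np.int32)
    n_rows, n_cols = mask.shape
    band_h = row_range[1] - row_range[0]
    # slot grid: enough cells for n rectangles, roughly square slots
    nc_slots = max(1, int(np.ceil(np.sqrt(n * n_cols / max(band_h, 1)))))
    nr_slots = max(1, int(np.ceil(n / nc_slots)))
    slot_h = band_h / nr_slots
    slot_w = n_cols / nc_slots
    slots = [(i, j) for i in range(nr_slots) for j in range(nc_slots)]
    rng.shuffle(slots)
    zid = 1
    for (si, sj) in slots:
        if zid > n:
            break
        r_lo = row_range[0] + int(si * slot_h)
        r_hi = row_range[0] + int((si + 1) * slot_h)
        c_lo, c_hi = int(sj * slot_w), int((sj + 1) * slot_w)
        placed = False
        for _ in range(max_tries):
            area = rng.uniform(*area_range) / cell_area
            ratio = rng.uniform(0.6, 1.7)
            h = max(1, min(int(round(np.sqrt(area * ratio))), r_hi - r_lo))
            wdt = max(1, min(int(round(area / h)), c_hi - c_lo))
            r0 = int(rng.integers(r_lo, max(r_lo + 1, r_hi - h + 1)))
            c0 = int(rng.integers(c_lo, max(c_lo + 1, c_hi - wdt + 1)))
            block = np.zeros(mask.shape, dtype=bool)
            block[r0:r0 + h, c0:c0 + wdt] = True
            block &= mask
            if not block.any() or (block & (occupied | (zones > 0))).any():
                continue
            zones[block] = zid
            placed = True
            break
        if placed:
            zid += 1
    if zid <= n:
        raise ValueError(f"infeasible packing: placed {zid - 1} of {n} rectangles")
    return zones


def _generate_threats(cfg: SynthConfig, mask: np.ndarray,
                      operative: np.ndarray) -> dict[str, ThreatLayer]:
    layers: dict[str, ThreatLayer] = {}
    mask_area = mask.sum() * cfg.grid.cell_area
    n_rows, n_cols = cfg.grid.shape
    for name, tc in cfg.threat_config.items():
        rng = cfg.rng(f"threat:{name}")
        kind = tc["kind"]
        if kind == "points":
            domain = (operative > 0) & mask if tc.get("in_blocks") else mask
            cells = np.argwhere(domain if domain.any() else mask)
            lam = tc.get("density_per_1000km2", 1.0) * mask_area / 1000.0
            k = max(0, int(rng.poisson(lam)))
            pts = cells[rng.choice(len(cells), size=min(k, len(cells)),
                                   replace=False)] if k else np.empty((0, 2), int)
            layers[name] = ThreatLayer(kind="points", points=pts)
        elif kind == "lines":
            lines = []
            for _ in range(tc.get("n_roads", 3)):
                # a jittered transect entering from a random west-edge row
                r = int(rng.integers(0, n_rows))
                verts = [(r, 0)]
                c = 0
                while c < n_cols - 1:
                    c = min(n_cols - 1, c + int(rng.integers(8, 20)))
                    r = int(np.clip(r + int(rng.integers(-8, 9)), 0, n_rows - 1))
                    verts.append((r, c))
                lines.append(np.array(verts))
            layers[name] = ThreatLayer(kind="lines", lines=lines)
        elif kind == "field":
            sig = tc.get("smooth_km", 5.0) / cfg.grid.cell_size
            f = gaussian_filter(rng.random(cfg.grid.shape), sigma=sig, mode="nearest")
            f = (f - f.min()) / max(f.max() - f.min(), 1e-12)
            layers[name] = ThreatLayer(kind="field", field=np.where(mask, f, 0.0))
        else:
            raise ValueError(f"unknown threat kind {kind!r} for {name!r}")
    return layers


def _deforestation(cfg: SynthConfig, mask: np.ndarray,
                   threats: dict[str, ThreatLayer]) -> np.ndarray:
    """Cells nearest to roads and wells, up to the requested fraction."""
    from .risk import rasterize_sources

    if cfg.deforestation_fraction <= 0:
        return np.zeros(mask.shape, dtype=bool)
    src = np.zeros(mask.shape, dtype=bool)
    for name in ("roads", "oil_wells"):
        if name in threats:
            src |= rasterize_sources(threats[name], mask.shape)
    if not src.any():
        return np.zeros(mask.shape, dtype=bool)
    d = distance_transform_edt(~src)
    d_in = np.sort(d[mask])
    k = int(round(cfg.deforestation_fraction * mask.sum()))
    if k <= 0:
        return np.zeros(mask.shape, dtype=bool)
    cut = d_in[min(k, len(d_in)) - 1]
    return (d <= cut) & mask


# ---------------------------------------------------------------------------


def generate_landscape(cfg: SynthConfig) -> Landscape:
    """Build a complete seeded landscape from the configuration.

    Deterministic for a fixed seed.  Thresholded species extents track the
    requested range-size spectrum (calibrated against the mask, so edge
    clipping does not bias them); ecosystems are a Voronoi partition with
    exactly ``n_ecosystems`` nonempty categories.
    """
    mask = _study_mask(cfg)
    eco = _voronoi_ecosystems(cfg, mask)

    n_rows = cfg.grid.n_rows
    # operative blocks in the northern ~half, southern blocks clustered south
    occupied = np.zeros(mask.shape, dtype=bool)
    rng_ob = cfg.rng("operative_blocks")
    op = _place_rectangles(
        rng_ob, mask, cfg.n_operative_blocks,
        (0.2 * cfg.max_block_area, 0.5 * cfg.max_block_area),
        cfg.grid.cell_area, (0, n_rows // 2), occupied)
    occupied |= op > 0
    rng_sb = cfg.rng("southern_blocks")
    so = _place_rectangles(
        rng_sb, mask, cfg.n_southern_blocks,
        (0.2 * cfg.max_block_area, 0.5 * cfg.max_block_area),
        cfg.grid.cell_area, (n_rows // 2, n_rows), occupied)

    # reserves may overlap operative blocks; untouchable areas sit inside
    # reserves.  Overlapping reserves are seeded at block cells.
    rng_pa = cfg.rng("protected_areas")
    pa = np.zeros(mask.shape, dtype=np.int32)
    n_overlapping = int(round(cfg.reserve_block_overlap * cfg.n_reserves))
    for zid in range(1, cfg.n_reserves + 1):
        overlap_block = zid <= n_overlapping
        domain = (op > 0) & mask if (overlap_block and (op > 0).any()) else mask & (pa == 0)
        cells = np.argwhere(domain)
        if not len(cells):
            raise ValueError("infeasible packing: no room for reserves")
        for _ in range(200):
            rc = cells[rng_pa.integers(len(cells))]
            area = rng_pa.uniform(100, 600) / cfg.grid.cell_area
            ratio = rng_pa.uniform(0.6, 1.6)
            h = max(2, int(round(np.sqrt(area * ratio))))
            wdt = max(2, int(round(area / h)))
            r0 = int(np.clip(rc[0] - h // 2, 0, mask.shape[0] - 1))
            c0 = int(np.clip(rc[1] - wdt // 2, 0, mask.shape[1] - 1))
            blockm = np.zeros(mask.shape, dtype=bool)
            blockm[r0:r0 + h, c0:c0 + wdt] = True
            blockm &= mask
            if blockm.any() and not (pa[blockm] > 0).any():
                pa[blockm] = zid
                break
        else:
            raise ValueError("infeasible packing: could not place reserve")

    rng_ua = cfg.rng("untouchable_areas")
    ua = np.zeros(mask.shape, dtype=np.int32)
    host_ids = list(range(1, cfg.n_reserves + 1))
    for zid in range(1, cfg.n_untouchable + 1):
        host = host_ids[int(rng_ua.integers(len(host_ids)))]
        cells = np.argwhere(pa == host)
        if not len(cells):
            continue
        rc = cells[rng_ua.integers(len(cells))]
        h = max(2, (cells[:, 0].max() - cells[:, 0].min()) // 2)
        wdt = max(2, (cells[:, 1].max() - cells[:, 1].min()) // 2)
        r0, c0 = int(rc[0]), int(rc[1])
        sub = np.zeros(mask.shape, dtype=bool)
        sub[r0:r0 + h, c0:c0 + wdt] = True
        sub &= mask
        ua[sub & (ua == 0)] = zid

    surfaces, groups, priority = _generate_species(cfg, mask, so > 0)
    threats = _generate_threats(cfg, mask, op)
    defo = _deforestation(cfg, mask, threats)

    ls = Landscape(
        grid=cfg.grid,
        study_mask=mask,
        sdm_surfaces=surfaces,
        species_groups=groups,
        priority_species=priority,
        ecosystems=eco,
        protected_areas=pa,
        untouchable_areas=ua,
        operative_blocks=op,
        southern_blocks=so,
        deforested=defo,
        threat_layers=threats,
        zone_labels={
            "protected_areas": {i: f"Reserve {i}" for i in range(1, cfg.n_reserves + 1)},
            "untouchable_areas": {i: f"Untouchable area {i}"
                                  for i in range(1, cfg.n_untouchable + 1)},
        },
    )
    ls.validate()
    return ls


# ---------------------------------------------------------------------------
# study-mimic landscape


def make_paper_mimic(seed: int = 0, grid_size: int = 100) -> Landscape:
    """A ~100×100 landscape whose zone extents approximate the study-area
    proportions: oil blocks ≈ 68% of the mask (operative 32%, southern 36%),
    protected zones ≈ 22%, with ≈ 29% of the protected zones inside blocks.

    Zones are laid out deterministically (blocks tile fixed bands; reserves
    straddle the operative band the way the large northern reserves straddle
    operative concessions); species, threats and deforestation are seeded.
    A fifth of each species group is confined to the southern blocks, so
    scenario contrasts are observable by construction.
    """
    g = grid_size
    grid = GridSpec(g, g, 1.0)
    mask = np.ones((g, g), dtype=bool)

    def band(r0: float, r1: float, c0: float, c1: float) -> tuple[slice, slice]:
        return (slice(int(round(r0 * g / 100)), int(round(r1 * g / 100))),
                slice(int(round(c0 * g / 100)), int(round(c1 * g / 100))))

    # operative blocks tile rows 0–32 (32% of the area), 8 blocks
    op = np.zeros((g, g), dtype=np.int32)
    zid = 1
    for r0, r1 in ((0, 16), (16, 32)):
        for c0, c1 in ((0, 25), (25, 50), (50, 75), (75, 100)):
            op[band(r0, r1, c0, c1)] = zid
            zid += 1
    # southern blocks tile rows 64–100 (36%), 12 blocks
    so = np.zeros((g, g), dtype=np.int32)
    zid = 1
    for r0, r1 in ((64, 76), (76, 88), (88, 100)):
        for c0, c1 in ((0, 25), (25, 50), (50, 75), (75, 100)):
            so[band(r0, r1, c0, c1)] = zid
            zid += 1

    # reserves: two large ones straddling the operative band, one tiny
    # reserve fully inside blocks, two small oil-free southern-band reserves
    pa = np.zeros((g, g), dtype=np.int32)
    pa[band(24, 44, 0, 50)] = 1    # Yasuní-like: 1000 cells, 400 in blocks
    pa[band(26, 46, 60, 90)] = 2   # Cuyabeno-like: 600 cells, 180 in blocks
    pa[band(10, 14, 40, 50)] = 3   # Limoncocha-like: 40 cells, 100% in blocks
    pa[band(50, 58, 5, 25)] = 4    # southern-band reserve, oil-free
    pa[band(54, 62, 70, 95)] = 5   # southern-band reserve, oil-free
    ua = np.zeros((g, g), dtype=np.int32)
    ua[band(34, 44, 0, 50)] = 1    # inside reserve 1, outside blocks
    ua[band(31, 51, 60, 95)] = 2   # straddles reserve 2; 1 row in blocks

    cfg = SynthConfig(
        seed=seed,
        grid=grid,
        n_ecosystems=25,
        south_specialist_fraction=0.2,
        richness_gradient=5.0,
        irregular_mask=False,
        range_size_spectrum=(50.0, 4000.0, "loguniform"),
        # shared richness hotspot inside the operative band -> the five
        # group tertiles provably overlap there
        hotspot=(int(0.06 * g), int(0.26 * g), int(0.30 * g), int(0.62 * g)),
        hotspot_fraction=0.6,
    )
    eco = _voronoi_ecosystems(cfg, mask)
    surfaces, groups, priority = _generate_species(cfg, mask, so > 0)

    threats = _generate_threats(cfg, mask, op)
    defo = _deforestation(cfg, mask, threats)
    # the block-free band just south of the operative concessions is the old
    # deforestation frontier, so the richness center (hotspot plus fringe)
    # sits inside blocks ∪ deforested by construction
    defo = defo | (mask & (np.indices((g, g))[0] < int(0.44 * g)))

    ls = Landscape(
        grid=grid,
        study_mask=mask,
        sdm_surfaces=surfaces,
        species_groups=groups,
        priority_species=priority,
        ecosystems=eco,
        protected_areas=pa,
        untouchable_areas=ua,
        operative_blocks=op,
        southern_blocks=so,
        deforested=defo,
        threat_layers=threats,
        zone_labels={
            "protected_areas": {
                1: "Yasuni-like NP", 2: "Cuyabeno-like WR", 3: "Limoncocha-like BR",
                4: "Quimi-like BR", 5: "Condor-like BR"},
            "untouchable_areas": {1: "Tagaeri-like UA", 2: "Cuyabeno-Imuya-like UA"},
        },
    )
    ls.validate()
    return ls
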