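"""Core domain types for gridded conservation-planning landscapes.

A :class:`Landscape` bundles everything the planning pipeline consumes: a
study-area mask on a regular grid, per-species habitat-suitability surfaces
(stacked species distribution models), a categorical ecosystem map, zone
layers (protected areas, untouchable areas, operative and biddable oil
blocks), a deforestation mask, and threat-source layers.  All rasters share
one :class:`GridSpec`; cells outside the study mask are no-data everywhere.

The planning side tessellates the landscape into square planning units
(PUs), applies scenario lock rules (protected zones forced in; oil blocks
and high-impact areas forced out), and tabulates how much of each feature
falls in each PU (:class:`FeatureAmountMatrix`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from math import ceil, sqrt

import numpy as np

__all__ = [
    "GridSpec",
    "ThreatLayer",
    "Landscape",
    "PUStatus",
    "PlanningUnitSet",
    "FeatureAmountMatrix",
    "tessellate",
    "apply_lock_rules",
    "build_feature_matrix",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular square-cell grid in an abstract planar CRS with km units.

    Row 0 is the northern edge; the origin is the lower-left (south-west)
    corner.  ``cell_area`` is in km²; cell side length is ``sqrt(cell_area)``.
    """

    n_rows: int
    n_cols: int
    cell_area: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_size(self) -> float:
        """Cell side length in km."""
        return sqrt(self.cell_area)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of cell centers, shaped like the grid."""
        cs = self.cell_size
        x0, y0 = self.origin
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = x0 + (cols + 0.5) * cs
        y = y0 + (self.n_rows - rows - 0.5) * cs
        return np.meshgrid(x, y)[0], np.meshgrid(x, y)[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridSpec):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.isclose(self.cell_area, other.cell_area)
            and np.allclose(self.origin, other.origin)
        )

    def __hash__(self) -> int:  # frozen dataclass with custom __eq__
        return hash((self.n_rows, self.n_cols))


@dataclass
class ThreatLayer:
    """One threat source: points (wells, dams, airports), polylines (roads)
    or a continuous field (population, agriculture).

    ``points``: integer (row, col) array, shape (n, 2).
    ``lines``: list of (row, col) vertex arrays; consecutive vertices are
    connected segments.  ``field``: float raster on the landscape grid.
    """

    kind: str  # "points" | "lines" | "field"
    points: np.ndarray | None = None
    lines: list[np.ndarray] | None = None
    field: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("points", "lines", "field"):
            raise ValueError(f"unknown threat layer kind {self.kind!r}")


@dataclass
class Landscape:
    """Aligned raster stack + zone layers defining one planning problem.

    Zone rasters hold integer ids (0 = none); ``zone_labels`` maps layer name
    -> {id: label}.  Ecosystem categories (1..K) partition the study mask.
    """

    grid: GridSpec
    study_mask: np.ndarray
    sdm_surfaces: dict[str, np.ndarray] = field(default_factory=dict)
    species_groups: dict[str, str] = field(default_factory=dict)
    priority_species: dict[str, bool] = field(default_factory=dict)
    ecosystems: np.ndarray | None = None
    protected_areas: np.ndarray | None = None
    untouchable_areas: np.ndarray | None = None
    operative_blocks: np.ndarray | None = None
    southern_blocks: np.ndarray | None = None
    deforested: np.ndarray | None = None
    threat_layers: dict[str, ThreatLayer] = field(default_factory=dict)
    zone_labels: dict[str, dict[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.study_mask = np.asarray(self.study_mask, dtype=bool)
        if self.study_mask.shape != self.grid.shape:
            raise ValueError("study_mask shape does not match grid")
        for name in ("ecosystems", "protected_areas", "untouchable_areas",
                     "operative_blocks", "southern_blocks"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != self.grid.shape:
                    raise ValueError(
                        f"layer {name!r} shape {arr.shape} does not match grid "
                        f"{self.grid.shape}"
                    )
                setattr(self, name, arr.astype(np.int32))
        if self.deforested is not None:
            self.deforested = np.asarray(self.deforested, dtype=bool)

    # -- derived masks -------------------------------------------------

    def _zone_mask(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        if arr is None:
            return np.zeros(self.grid.shape, dtype=bool)
        return arr > 0

    @property
    def protected_zones_mask(self) -> np.ndarray:
        """Protected areas ∪ untouchable areas (the 'protected zones')."""
        return self._zone_mask("protected_areas") | self._zone_mask("untouchable_areas")

    @property
    def all_blocks_mask(self) -> np.ndarray:
        """Operative ∪ southern (biddable) oil blocks."""
        return self._zone_mask("operative_blocks") | self._zone_mask("southern_blocks")

    @property
    def deforested_mask(self) -> np.ndarray:
        if self.deforested is None:
            return np.zeros(self.grid.shape, dtype=bool)
        return self.deforested

    def species(self) -> list[str]:
        return list(self.sdm_surfaces)

    def ecosystem_ids(self) -> list[int]:
        if self.ecosystems is None:
            return []
        vals = np.unique(self.ecosystems[self.study_mask])
        return [int(v) for v in vals if v > 0]

    def validate(self) -> None:
        """Check cross-layer invariants; raise ValueError on violation."""
        if not self.study_mask.any():
            raise ValueError("study mask is empty")
        for name, surf in self.sdm_surfaces.items():
            if surf.shape != self.grid.shape:
                raise ValueError(f"SDM surface {name!r} misaligned with grid")
            inside = surf[self.study_mask]
            if np.nanmin(inside) < -1e-9 or np.nanmax(inside) > 1 + 1e-9:
                raise ValueError(f"SDM surface {name!r} outside [0, 1]")
            if name not in self.species_groups:
                raise ValueError(f"species {name!r} has no group label")
        if self.ecosystems is not None:
            eco_in = self.ecosystems[self.study_mask]
            if (eco_in <= 0).any():
                raise ValueError("ecosystem categories must partition the study mask")
            if (self.ecosystems[~self.study_mask] != 0).any():
                raise ValueError("ecosystem ids present outside the study mask")


class PUStatus(IntEnum):
    AVAILABLE = 0
    LOCKED_IN = 1
    LOCKED_OUT = 2


@dataclass
class PlanningUnitSet:
    """Square planning units clipped to the study mask.

    ``pu_index`` maps each grid cell to its PU id (-1 outside the mask).
    ``adjacency`` maps ordered id pairs (i < j) to shared rook-boundary
    length in km.
    """

    grid: GridSpec
    pu_index: np.ndarray
    area: np.ndarray
    cost: np.ndarray
    status: np.ndarray
    adjacency: dict[tuple[int, int], float]

    @property
    def n_pus(self) -> int:
        return len(self.area)

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.n_pus)

    def cells_of(self, pu: int) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of the member cells of one PU."""
        return np.nonzero(self.pu_index == pu)

    def mask_from_pus(self, selected: np.ndarray) -> np.ndarray:
        """Boolean cell raster covered by the given PU selection."""
        sel = np.zeros(self.n_pus + 1, dtype=bool)
        sel[:-1] = selected
        return sel[self.pu_index]  # pu_index == -1 hits the trailing False

    @property
    def locked_in(self) -> np.ndarray:
        return self.status == PUStatus.LOCKED_IN

    @property
    def locked_out(self) -> np.ndarray:
        return self.status == PUStatus.LOCKED_OUT

    @property
    def available(self) -> np.ndarray:
        return self.status == PUStatus.AVAILABLE

    def copy(self) -> "PlanningUnitSet":
        return PlanningUnitSet(
            grid=self.grid,
            pu_index=self.pu_index.copy(),
            area=self.area.copy(),
            cost=self.cost.copy(),
            status=self.status.copy(),
            adjacency=dict(self.adjacency),
        )

    def zone_fraction(self, zone_mask: np.ndarray) -> np.ndarray:
        """Per-PU fraction of member cells inside ``zone_mask``."""
        inside = np.asarray(zone_mask, dtype=bool) & (self.pu_index >= 0)
        counts = np.bincount(self.pu_index[self.pu_index >= 0],
                             minlength=self.n_pus).astype(float)
        hits = np.bincount(self.pu_index[inside], minlength=self.n_pus)
        return hits / counts


def tessellate(landscape: Landscape, pu_area: float) -> PlanningUnitSet:
    """Divide the study area into square planning units of ~``pu_area`` km².

    Units are aligned blocks of ``b × b`` cells with ``b = ceil(sqrt(pu_area /
    cell_area))``, clipped to the study mask: a PU exists iff at least one of
    its member cells lies inside the mask, and its area is the member-cell
    count times the cell area (edge and coastline PUs are smaller).
    """
    grid = landscape.grid
    if pu_area < grid.cell_area:
        raise ValueError("pu_area must be at least one cell")
    if not landscape.study_mask.any():
        raise ValueError("no planning units: study mask is empty")
    b = ceil(sqrt(pu_area / grid.cell_area))
    rows, cols = np.indices(grid.shape)
    block = (rows // b) * (ceil(grid.n_cols / b)) + (cols // b)
    block = np.where(landscape.study_mask, block, -1)
    # relabel occupied blocks to dense ids in row-major block order
    occupied = np.unique(block[block >= 0])
    remap = np.full(block.max() + 2, -1, dtype=np.int64)
    remap[occupied] = np.arange(len(occupied))
    pu_index = np.where(block >= 0, remap[block], -1)

    counts = np.bincount(pu_index[pu_index >= 0], minlength=len(occupied))
    area = counts * grid.cell_area

    adjacency: dict[tuple[int, int], float] = {}
    cs = grid.cell_size
    # rook-neighbour shared edges between masked cells of different PUs
    for a, bb in ((pu_index[:, :-1], pu_index[:, 1:]),
                  (pu_index[:-1, :], pu_index[1:, :])):
        both = (a >= 0) & (bb >= 0) & (a != bb)
        for i, j in zip(a[both].ravel(), bb[both].ravel()):
            key = (int(min(i, j)), int(max(i, j)))
            adjacency[key] = adjacency.get(key, 0.0) + cs

    n = len(occupied)
    return PlanningUnitSet(
        grid=grid,
        pu_index=pu_index,
        area=area.astype(float),
        cost=np.ones(n),
        status=np.full(n, PUStatus.AVAILABLE, dtype=np.int8),
        adjacency=adjacency,
    )


#: rule priority: a PU overlapping a protected zone and an oil block stays
#: locked in — protected zones are forced into every solution even where
#: they overlap operative blocks.
DEFAULT_LOCK_PRECEDENCE = ("locked_in", "locked_out")

_SCENARIO_BLOCKS = {
    1: ("operative_blocks", "southern_blocks"),
    2: ("operative_blocks",),
    3: (),
}


def apply_lock_rules(
    pus: PlanningUnitSet,
    landscape: Landscape,
    scenario: int,
    ers_mask: np.ndarray | None = None,
    majority: float = 0.5,
    precedence: tuple[str, str] = DEFAULT_LOCK_PRECEDENCE,
) -> PlanningUnitSet:
    """Return a copy of ``pus`` with scenario lock states applied.

    All scenarios lock in protected-zone PUs and lock out high-impact PUs
    (majority of member cells above the risk threshold).  Oil blocks are
    locked out per scenario: 1 = operative + southern, 2 = operative only,
    3 = none.  A PU is "within" a zone when more than ``majority`` of its
    member cells are.  When a PU qualifies for both states, the first entry
    of ``precedence`` wins.
    """
    if scenario not in _SCENARIO_BLOCKS:
        raise ValueError(f"unknown scenario {scenario!r}; expected 1, 2 or 3")
    if ers_mask is not None and ers_mask.shape != landscape.grid.shape:
        raise ValueError("ers_mask misaligned with landscape grid")

    out = pus.copy()
    in_pz = out.zone_fraction(landscape.protected_zones_mask) > majority

    blocked = np.zeros(out.n_pus, dtype=bool)
    if ers_mask is not None:
        blocked |= out.zone_fraction(np.asarray(ers_mask, dtype=bool)) > majority
    for layer in _SCENARIO_BLOCKS[scenario]:
        blocked |= out.zone_fraction(landscape._zone_mask(layer)) > majority

    status = np.full(out.n_pus, PUStatus.AVAILABLE, dtype=np.int8)
    if precedence[0] == "locked_in":
        status[blocked] = PUStatus.LOCKED_OUT
        status[in_pz] = PUStatus.LOCKED_IN
    else:
        status[in_pz] = PUStatus.LOCKED_IN
        status[blocked] = PUStatus.LOCKED_OUT
    out.status = status
    return out


@dataclass
class FeatureAmountMatrix:
    """Per-feature, per-PU amounts in km² for species and ecosystems.

    ``amount`` has shape (n_features, n_pus).  ``total_extent`` is the
    feature's extent over the whole study area; ``protected_amount`` the
    extent inside locked-in PUs.
    """

    feature_ids: list[str]
    kind: np.ndarray  # "species" | "ecosystem" per feature
    amount: np.ndarray
    total_extent: np.ndarray
    protected_amount: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def index_of(self, feature_id: str) -> int:
        return self.feature_ids.index(feature_id)

    def achieved(self, selected: np.ndarray) -> np.ndarray:
        """Per-feature km² inside the selected PU set."""
        return self.amount[:, np.asarray(selected, dtype=bool)].sum(axis=1)

    def recompute_protected(self, pus: PlanningUnitSet) -> None:
        self.protected_amount = self.achieved(pus.locked_in)


def build_feature_matrix(
    landscape: Landscape,
    pus: PlanningUnitSet,
    binarize_threshold: float = 0.5,
    continuous: bool = False,
) -> FeatureAmountMatrix:
    """Tabulate feature amounts per planning unit.

    Species amounts come from thresholding each suitability surface at
    ``binarize_threshold`` (presence-cell count × cell area), or, with
    ``continuous=True``, from summing raw suitabilities.  Ecosystem amounts
    count categorical cells.  Features with zero total extent are an error.
    """
    grid = landscape.grid
    n_pus = pus.n_pus
    valid = pus.pu_index >= 0
    idx = pus.pu_index[valid]

    ids: list[str] = []
    kinds: list[str] = []
    rows: list[np.ndarray] = []
    for name, surf in landscape.sdm_surfaces.items():
        if continuous:
            w = np.where(landscape.study_mask, surf, 0.0)
        else:
            w = (np.where(landscape.study_mask, surf, 0.0) >= binarize_threshold).astype(float)
        rows.append(np.bincount(idx, weights=w[valid], minlength=n_pus) * grid.cell_area)
        ids.append(name)
        kinds.append("species")
    if landscape.ecosystems is not None:
        for k in landscape.ecosystem_ids():
            w = (landscape.ecosystems == k) & landscape.study_mask
            rows.append(np.bincount(idx, weights=w[valid].astype(float),
                                    minlength=n_pus) * grid.cell_area)
            ids.append(f"eco_{k}")
            kinds.append("ecosystem")

    amount = np.array(rows) if rows else np.zeros((0, n_pus))
    total = amount.sum(axis=1)
    empty = [ids[i] for i in np.nonzero(total <= 0)[0]]
    if empty:
        raise ValueError(f"features with zero total extent: {empty}")
    fam = FeatureAmountMatrix(
        feature_ids=ids,
        kind=np.array(kinds),
        amount=amount,
        total_extent=total,
        protected_amount=np.zeros(len(ids)),
    )
    fam.recompute_protected(pus)
    return fam
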