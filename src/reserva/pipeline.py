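"""End-to-end scenario orchestration.

``run`` drives landscape → feature matrix → targets → ERS → lock rules →
annealed selection → priority areas → reports for each requested oil-block
lock scenario, writing tables, rasters, a reproducibility manifest and a
structured log under one run directory.  Identical config + seed gives
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .landscape import Landscape, apply_lock_rules, build_feature_matrix, tessellate
from .overlap import (area_of, ecosystem_coverage, ecosystem_summary, percent_cover,
                      table1, table2)
from .richness import (center_vulnerability, presence_rasters, richness_center,
                       stack_richness, tertile_cut, upper_tertile_mask)
from .risk import DEFAULT_THREAT_SPECS, ThreatSpec, build_ers, high_impact_mask, pu_cost
from .selector import (AnnealSchedule, SelectionProblem, priority_areas,
                       summed_solution)
from .synthetic import SynthConfig, generate_landscape, make_paper_mimic
from .targets import TargetScheme, achievement_report, build_target_table
from .importance import block_metrics, importance_index
from .io import write_ascii_grid, write_pu_table

__all__ = ["RunConfig", "run", "rerun_with_half_targets"]

log = logging.getLogger("reserva")


@dataclass
class RunConfig:
    """Validated parameters for one pipeline run.

    ``landscape`` is either a directory path (written by :func:`reserva.io.
    write_landscape`) or ``{"synthetic": {...}}`` / ``{"mimic": {}}`` for
    generated inputs.  Desk-scale species range thresholds default to a
    tenth of the continental scheme, matching the generator's map extent.
    """

    landscape: dict | str = field(default_factory=lambda: {"mimic": {}})
    seed: int = 0
    pu_area: float = 4.0
    binarize_threshold: float = 0.5
    scheme: TargetScheme = field(default_factory=lambda: TargetScheme(
        scale=0.4, species_thresholds=(1000.0, 7500.0),
        ecosystem_thresholds=(100.0, 10_000.0)))
    ers_threshold: float = 32.0
    threat_specs: dict[str, ThreatSpec] = field(
        default_factory=lambda: dict(DEFAULT_THREAT_SPECS))
    scenarios: tuple[int, ...] = (1, 2, 3)
    n_reps: int = 100
    n_iter: int = 100_000
    spf: float = 10.0
    blm: float = 0.0
    priority_fraction: float = 0.75  # summed-solution threshold as share of reps

    def validate(self) -> None:
        if self.pu_area <= 0:
            raise ValueError("pu_area must be positive")
        if not 0 <= self.binarize_threshold <= 1:
            raise ValueError("binarize_threshold must be in [0, 1]")
        if self.n_reps < 1 or self.n_iter < 1:
            raise ValueError("n_reps and n_iter must be at least 1")
        if not 0 < self.priority_fraction <= 1:
            raise ValueError("priority_fraction must be in (0, 1]")
        bad = [s for s in self.scenarios if s not in (1, 2, 3)]
        if bad:
            raise ValueError(f"unknown scenarios {bad}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scheme"] = dataclasses.asdict(self.scheme)
        d["threat_specs"] = {k: dataclasses.asdict(v) for k, v in self.threat_specs.items()}
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "scheme" in raw:
            raw["scheme"] = TargetScheme(**raw["scheme"])
        if "threat_specs" in raw:
            raw["threat_specs"] = {k: ThreatSpec(**v) for k, v in raw["threat_specs"].items()}
        if "scenarios" in raw:
            raw["scenarios"] = tuple(raw["scenarios"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _load_landscape(cfg: RunConfig) -> Landscape:
    if isinstance(cfg.landscape, (str, Path)):
        from .io import read_landscape
        return read_landscape(cfg.landscape)
    if "mimic" in cfg.landscape:
        return make_paper_mimic(seed=cfg.seed, **cfg.landscape["mimic"])
    if "synthetic" in cfg.landscape:
        synth = dict(cfg.landscape["synthetic"])
        synth.setdefault("seed", cfg.seed)
        return generate_landscape(SynthConfig(**synth))
    raise ValueError("landscape config must be a path, {'mimic': ...} or {'synthetic': ...}")


class _JsonlLog:
    def __init__(self, path: Path):
        self.fh = open(path, "w")

    def event(self, stage: str, **kw) -> None:
        rec = {"stage": stage, **kw}
        self.fh.write(json.dumps(rec, default=str) + "\n")
        self.fh.flush()
        log.info("%s %s", stage, kw)


def run_scenario(
    landscape: Landscape,
    cfg: RunConfig,
    scenario: int,
    out_dir: Path,
    jlog: _JsonlLog,
    scheme: TargetScheme | None = None,
) -> dict:
    """Run one lock scenario end-to-end; returns the achievement summary."""
    scheme = scheme or cfg.scheme
    sdir = out_dir / f"scenario_{scenario}" / (
        "full_targets" if scheme.scale == cfg.scheme.scale else "half_targets")
    sdir.mkdir(parents=True, exist_ok=True)

    pus = tessellate(landscape, cfg.pu_area)
    ers = build_ers(landscape, cfg.threat_specs, threshold=cfg.ers_threshold)
    pus.cost = pu_cost(ers, pus)
    pus = apply_lock_rules(pus, landscape, scenario, ers_mask=high_impact_mask(ers))
    features = build_feature_matrix(landscape, pus, cfg.binarize_threshold)
    targets = build_target_table(features, scheme)
    problem = SelectionProblem(pus=pus, amounts=features, targets=targets,
                               spf=np.full(features.n_features, cfg.spf), blm=cfg.blm)
    jlog.event("problem", scenario=scenario, n_pus=pus.n_pus,
               n_features=features.n_features,
               n_locked_in=int(pus.locked_in.sum()),
               n_locked_out=int(pus.locked_out.sum()))

    threshold = ceil(cfg.priority_fraction * cfg.n_reps)
    ss = summed_solution(problem, n_reps=cfg.n_reps, base_seed=cfg.seed,
                         schedule=AnnealSchedule(n_iter=cfg.n_iter),
                         priority_threshold=threshold)
    prio = priority_areas(ss)
    # representation is judged on the best replicate (the reserve network one
    # would implement); the summed solution maps irreplaceability
    achieved = ss.best.achieved
    report = achievement_report(achieved, targets)

    targets.assign(achieved_km2=achieved).to_csv(sdir / "targets.csv", index=False)
    write_pu_table(sdir / "pu.csv", pus)
    pd.DataFrame({"pu_id": pus.ids, "frequency": ss.frequency}).to_csv(
        sdir / "ssoln.csv", index=False)
    write_ascii_grid(sdir / "priority_mask.asc",
                     pus.mask_from_pus(prio).astype(float), landscape.grid)

    prio_cells = pus.mask_from_pus(prio | pus.locked_in)
    southern = landscape._zone_mask("southern_blocks")
    south_area = area_of(southern, landscape.grid.cell_area)
    summary = {
        "scenario": scenario,
        "scale": scheme.scale,
        "pct_species_met": report["pct_species_met"],
        "pct_ecosystems_met": report["pct_ecosystems_met"],
        "pct_all_met": report["pct_all_met"],
        "pct_unmet": 100.0 - report["pct_all_met"],
        "n_priority_pus": int(prio.sum()),
        "priority_extent_km2": float(pus.area[prio].sum()),
        "pct_southern_blocks_in_priority": (
            percent_cover(area_of(prio_cells & southern, landscape.grid.cell_area),
                          south_area) if south_area > 0 else 0.0),
    }
    with open(sdir / "achievement.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    jlog.event("scenario_done", **summary)
    return summary


def run(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Execute every configured scenario plus the descriptive overlays."""
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO)
    jlog = _JsonlLog(out / "run.jsonl")
    t0 = time.time()

    landscape = _load_landscape(cfg)
    jlog.event("landscape", n_species=len(landscape.sdm_surfaces),
               n_ecosystems=len(landscape.ecosystem_ids()),
               study_km2=area_of(landscape.study_mask, landscape.grid.cell_area))

    # descriptive overlap accounting
    table1(landscape).to_csv(out / "table1.csv", index=False)
    table2(landscape).to_csv(out / "table2.csv", index=False)
    eco_cov = ecosystem_coverage(landscape)
    eco_cov.to_csv(out / "ecosystem_coverage.csv", index=False)
    jlog.event("overlaps", **ecosystem_summary(eco_cov))

    # richness stacking and the multi-group richness center
    pres = presence_rasters(landscape, threshold=cfg.binarize_threshold)
    groups = sorted(set(landscape.species_groups.values()))
    masks = {}
    summary_rows = []
    for grp in groups:
        sub = {s: pres[s] for s, gg in landscape.species_groups.items() if gg == grp}
        rmap = stack_richness(sub, landscape.study_mask, landscape.grid, group=grp)
        write_ascii_grid(out / f"richness_{grp}.asc", rmap.values.astype(float),
                         landscape.grid)
        masks[grp] = upper_tertile_mask(rmap)
        summary_rows.append({
            "group": grp, "n_species": len(sub),
            "tertile_cut": tertile_cut(rmap),
            "tertile_extent_km2": area_of(masks[grp], landscape.grid.cell_area),
        })
    center = richness_center(masks, landscape.grid, expected_groups=groups)
    compromised = landscape.all_blocks_mask | landscape.deforested_mask
    pct_comp, pct_prot = center_vulnerability(center, compromised,
                                              landscape.protected_zones_mask)
    pd.DataFrame(summary_rows).to_csv(out / "richness_summary.csv", index=False)
    write_ascii_grid(out / "richness_center.asc", center.mask.astype(float),
                     landscape.grid)
    jlog.event("richness_center", extent_km2=center.extent_km2,
               pct_compromised=pct_comp, pct_protected=pct_prot)

    scenario_summaries = [
        run_scenario(landscape, cfg, s, out, jlog) for s in cfg.scenarios
    ]

    # oil-block importance feeds off scenario-3 priority areas
    if 3 in cfg.scenarios:
        pus = tessellate(landscape, cfg.pu_area)
        prio_mask, _, _ = _read_priority(out / "scenario_3" / "full_targets", landscape)
        all_rmap = stack_richness(pres, landscape.study_mask, landscape.grid)
        prio_species = {s for s, p in landscape.priority_species.items() if p}
        if prio_species:
            prio_rmap = stack_richness({s: pres[s] for s in prio_species},
                                       landscape.study_mask, landscape.grid,
                                       group="priority")
        else:
            prio_rmap = stack_richness(pres, landscape.study_mask, landscape.grid)
        metrics = block_metrics(landscape, all_rmap, prio_rmap, prio_mask, pus)
        if len(metrics) >= 4:
            importance_index(metrics).to_csv(out / "block_importance.csv", index=False)

    manifest = {
        "package": "reserva",
        "version": __version__,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "scenarios": scenario_summaries,
        "richness_center": {"extent_km2": center.extent_km2,
                            "pct_compromised": pct_comp, "pct_protected": pct_prot},
        "elapsed_s": round(time.time() - t0, 2),
        "libraries": _library_versions(),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()).hexdigest()[:16]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out


def _read_priority(sdir: Path, landscape: Landscape) -> tuple[np.ndarray, None, None]:
    from .io import read_ascii_grid
    vals, _, _ = read_ascii_grid(sdir / "priority_mask.asc")
    return vals > 0.5, None, None


def _library_versions() -> dict:
    import scipy
    import shapely
    vers = {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "shapely": shapely.__version__}
    return vers


def rerun_with_half_targets(cfg: RunConfig, out_dir: str | Path,
                            scenarios: tuple[int, ...] | None = None) -> pd.DataFrame:
    """Re-run scenarios with the target scheme halved and compare achievement.

    Returns a per-scenario comparison table; per-feature achieved amounts
    under half targets are never lower requirements than the full run, so
    the met share can only stay or rise.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    jlog = _JsonlLog(out / "half_targets.jsonl")
    landscape = _load_landscape(cfg)
    half = cfg.scheme.halved()
    rows = []
    for s in (scenarios or cfg.scenarios):
        full_summary_path = out / f"scenario_{s}" / "full_targets" / "achievement.json"
        if full_summary_path.exists():
            with open(full_summary_path) as fh:
                full_summary = json.load(fh)
        else:
            full_summary = run_scenario(landscape, cfg, s, out, jlog)
        half_summary = run_scenario(landscape, cfg, s, out, jlog, scheme=half)
        rows.append({
            "scenario": s,
            "scale_full": cfg.scheme.scale, "scale_half": half.scale,
            "pct_all_met_full": full_summary["pct_all_met"],
            "pct_all_met_half": half_summary["pct_all_met"],
        })
    cmp_df = pd.DataFrame(rows)
    cmp_df.to_csv(out / "half_target_comparison.csv", index=False)
    return cmp_df
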