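"""Shared fixtures: tiny hand-built landscapes and random selection instances."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from reserva.landscape import (FeatureAmountMatrix, GridSpec, Landscape,
                               PlanningUnitSet, PUStatus)
from reserva.selector import SelectionProblem
from reserva.synthetic import make_paper_mimic


def make_random_problem(seed: int, n_pu: int = 15, n_feat: int = 8,
                        spf: float = 1e4, n_locked_in: int = 0,
                        n_locked_out: int = 0) -> SelectionProblem:
    """Small random minimum-set instance on a 1×n strip of unit cells."""
    rng = np.random.default_rng(seed)
    grid = GridSpec(1, n_pu, 1.0)
    status = np.full(n_pu, PUStatus.AVAILABLE, dtype=np.int8)
    ids = rng.permutation(n_pu)
    status[ids[:n_locked_in]] = PUStatus.LOCKED_IN
    status[ids[n_locked_in:n_locked_in + n_locked_out]] = PUStatus.LOCKED_OUT
    pus = PlanningUnitSet(
        grid=grid, pu_index=np.arange(n_pu).reshape(1, -1),
        area=np.ones(n_pu), cost=rng.uniform(0.5, 2.0, n_pu),
        status=status,
        adjacency={(i, i + 1): 1.0 for i in range(n_pu - 1)},
    )
    amt = rng.random((n_feat, n_pu)) * (rng.random((n_feat, n_pu)) < 0.4) + 1e-6
    fam = FeatureAmountMatrix(
        feature_ids=[f"f{i}" for i in range(n_feat)],
        kind=np.array(["species"] * n_feat),
        amount=amt, total_extent=amt.sum(axis=1),
        protected_amount=amt[:, status == PUStatus.LOCKED_IN].sum(axis=1),
    )
    targets = pd.DataFrame({
        "feature_id": fam.feature_ids, "kind": fam.kind,
        "target_km2": rng.uniform(0.2, 0.6) * fam.total_extent,
    })
    return SelectionProblem(pus=pus, amounts=fam, targets=targets,
                            spf=np.full(n_feat, spf))


@pytest.fixture(scope="session")
def mimic_landscape() -> Landscape:
    return make_paper_mimic(seed=2)


@pytest.fixture
def toy_landscape() -> Landscape:
    """10×10 unit-cell landscape with two species, two ecosystems, and one
    block/reserve pair for overlap arithmetic."""
    grid = GridSpec(10, 10, 1.0)
    mask = np.ones((10, 10), dtype=bool)
    eco = np.ones((10, 10), dtype=np.int32)
    eco[5:, :] = 2
    sdm_a = np.zeros((10, 10))
    sdm_a[0:2, 0:5] = 1.0  # 10 presence cells
    sdm_b = np.zeros((10, 10))
    sdm_b[6:9, 6:9] = 0.9
    pa = np.zeros((10, 10), dtype=np.int32)
    pa[6:10, 5:10] = 1
    op = np.zeros((10, 10), dtype=np.int32)
    op[0:4, 0:6] = 1
    so = np.zeros((10, 10), dtype=np.int32)
    so[8:10, 0:4] = 1
    return Landscape(
        grid=grid, study_mask=mask,
        sdm_surfaces={"sp_a": sdm_a, "sp_b": sdm_b},
        species_groups={"sp_a": "bird", "sp_b": "plant"},
        priority_species={"sp_a": True, "sp_b": False},
        ecosystems=eco, protected_areas=pa,
        operative_blocks=op, southern_blocks=so,
        deforested=np.zeros((10, 10), dtype=bool),
        zone_labels={"protected_areas": {1: "Toy Reserve"}},
    )
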