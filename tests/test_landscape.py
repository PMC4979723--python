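"""Planning-unit tessellation, scenario lock rules and feature amounts."""

import numpy as np
import pytest

from reserva.landscape import (GridSpec, Landscape, PUStatus, apply_lock_rules,
                               build_feature_matrix, tessellate)


def _bare(mask, **layers):
    grid = GridSpec(*mask.shape, 1.0)
    return Landscape(grid=grid, study_mask=mask, **layers)


class TestTessellate:
    def test_exact_tiling(self):
        ls = _bare(np.ones((10, 10), dtype=bool))
        pus = tessellate(ls, 4.0)
        assert pus.n_pus == 25
        assert np.allclose(pus.area, 4.0)

    def test_corner_clipping(self):
        mask = np.ones((10, 10), dtype=bool)
        mask[0, 0] = mask[0, 1] = mask[1, 0] = False  # 3 cells of one 2x2 PU
        pus = tessellate(_bare(mask), 4.0)
        assert pus.n_pus == 25
        assert sorted(pus.area)[:1] == [1.0]
        assert pus.area.sum() == mask.sum()

    def test_irregular_mask_matches_block_enumeration(self):
        # oracle: directly enumerate 2x2 blocks intersecting the mask
        rng = np.random.default_rng(7)
        mask = rng.random((60, 60)) < 0.6
        mask[0, 0] = True
        pus = tessellate(_bare(mask), 3.45)
        b = 2  # ceil(sqrt(3.45)) = 2
        expected = sum(
            mask[r:r + b, c:c + b].any()
            for r in range(0, 60, b) for c in range(0, 60, b)
        )
        assert pus.n_pus == expected

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_area_conservation(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((31, 17)) < 0.5
        mask[3, 3] = True
        pus = tessellate(_bare(mask), 9.0)
        assert pus.area.sum() == pytest.approx(mask.sum() * 1.0)
        # every masked cell belongs to exactly one PU
        assert ((pus.pu_index >= 0) == mask).all()

    def test_adjacency_is_rook_shared_edges(self):
        pus = tessellate(_bare(np.ones((4, 4), dtype=bool)), 4.0)
        # 2x2 grid of 2x2-cell PUs: 4 neighbouring pairs, each sharing 2 edges
        assert len(pus.adjacency) == 4
        assert all(v == pytest.approx(2.0) for v in pus.adjacency.values())

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="no planning units"):
            tessellate(_bare(np.zeros((5, 5), dtype=bool)), 4.0)

    def test_pu_smaller_than_cell_errors(self):
        with pytest.raises(ValueError):
            tessellate(_bare(np.ones((5, 5), dtype=bool)), 0.5)


class TestLockRules:
    @pytest.fixture
    def zoned(self):
        mask = np.ones((10, 10), dtype=bool)
        so = np.zeros((10, 10), dtype=np.int32)
        so[0:2, 0:2] = 1  # one full PU
        op = np.zeros((10, 10), dtype=np.int32)
        op[4:6, 4:6] = 1
        pa = np.zeros((10, 10), dtype=np.int32)
        pa[4:6, 4:6] = 1  # reserve exactly atop the operative block
        ls = _bare(mask, southern_blocks=so, operative_blocks=op, protected_areas=pa)
        return ls, tessellate(ls, 4.0)

    def test_southern_block_locked_out_in_scenario_1(self, zoned):
        ls, pus = zoned
        out = apply_lock_rules(pus, ls, scenario=1)
        pu = out.pu_index[0, 0]
        assert out.status[pu] == PUStatus.LOCKED_OUT

    def test_southern_block_available_in_scenario_2(self, zoned):
        ls, pus = zoned
        out = apply_lock_rules(pus, ls, scenario=2)
        pu = out.pu_index[0, 0]
        assert out.status[pu] == PUStatus.AVAILABLE

    @pytest.mark.parametrize("scenario", [1, 2, 3])
    def test_reserve_over_operative_block_stays_locked_in(self, zoned, scenario):
        ls, pus = zoned
        out = apply_lock_rules(pus, ls, scenario=scenario)
        pu = out.pu_index[4, 4]
        assert out.status[pu] == PUStatus.LOCKED_IN

    def test_locked_out_precedence_override(self, zoned):
        ls, pus = zoned
        out = apply_lock_rules(pus, ls, scenario=1,
                               precedence=("locked_out", "locked_in"))
        pu = out.pu_index[4, 4]
        assert out.status[pu] == PUStatus.LOCKED_OUT

    def test_high_impact_cells_locked_out_every_scenario(self, zoned):
        ls, pus = zoned
        ers_mask = np.zeros((10, 10), dtype=bool)
        ers_mask[8:10, 8:10] = True
        for scenario in (1, 2, 3):
            out = apply_lock_rules(pus, ls, scenario, ers_mask=ers_mask)
            assert out.status[out.pu_index[8, 8]] == PUStatus.LOCKED_OUT

    def test_lock_states_partition(self, zoned):
        ls, pus = zoned
        out = apply_lock_rules(pus, ls, scenario=1)
        assert not (out.locked_in & out.locked_out).any()

    def test_unknown_scenario_errors(self, zoned):
        ls, pus = zoned
        with pytest.raises(ValueError, match="scenario"):
            apply_lock_rules(pus, ls, scenario=4)


class TestFeatureMatrix:
    def test_presence_cell_counting(self, toy_landscape):
        pus = tessellate(toy_landscape, 4.0)
        fam = build_feature_matrix(toy_landscape, pus)
        assert fam.total_extent[fam.index_of("sp_a")] == pytest.approx(10.0)

    def test_ecosystems_partition_study_area(self, toy_landscape):
        pus = tessellate(toy_landscape, 4.0)
        fam = build_feature_matrix(toy_landscape, pus)
        eco = fam.kind == "ecosystem"
        assert fam.total_extent[eco].sum() == pytest.approx(100.0)

    def test_amount_conservation(self, toy_landscape):
        pus = tessellate(toy_landscape, 4.0)
        fam = build_feature_matrix(toy_landscape, pus)
        np.testing.assert_allclose(fam.amount.sum(axis=1), fam.total_extent)

    def test_fully_protected_feature(self, toy_landscape):
        pus = tessellate(toy_landscape, 4.0)
        pus = apply_lock_rules(pus, toy_landscape, scenario=3)
        fam = build_feature_matrix(toy_landscape, pus)
        i = fam.index_of("sp_b")  # sp_b lives inside the reserve
        assert fam.protected_amount[i] == pytest.approx(fam.total_extent[i])

    def test_no_locked_in_means_zero_protected(self, toy_landscape):
        pus = tessellate(toy_landscape, 4.0)
        fam = build_feature_matrix(toy_landscape, pus)
        assert (fam.protected_amount == 0).all()

    def test_zero_extent_feature_errors(self, toy_landscape):
        toy_landscape.sdm_surfaces["ghost"] = np.zeros((10, 10))
        toy_landscape.species_groups["ghost"] = "bird"
        pus = tessellate(toy_landscape, 4.0)
        with pytest.raises(ValueError, match="ghost"):
            build_feature_matrix(toy_landscape, pus)

    def test_continuous_mode_sums_suitability(self, toy_landscape):
        pus = tessellate(toy_landscape, 4.0)
        fam = build_feature_matrix(toy_landscape, pus, continuous=True)
        i = fam.index_of("sp_b")
        assert fam.total_extent[i] == pytest.approx(0.9 * 9)
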