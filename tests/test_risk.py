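"""Environmental risk surface: footprints, composition, cost."""

import numpy as np
import pytest

from reserva.landscape import GridSpec, Landscape, ThreatLayer, tessellate
from reserva.risk import (ERS, ThreatSpec, compose_ers, high_impact_mask,
                          pu_cost, threat_footprint)


def flat_landscape(n=11):
    return Landscape(grid=GridSpec(n, n, 1.0), study_mask=np.ones((n, n), bool))


class TestFootprint:
    def test_linear_kernel_point_source(self):
        ls = flat_landscape()
        layer = ThreatLayer(kind="points", points=np.array([[5, 5]]))
        spec = ThreatSpec("wells", decay_radius_km=3.0, kernel="linear")
        fp = threat_footprint(ls, layer, spec)
        assert fp[5, 5] == pytest.approx(1.0)
        assert fp[5, 7] == pytest.approx(1 - 2 / 3)
        assert fp[5, 9] == 0.0  # beyond the radius

    def test_no_sources_gives_zero(self):
        ls = flat_landscape()
        fp = threat_footprint(ls, ThreatLayer(kind="points",
                                              points=np.empty((0, 2), int)),
                              ThreatSpec("wells", decay_radius_km=2.0))
        assert not fp.any()

    def test_two_points_equal_cellwise_max(self):
        ls = flat_landscape()
        spec = ThreatSpec("wells", decay_radius_km=4.0)
        a = threat_footprint(ls, ThreatLayer("points", points=np.array([[2, 2]])), spec)
        b = threat_footprint(ls, ThreatLayer("points", points=np.array([[8, 8]])), spec)
        both = threat_footprint(
            ls, ThreatLayer("points", points=np.array([[2, 2], [8, 8]])), spec)
        np.testing.assert_allclose(both, np.maximum(a, b))

    def test_field_passes_through_normalized(self):
        ls = flat_landscape()
        f = np.linspace(0, 4, 121).reshape(11, 11)
        fp = threat_footprint(ls, ThreatLayer("field", field=f),
                              ThreatSpec("population"))
        assert fp.max() == pytest.approx(1.0)
        np.testing.assert_allclose(fp, f / 4)

    def test_exponential_kernel_zero_beyond_radius(self):
        ls = flat_landscape()
        spec = ThreatSpec("dams", decay_radius_km=2.0, kernel="exponential")
        fp = threat_footprint(ls, ThreatLayer("points", points=np.array([[5, 5]])), spec)
        assert fp[5, 5] == pytest.approx(1.0)
        assert fp[5, 7] == pytest.approx(np.exp(-1))
        assert fp[5, 9] == 0.0


class TestComposeERS:
    def test_zero_threats_give_zero_surface(self):
        specs = {"a": ThreatSpec("a"), "b": ThreatSpec("b")}
        fps = {"a": np.zeros((4, 4)), "b": np.zeros((4, 4))}
        assert not compose_ers(fps, specs).values.any()

    def test_all_threats_maxed_give_100(self):
        specs = {"a": ThreatSpec("a", weight=2.0), "b": ThreatSpec("b", weight=1.0)}
        fps = {"a": np.ones((4, 4)), "b": np.ones((4, 4))}
        assert compose_ers(fps, specs).values.max() == pytest.approx(100.0)

    def test_matches_weighted_sum_oracle(self):
        rng = np.random.default_rng(2)
        specs = {n: ThreatSpec(n, weight=w)
                 for n, w in (("a", 0.5), ("b", 1.5), ("c", 2.0))}
        fps = {n: rng.random((6, 6)) for n in specs}
        ers = compose_ers(fps, specs)
        expected = 100 * (0.5 * fps["a"] + 1.5 * fps["b"] + 2.0 * fps["c"]) / 4.0
        np.testing.assert_allclose(ers.values, expected)

    def test_bounded_0_100(self):
        rng = np.random.default_rng(4)
        specs = {"a": ThreatSpec("a", weight=3.0)}
        ers = compose_ers({"a": rng.random((8, 8))}, specs)
        assert ers.values.min() >= 0 and ers.values.max() <= 100

    def test_monotone_in_weight(self):
        rng = np.random.default_rng(5)
        fps = {"a": rng.random((6, 6)), "b": rng.random((6, 6))}
        lo = compose_ers(fps, {"a": ThreatSpec("a", 1.0), "b": ThreatSpec("b", 1.0)})
        hi = compose_ers(fps, {"a": ThreatSpec("a", 1.0), "b": ThreatSpec("b", 2.0)})
        better = fps["b"] >= fps["a"]  # raising b's weight helps where b dominates
        assert (hi.values[better] >= lo.values[better] - 1e-9).all()

    def test_all_zero_weights_error(self):
        with pytest.raises(ValueError):
            compose_ers({"a": np.ones((2, 2))}, {"a": ThreatSpec("a", weight=0.0)})


class TestThresholdAndCost:
    def test_value_at_threshold_not_masked(self):
        ers = ERS(values=np.array([[32.0, 33.0], [0.0, 100.0]]), threshold=32)
        m = high_impact_mask(ers)
        assert not m[0, 0] and m[0, 1] and m[1, 1] and not m[1, 0]

    def test_zero_threshold_masks_positive_cells(self):
        ers = ERS(values=np.array([[0.0, 1.0], [50.0, 0.0]]), threshold=0)
        assert high_impact_mask(ers).sum() == 2

    def test_uniform_surface_gives_uniform_cost(self):
        ls = flat_landscape(8)
        pus = tessellate(ls, 4.0)
        ers = ERS(values=np.full((8, 8), 7.5))
        np.testing.assert_allclose(pu_cost(ers, pus), 7.5)

    def test_epsilon_floor_on_pristine_pu(self):
        ls = flat_landscape(8)
        pus = tessellate(ls, 4.0)
        ers = ERS(values=np.zeros((8, 8)))
        costs = pu_cost(ers, pus)
        np.testing.assert_allclose(costs, 0.01)

    def test_matches_per_pu_mean_oracle(self):
        ls = flat_landscape(8)
        pus = tessellate(ls, 4.0)
        rng = np.random.default_rng(6)
        vals = rng.random((8, 8)) * 80
        costs = pu_cost(ERS(values=vals), pus)
        for pu in range(pus.n_pus):
            rows, cols = pus.cells_of(pu)
            assert costs[pu] == pytest.approx(max(vals[rows, cols].mean(), 0.01))
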