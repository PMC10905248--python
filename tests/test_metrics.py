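import numpy as np
import pytest
from shapely.geometry import box

from nicheshift.grid import RasterGrid
from nicheshift.maxent import SuitabilityMap
from nicheshift.niche_metrics import (
    ProbabilitySurface,
    combined_change,
    habitat_change,
    intersect_ranges,
    normalize_surface,
    schoener_d,
    vulnerability_report,
    warren_i,
)
from nicheshift.rasters import RangeArea

from conftest import random_probability_pair


def surface(values):
    values = np.atleast_2d(np.asarray(values, float))
    grid = RasterGrid(*values.shape, 1.0)
    return ProbabilitySurface(grid, values)


def d_oracle(px, py):
    mask = np.isfinite(px)
    total = 0.0
    for a, b in zip(px[mask].ravel(), py[mask].ravel()):
        total += abs(a - b)
    return 1.0 - 0.5 * total


def i_oracle(px, py):
    mask = np.isfinite(px)
    total = 0.0
    for a, b in zip(px[mask].ravel(), py[mask].ravel()):
        total += (np.sqrt(a) - np.sqrt(b)) ** 2
    return 1.0 - 0.5 * total


class TestNormalizeSurface:
    def test_uniform_map(self, grid10):
        m = SuitabilityMap(grid10, np.full(grid10.shape, 0.37), "cloglog")
        p = normalize_surface(m)
        np.testing.assert_allclose(p.p, 0.01)

    def test_already_normalized_unchanged(self, grid10):
        vals = np.random.default_rng(0).random(grid10.shape)
        vals /= vals.sum()
        m = SuitabilityMap(grid10, vals, "raw")
        np.testing.assert_allclose(normalize_surface(m).p, vals, atol=1e-15)

    def test_two_cell_arithmetic(self):
        grid = RasterGrid(1, 2, 1.0)
        m = SuitabilityMap(grid, np.array([[2.0, 6.0]]), "cloglog")
        np.testing.assert_allclose(normalize_surface(m).p, [[0.25, 0.75]])

    def test_all_zero_rejected(self, grid10):
        m = SuitabilityMap(grid10, np.zeros(grid10.shape), "cloglog")
        with pytest.raises(ValueError, match="all-zero"):
            normalize_surface(m)

    def test_shared_mask_restricts_support(self, grid10):
        vals = np.ones(grid10.shape)
        m = SuitabilityMap(grid10, vals, "cloglog")
        shared = np.zeros(grid10.shape, bool)
        shared[:5] = True
        p = normalize_surface(m, shared)
        assert np.nansum(p.p) == pytest.approx(1.0)
        assert np.isnan(p.p[6, 0])


class TestOverlapMetrics:
    def test_identical_surfaces_give_one(self):
        p = surface([[0.25, 0.75]])
        assert schoener_d(p, p) == 1.0
        assert warren_i(p, p) == 1.0

    def test_disjoint_supports_give_zero(self):
        px, py = surface([[1.0, 0.0]]), surface([[0.0, 1.0]])
        assert schoener_d(px, py) == 0.0
        assert warren_i(px, py) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_examples(self):
        px, py = surface([[0.7, 0.3]]), surface([[0.5, 0.5]])
        assert schoener_d(px, py) == pytest.approx(0.8)
        expected_i = 1 - 0.5 * ((np.sqrt(0.7) - np.sqrt(0.5)) ** 2
                                + (np.sqrt(0.3) - np.sqrt(0.5)) ** 2)
        assert warren_i(px, py) == pytest.approx(expected_i, abs=1e-12)
        assert warren_i(px, py) == pytest.approx(0.97891, abs=1e-5)

    def test_matches_bruteforce_and_i_dominates_d(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            grid, mask, px, py = random_probability_pair(rng, max_side=25)
            sx, sy = ProbabilitySurface(grid, px), ProbabilitySurface(grid, py)
            d, i = schoener_d(sx, sy), warren_i(sx, sy)
            assert d == pytest.approx(d_oracle(px, py), abs=1e-12)
            assert i == pytest.approx(i_oracle(px, py), abs=1e-12)
            assert 0.0 <= d <= 1.0 and 0.0 <= i <= 1.0
            assert i >= d - 1e-12

    def test_invariant_to_positive_scaling_before_normalization(self, grid10):
        rng = np.random.default_rng(7)
        a, b = rng.random(grid10.shape), rng.random(grid10.shape)
        ma = SuitabilityMap(grid10, a, "cloglog")
        mb = SuitabilityMap(grid10, b, "cloglog")
        ma_scaled = SuitabilityMap(grid10, 37.5 * a, "cloglog")
        d1 = schoener_d(normalize_surface(ma), normalize_surface(mb))
        d2 = schoener_d(normalize_surface(ma_scaled), normalize_surface(mb))
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        px = surface([[0.5, 0.5]])
        py = ProbabilitySurface(RasterGrid(2, 1, 1.0), np.array([[0.5], [0.5]]))
        with pytest.raises(ValueError, match="different grids"):
            schoener_d(px, py)


class TestIntersectRanges:
    def test_identical_polygons(self):
        ra = RangeArea("a", box(0, 0, 2, 1))
        inter = intersect_ranges(ra, RangeArea("b", box(0, 0, 2, 1)))
        assert inter.area == pytest.approx(2.0)

    def test_disjoint_polygons_warn_and_return_empty(self):
        ra = RangeArea("a", box(0, 0, 1, 1))
        rb = RangeArea("b", box(5, 5, 6, 6))
        with pytest.warns(UserWarning, match="do not overlap"):
            inter = intersect_ranges(ra, rb)
        assert inter.is_empty

    def test_offset_unit_squares(self):
        ra = RangeArea("a", box(0, 0, 1, 1))
        rb = RangeArea("b", box(0.5, 0.5, 1.5, 1.5))
        assert intersect_ranges(ra, rb).area == pytest.approx(0.25)


class TestChangeFormulas:
    def test_habitat_change_examples(self):
        assert habitat_change(110.0, 100.0) == pytest.approx(10.0)
        assert habitat_change(55.5, 55.5) == 0.0
        assert habitat_change(99.2, 20.0) == pytest.approx(396.0)

    def test_negative_is_loss(self):
        assert habitat_change(90.0, 100.0) == pytest.approx(-10.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            habitat_change(1.0, 0.0)

    def test_combined_change_examples(self):
        assert combined_change(6.0, 6.0, 5.0, 5.0) == pytest.approx(20.0)
        assert combined_change(3.0, 4.0, 3.0, 4.0) == 0.0
        # +10% and -10% with equal reference H cancel exactly
        assert combined_change(11.0, 9.0, 10.0, 10.0) == pytest.approx(0.0)

    def test_combined_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            combined_change(1.0, 1.0, 0.0, 0.0)

    def test_scale_covariance(self):
        rng = np.random.default_rng(9)
        h_new, h_ref = rng.random(2) + 0.5
        assert habitat_change(2 * h_new, 2 * h_ref) == pytest.approx(
            habitat_change(h_new, h_ref), abs=1e-12
        )


class TestVulnerabilityReport:
    def _current(self, grid):
        rng = np.random.default_rng(11)
        return {
            "sp_a": SuitabilityMap(grid, rng.random(grid.shape), "cloglog"),
            "sp_b": SuitabilityMap(grid, rng.random(grid.shape), "cloglog"),
        }

    def test_identity_scenarios_give_zero(self, grid10):
        current = self._current(grid10)
        scen = {"same": {k: SuitabilityMap(grid10, v.values, "cloglog")
                         for k, v in current.items()}}
        rep = vulnerability_report(current, scen, np.ones(grid10.shape, bool))
        assert (rep.changes["same"] == 0.0).all()

    def test_ten_percent_scaling_gives_plus_ten(self, grid10):
        current = self._current(grid10)
        scen = {"f": {k: SuitabilityMap(grid10, 1.10 * v.values, "cloglog")
                      for k, v in current.items()}}
        rep = vulnerability_report(current, scen, np.ones(grid10.shape, bool))
        assert rep.changes.loc["sp_a", "f"] == pytest.approx(10.0)
        assert rep.changes.loc["sp_b", "f"] == pytest.approx(10.0)
        assert rep.changes.loc["Overlap area", "f"] == pytest.approx(10.0)

    def test_past_label_reverses_direction(self, grid10):
        current = self._current(grid10)
        scen = {"paleo": {k: SuitabilityMap(grid10, 0.5 * v.values, "cloglog")
                          for k, v in current.items()}}
        rep = vulnerability_report(current, scen, np.ones(grid10.shape, bool),
                                   past_labels={"paleo"})
        # habitat doubled from past to current: +100%
        assert rep.changes.loc["sp_a", "paleo"] == pytest.approx(100.0)

    def test_percent_entries_reproducible_from_stored_h(self, grid10):
        current = self._current(grid10)
        scen = {"f": {k: SuitabilityMap(grid10, 1.3 * v.values, "cloglog")
                      for k, v in current.items()}}
        rep = vulnerability_report(current, scen, np.ones(grid10.shape, bool))
        h = rep.h_values
        recomputed = habitat_change(h["f"]["sp_a"], h["current"]["sp_a"])
        assert rep.changes.loc["sp_a", "f"] == pytest.approx(recomputed, abs=5e-3)

    def test_scale_mismatch_rejected(self, grid10):
        current = self._current(grid10)
        bad = {"f": {k: SuitabilityMap(grid10, v.values / v.values.sum(), "raw")
                     for k, v in current.items()}}
        with pytest.raises(ValueError, match="scale mismatch"):
            vulnerability_report(current, bad, np.ones(grid10.shape, bool))
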