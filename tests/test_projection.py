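"""Projection, ensembles, suitability classification and area accounting."""

import math

import numpy as np
import pandas as pd
import pytest

from maxsdm.model import train
from maxsdm.projection import (
    EARTH_RADIUS_KM,
    change_table,
    class_areas,
    classify_suitability,
    ensemble_mean,
    project_map,
)
from .conftest import make_grid


@pytest.fixture(scope="module")
def fitted(small_presence, small_background):
    return train(small_presence, small_background, classes="LH", rm=1.0, n_knots=5)


class TestProjectMap:
    def test_reproduces_training_cell_predictions(
        self, fitted, small_stack, small_landscape
    ):
        from maxsdm.features import transform_features
        from maxsdm.model import predict_cloglog

        surface = project_map(fitted, small_stack)
        direct = predict_cloglog(
            fitted, transform_features(small_landscape, fitted.defs)
        )
        projected = surface.values.ravel()[small_landscape.cell_indices]
        np.testing.assert_allclose(projected, direct)

    def test_uniform_model_constant_map(self, small_stack, small_presence, small_background):
        uniform = train(small_presence, small_background, classes="L", rm=1e9, n_knots=3)
        surface = project_map(uniform, small_stack)
        np.testing.assert_allclose(
            surface.values[surface.valid_mask], 1 - math.exp(-1)
        )

    def test_all_nodata_stack(self, fitted):
        from maxsdm.raster import RasterStack

        empty = RasterStack(
            {
                v: make_grid(np.full((3, 3), -9999.0))
                for v in fitted.defs.variables
            }
        )
        surface = project_map(fitted, empty)
        assert surface.valid_mask.sum() == 0

    def test_missing_layer_named(self, fitted, small_stack):
        partial = small_stack.subset(fitted.defs.variables[1:])
        with pytest.raises(KeyError, match=fitted.defs.variables[0]):
            project_map(fitted, partial)


class TestEnsemble:
    def test_single_map_identity(self):
        g = make_grid([[0.1, 0.9]])
        np.testing.assert_array_equal(ensemble_mean([g]).values, g.values)

    def test_mean_of_two_constants(self):
        a, b = make_grid(np.full((2, 2), 0.2)), make_grid(np.full((2, 2), 0.4))
        np.testing.assert_allclose(ensemble_mean([a, b]).values, 0.3)

    def test_idempotent_on_identical_maps(self):
        g = make_grid(np.random.default_rng(0).uniform(size=(4, 4)))
        np.testing.assert_allclose(ensemble_mean([g, g, g]).values, g.values)

    def test_nodata_if_any_input_nodata(self):
        a = make_grid([[0.2, -9999.0]])
        b = make_grid([[0.4, 0.4]])
        out = ensemble_mean([a, b])
        assert out.values[0, 1] == -9999.0 and out.values[0, 0] == pytest.approx(0.3)

    def test_bounded_by_inputs(self):
        rng = np.random.default_rng(1)
        maps = [make_grid(rng.uniform(size=(5, 5))) for _ in range(4)]
        out = ensemble_mean(maps).values
        lo = np.min([m.values for m in maps], axis=0)
        hi = np.max([m.values for m in maps], axis=0)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ensemble_mean([])


class TestClassification:
    def test_printed_break_vector(self):
        """t = 0.1945 gives the published class bounds after 3-decimal
        rounding: 0.195, 0.389, 0.584, 0.778."""
        cm = classify_suitability(make_grid([[0.5]]), t=0.1945)
        assert [round(b, 3) for b in cm.breaks] == [0.195, 0.389, 0.584, 0.778]

    def test_high_class_assignment(self):
        cm = classify_suitability(make_grid([[0.95, 0.0, 0.5, 0.2]]), t=0.1945)
        assert cm.grid.values[0].tolist() == [4.0, 0.0, 2.0, 1.0]

    def test_band_edges_inclusive_below(self):
        # v exactly at a break belongs to the upper class (binary-exact t)
        cm = classify_suitability(make_grid([[0.125, 0.25, 0.375, 0.5]]), t=0.125)
        assert cm.grid.values[0].tolist() == [1.0, 2.0, 3.0, 4.0]

    def test_threshold_bounds_enforced(self):
        with pytest.raises(ValueError):
            classify_suitability(make_grid([[0.5]]), t=0.25)
        with pytest.raises(ValueError):
            classify_suitability(make_grid([[0.5]]), t=0.0)

    def test_nodata_passes_through(self):
        cm = classify_suitability(make_grid([[0.5, -9999.0]]), t=0.1)
        assert cm.grid.values[0, 1] == -9999.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        g = make_grid(rng.uniform(size=(10, 10)))
        c1 = classify_suitability(g, t=0.1).grid.values
        c2 = classify_suitability(g, t=0.2).grid.values
        assert np.all(c2 <= c1)

    def test_explicit_breaks(self):
        cm = classify_suitability(make_grid([[0.5]]), breaks=(0.1, 0.3, 0.6, 0.9))
        assert cm.grid.values[0, 0] == 2.0


class TestAreas:
    def test_one_degree_cell_at_equator(self):
        """1 deg x 1 deg spanning latitude 0-1: ~12364 km^2."""
        g = make_grid([[0.5]], xll=0.0, yll=0.0, cellsize=1.0)
        areas = class_areas(classify_suitability(g, t=0.1))
        expected = (
            EARTH_RADIUS_KM**2 * math.radians(1.0) * (math.sin(math.radians(1.0)) - 0)
        )
        assert areas["total"] == pytest.approx(expected, abs=1.0)
        assert round(expected) == 12364

    def test_whole_sphere_closure(self):
        """Summing cell areas over the globe recovers 4 pi R^2 within 0.1%."""
        g = make_grid(np.full((180, 360), 0.5), xll=-180.0, yll=-90.0, cellsize=1.0)
        areas = class_areas(classify_suitability(g, t=0.1))
        assert areas["total"] == pytest.approx(4 * math.pi * EARTH_RADIUS_KM**2, rel=1e-3)

    def test_classes_partition_total(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(size=(30, 30))
        vals[rng.uniform(size=(30, 30)) < 0.2] = -9999.0
        g = make_grid(vals, xll=70.0, yll=8.0, cellsize=0.1)
        areas = class_areas(classify_suitability(g, t=0.1945))
        class_sum = sum(areas[k] for k in ("unsuitable", "low", "moderate", "optimum", "high"))
        assert class_sum == pytest.approx(areas["total"], rel=1e-6)

    def test_same_mask_same_total(self):
        rng = np.random.default_rng(4)
        vals1, vals2 = rng.uniform(size=(20, 20)), rng.uniform(size=(20, 20))
        mask = rng.uniform(size=(20, 20)) < 0.3
        vals1[mask] = vals2[mask] = -9999.0
        a1 = class_areas(classify_suitability(make_grid(vals1, yll=10.0), t=0.15))
        a2 = class_areas(classify_suitability(make_grid(vals2, yll=10.0), t=0.15))
        assert a1["total"] == pytest.approx(a2["total"])


class TestChangeTable:
    def series(self, **kw):
        base = dict.fromkeys(("unsuitable", "low", "moderate", "optimum", "high"), 100.0)
        base.update(kw)
        return pd.Series(base)

    def test_present_denominator(self):
        ch = change_table(self.series(high=100.0), self.series(high=80.0), "present")
        assert ch["high"] == pytest.approx(-20.0)

    def test_future_denominator(self):
        ch = change_table(self.series(high=100.0), self.series(high=80.0), "future")
        assert ch["high"] == pytest.approx(-25.0)

    def test_no_change_both_conventions(self):
        for denom in ("present", "future"):
            ch = change_table(self.series(), self.series(), denom)
            assert all(v == 0.0 for v in ch)

    def test_empty_to_nonempty_is_infinite(self):
        ch = change_table(self.series(high=0.0), self.series(high=50.0), "present")
        assert math.isinf(ch["high"]) and ch["high"] > 0

    def test_unknown_denominator_rejected(self):
        with pytest.raises(ValueError):
            change_table(self.series(), self.series(), "both")
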