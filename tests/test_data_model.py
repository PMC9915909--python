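import numpy as np
import pytest

import ecolag as e
from ecolag.data_model import write_panel_csv


def make_panel(values, missing=None, timepoints=(2010, 2015, 2020)):
    vals = np.asarray(values, dtype=float)
    return e.PanelTable(
        variable="LE",
        region_ids=[f"r{i}" for i in range(vals.shape[0])],
        timepoints=list(timepoints),
        values=vals,
        missing_mask=missing,
    )


class TestPanelCSV:
    def test_shipped_le_table_shape(self):
        le = e.load_le_table()
        assert le.n_regions == 16
        assert le.timepoints == [2010, 2015, 2020]
        assert not le.missing_mask.any()

    def test_round_trip_preserves_finite_values_exactly(self, tmp_path, rng):
        vals = rng.standard_normal((5, 3)) * 1e3
        vals[2, 1] = np.nan
        panel = make_panel(vals)
        write_panel_csv(panel, tmp_path / "p.csv")
        back = e.read_panel_csv(tmp_path / "p.csv", "LE")
        finite = ~panel.missing_mask
        assert np.array_equal(panel.values[finite], back.values[finite])
        assert np.array_equal(panel.missing_mask, back.missing_mask)
        assert back.timepoints == panel.timepoints

    def test_blank_cell_becomes_missing(self, tmp_path):
        (tmp_path / "p.csv").write_text(
            "region_id,2010,2015,2020\na,70,,74\nb,71,72,73\n")
        panel = e.read_panel_csv(tmp_path / "p.csv", "LE")
        assert panel.missing_mask[0, 1]
        assert panel.missing_mask.sum() == 1
        assert np.isfinite(panel.values[~panel.missing_mask]).all()

    def test_empty_file_errors(self, tmp_path):
        (tmp_path / "p.csv").write_text("region_id,2010\n")
        with pytest.raises(ValueError, match="empty"):
            e.read_panel_csv(tmp_path / "p.csv", "LE")

    def test_duplicate_region_id_named_in_error(self, tmp_path):
        (tmp_path / "p.csv").write_text(
            "region_id,2010\na,70\nb,71\na,72\n")
        with pytest.raises(ValueError, match="a"):
            e.read_panel_csv(tmp_path / "p.csv", "LE")

    def test_non_numeric_cell_reports_location(self, tmp_path):
        (tmp_path / "p.csv").write_text("region_id,2010\na,oops\n")
        with pytest.raises(ValueError, match="oops"):
            e.read_panel_csv(tmp_path / "p.csv", "LE")


class TestPanelInvariants:
    def test_timepoints_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            make_panel(np.zeros((2, 3)), timepoints=(2010, 2010, 2020))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            e.PanelTable("x", ["a"], [2010, 2015], np.zeros((2, 2)))


class TestGeoJSON:
    def test_grid_round_trip(self, tmp_path, grid_regions):
        e.write_regions_geojson(grid_regions, tmp_path / "r.geojson")
        back = e.read_regions_geojson(tmp_path / "r.geojson")
        assert [r.id for r in back] == [r.id for r in grid_regions]
        assert len(back) == 16
        for a, b in zip(back, grid_regions):
            assert a.geometry.equals(b.geometry)

    def test_duplicate_ids_error(self, tmp_path):
        gj = ('{"type":"FeatureCollection","features":['
              '{"type":"Feature","properties":{"id":"a"},"geometry":'
              '{"type":"Polygon","coordinates":[[[0,0],[1,0],[1,1],[0,0]]]}},'
              '{"type":"Feature","properties":{"id":"a"},"geometry":'
              '{"type":"Polygon","coordinates":[[[2,0],[3,0],[3,1],[2,0]]]}}]}')
        (tmp_path / "r.geojson").write_text(gj)
        with pytest.raises(ValueError, match="duplicate"):
            e.read_regions_geojson(tmp_path / "r.geojson")

    def test_single_triangle(self, tmp_path):
        gj = ('{"type":"FeatureCollection","features":['
              '{"type":"Feature","properties":{"id":"t"},"geometry":'
              '{"type":"Polygon","coordinates":[[[0,0],[1,0],[1,1],[0,0]]]}}]}')
        (tmp_path / "r.geojson").write_text(gj)
        regions = e.read_regions_geojson(tmp_path / "r.geojson")
        assert len(regions) == 1
        assert regions[0].geometry.geom_type == "Polygon"

    def test_missing_id_property_errors(self, tmp_path):
        gj = ('{"type":"FeatureCollection","features":['
              '{"type":"Feature","properties":{},"geometry":'
              '{"type":"Polygon","coordinates":[[[0,0],[1,0],[1,1],[0,0]]]}}]}')
        (tmp_path / "r.geojson").write_text(gj)
        with pytest.raises(ValueError, match="id"):
            e.read_regions_geojson(tmp_path / "r.geojson")

    def test_non_polygon_geometry_errors(self):
        from shapely.geometry import Point
        with pytest.raises(ValueError, match="Polygon"):
            e.Region(id="p", geometry=Point(0, 0))


class TestInterpolation:
    def test_interior_gap_linear_midpoint(self):
        panel = make_panel([[70, np.nan, 74]])
        out = e.interpolate_missing(panel)
        assert out.values[0, 1] == pytest.approx(72.0)
        assert not out.missing_mask.any()
        assert out.filled_mask[0, 1] and out.filled_mask.sum() == 1

    def test_leading_gap_backward_extrapolation(self):
        # slope (75.66-73.50)/5 projected back: matches the published
        # Wuwei row 71.34, 73.50, 75.66
        panel = make_panel([[np.nan, 73.50, 75.66]])
        out = e.interpolate_missing(panel)
        assert out.values[0, 0] == pytest.approx(71.34)

    def test_trailing_gap_forward_extrapolation(self):
        panel = make_panel([[70.0, 72.0, np.nan]])
        out = e.interpolate_missing(panel)
        assert out.values[0, 2] == pytest.approx(74.0)

    def test_fully_observed_unchanged(self, rng):
        panel = make_panel(rng.standard_normal((4, 3)))
        out = e.interpolate_missing(panel)
        assert np.array_equal(out.values, panel.values)

    def test_single_observation_constant_fill(self):
        panel = make_panel([[np.nan, 71.5, np.nan]])
        out = e.interpolate_missing(panel)
        assert np.allclose(out.values[0], 71.5)

    def test_zero_observations_names_region(self):
        panel = make_panel([[np.nan, np.nan, np.nan], [1, 2, 3]])
        with pytest.raises(ValueError, match="r0"):
            e.interpolate_missing(panel)

    def test_idempotent(self, rng):
        vals = rng.standard_normal((6, 3))
        vals[rng.random((6, 3)) < 0.3] = np.nan
        vals[:, 1] = 1.0  # ensure every region observed somewhere
        once = e.interpolate_missing(make_panel(vals))
        twice = e.interpolate_missing(once)
        assert np.array_equal(once.values, twice.values)
        assert np.array_equal(once.filled_mask, twice.filled_mask)

    def test_affine_ramp_recovered_exactly(self, rng):
        # any a + b*t series is reproduced with zero error at masked cells
        t = np.array([2010.0, 2015.0, 2020.0, 2030.0])
        a, b = 60.0, 0.37
        vals = np.tile(a + b * (t - 2010), (3, 1))
        vals[0, 0] = np.nan
        vals[1, 2] = np.nan
        vals[2, 3] = np.nan
        panel = e.PanelTable("LE", ["x", "y", "z"],
                             [2010, 2015, 2020, 2030], vals)
        out = e.interpolate_missing(panel)
        expect = a + b * (t - 2010)
        assert np.allclose(out.values, expect, atol=1e-12)


class TestTextGrid:
    def test_round_trip_with_nodata_and_transform(self, tmp_path, rng):
        vals = rng.standard_normal((4, 5))
        mask = np.zeros((4, 5), bool)
        mask[1, 2] = True
        grid = e.RasterGrid(np.where(mask, np.nan, vals), mask,
                            transform=(0.5, 0, 1, 0, 0.5, 2))
        e.write_text_grid(grid, tmp_path / "g.txt")
        back = e.read_text_grid(tmp_path / "g.txt")
        assert np.array_equal(back.nodata_mask, mask)
        assert np.array_equal(back.values[~mask], vals[~mask])
        assert back.transform == (0.5, 0, 1, 0, 0.5, 2)

    def test_missing_nodata_header_errors(self, tmp_path):
        (tmp_path / "g.txt").write_text("1 2\n3 4\n")
        with pytest.raises(ValueError, match="NODATA"):
            e.read_text_grid(tmp_path / "g.txt")
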