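import numpy as np
import pytest

from aquaretrieve.errors import ValidationError
from aquaretrieve.features import FeatureRegistry, compute_feature_stack
from aquaretrieve.masking import WaterMask, threshold_mask, compute_ndwi
from aquaretrieve.matchup import (FLAG_EDGE, FLAG_LOW_VALID, FLAG_OOB,
                                  MatchupTable, StationRecord,
                                  build_matchup_table, extract_window_stat,
                                  read_stations_csv)
from aquaretrieve.synthdata import make_stations


def brute_force_window_stat(grid, mask, r, c, window, stat):
    half = window // 2
    vals = []
    for rr in range(r - half, r + half + 1):
        for cc in range(c - half, c + half + 1):
            if 0 <= rr < grid.shape[0] and 0 <= cc < grid.shape[1]:
                if mask[rr, cc] and np.isfinite(grid[rr, cc]):
                    vals.append(grid[rr, cc])
    if not vals:
        return float("nan"), 0
    fn = np.median if stat == "median" else np.mean
    return float(fn(vals)), len(vals)


class TestExtractWindowStat:
    def test_hand_case_six_valid_median(self):
        grid = np.array([[0.1, 0.2, 0.3],
                         [0.9, 0.9, 0.25],
                         [0.15, 0.9, 0.5]])
        mask = np.array([[1, 1, 1],
                         [0, 0, 1],
                         [1, 0, 1]], dtype=bool)
        value, n_valid, flags = extract_window_stat(grid, mask, (1, 1), 3, "median")
        assert value == pytest.approx(0.225)  # median of the 6 unmasked values
        assert n_valid == 6

    def test_constant_window(self):
        grid = np.full((3, 3), 0.42)
        value, n_valid, _ = extract_window_stat(
            grid, np.ones((3, 3), bool), (1, 1), 3, "mean")
        assert value == pytest.approx(0.42) and n_valid == 9

    def test_fully_masked_window(self):
        value, n_valid, flags = extract_window_stat(
            np.ones((5, 5)), np.zeros((5, 5), bool), (2, 2), 3, "median")
        assert np.isnan(value) and n_valid == 0
        assert FLAG_OOB in flags

    def test_edge_clipping_flagged(self):
        grid = np.arange(25, dtype=float).reshape(5, 5)
        value, n_valid, flags = extract_window_stat(
            grid, np.ones((5, 5), bool), (0, 0), 3, "mean")
        assert FLAG_EDGE in flags
        assert n_valid == 4  # 2x2 clipped corner window

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            extract_window_stat(np.ones((5, 5)), np.ones((5, 5), bool), (2, 2), 4)

    @pytest.mark.parametrize("window", [3, 5])
    @pytest.mark.parametrize("stat", ["median", "mean"])
    def test_matches_brute_force_everywhere(self, window, stat):
        rng = np.random.default_rng(17)
        grid = rng.random((20, 20))
        grid[rng.random((20, 20)) < 0.1] = np.nan
        mask = rng.random((20, 20)) > 0.3
        for r in range(20):
            for c in range(20):
                got, n_got, _ = extract_window_stat(grid, mask, (r, c), window, stat)
                want, n_want = brute_force_window_stat(grid, mask, r, c, window, stat)
                assert n_got == n_want
                if n_want:
                    assert got == pytest.approx(want)
                else:
                    assert np.isnan(got)


def _lake_setup(default_scene):
    scene = default_scene["scene"]
    truth = default_scene["truth"]
    mask = WaterMask(truth.water_mask_truth)
    reg = FeatureRegistry.defaults()
    feats = compute_feature_stack(scene, reg, mask, ["NDCI", "NDTI"])
    return scene, truth, mask, feats


class TestBuildMatchupTable:
    def test_center_station_fully_valid(self, default_scene):
        scene, truth, mask, feats = _lake_setup(default_scene)
        x, y = scene.transform.xy(128, 128)  # lake center pixel
        st = StationRecord("C1", "2024-01-01T00:00:00Z", float(x), float(y),
                           "chl_a", 30.0)
        table = build_matchup_table([st], feats, mask, scene)
        row = table.rows[0]
        assert row.n_valid == 9 and not row.flags
        # median of the window should sit near the per-pixel feature value
        assert row.predictors["NDCI"] == pytest.approx(
            feats.grids["NDCI"][128, 128], abs=0.02)

    def test_land_station_flagged_with_nodata(self, default_scene):
        scene, truth, mask, feats = _lake_setup(default_scene)
        x, y = scene.transform.xy(5, 5)  # far from the lake
        st = StationRecord("L1", "t", float(x), float(y), "chl_a", 10.0)
        row = build_matchup_table([st], feats, mask, scene).rows[0]
        assert {FLAG_LOW_VALID, FLAG_OOB} & row.flags
        assert np.isnan(row.predictors["NDCI"])

    def test_station_outside_scene(self, default_scene):
        scene, truth, mask, feats = _lake_setup(default_scene)
        st = StationRecord("X1", "t", -1e6, -1e6, "chl_a", 10.0)
        row = build_matchup_table([st], feats, mask, scene).rows[0]
        assert FLAG_OOB in row.flags and row.n_valid == 0

    def test_duplicate_pixel_stations_kept(self, default_scene):
        scene, truth, mask, feats = _lake_setup(default_scene)
        x, y = scene.transform.xy(128, 128)
        sts = [StationRecord(f"D{i}", "t", float(x), float(y), "chl_a", 30.0)
               for i in range(2)]
        table = build_matchup_table(sts, feats, mask, scene)
        assert len(table) == 2
        assert table.rows[0].predictors == table.rows[1].predictors
        assert table.rows[0].station.sample_id != table.rows[1].station.sample_id

    def test_row_order_follows_station_order(self, default_scene):
        scene, truth, mask, feats = _lake_setup(default_scene)
        stations = make_stations(truth, scene, n=10, seed=2, obs_noise_sd=0.0)
        table = build_matchup_table(stations, feats, mask, scene)
        assert [r.station.sample_id for r in table.rows] == \
               [s.sample_id for s in stations]
        reversed_table = build_matchup_table(stations[::-1], feats, mask, scene)
        assert reversed_table.rows[-1].predictors == table.rows[0].predictors

    def test_min_valid_fraction_extremes(self, default_scene):
        scene, truth, mask, feats = _lake_setup(default_scene)
        # station one pixel inside the shoreline: window touches land
        edge_rc = None
        interior = truth.water_mask_truth
        for r in range(interior.shape[0]):
            for c in range(interior.shape[1]):
                if interior[r, c] and not interior[r, c - 1]:
                    edge_rc = (r, c)
                    break
            if edge_rc:
                break
        x, y = scene.transform.xy(*edge_rc)
        st = StationRecord("E1", "t", float(x), float(y), "chl_a", 20.0)
        row0 = build_matchup_table([st], feats, mask, scene,
                                   min_valid_fraction=0.0).rows[0]
        assert FLAG_LOW_VALID not in row0.flags
        row1 = build_matchup_table([st], feats, mask, scene,
                                   min_valid_fraction=1.0).rows[0]
        assert FLAG_LOW_VALID in row1.flags

    def test_empty_station_list(self, default_scene):
        scene, truth, mask, feats = _lake_setup(default_scene)
        table = build_matchup_table([], feats, mask, scene)
        assert len(table) == 0

    def test_csv_round_trip(self, tmp_path, default_scene):
        scene, truth, mask, feats = _lake_setup(default_scene)
        stations = make_stations(truth, scene, n=8, seed=6, obs_noise_sd=1.0)
        table = build_matchup_table(stations, feats, mask, scene)
        path = table.to_csv(tmp_path / "matchups.csv")
        back = MatchupTable.from_csv(path, "chl_a")
        assert back.feature_names == table.feature_names
        Xa, ya = table.to_arrays()
        Xb, yb = back.to_arrays()
        np.testing.assert_allclose(Xa, Xb)
        np.testing.assert_allclose(ya, yb)


class TestStationCsv:
    def test_read_stations(self, tmp_path):
        path = tmp_path / "situ.csv"
        path.write_text("sample_id,timestamp,lon,lat,chl_a\n"
                        "A,2024-01-01T00:00:00Z,100.0,200.0,12.5\n")
        stations = read_stations_csv(path)
        assert stations[0].response_name == "chl_a"
        assert stations[0].response_value == 12.5

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,chl_a\nA,1.0\n")
        with pytest.raises(ValidationError, match="missing columns"):
            read_stations_csv(path)

    def test_non_finite_station_rejected(self):
        with pytest.raises(ValidationError):
            StationRecord("A", "t", float("nan"), 0.0, "chl_a", 1.0)
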