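"""Similarity registration, cropping, spot binning, composition, benchmarking."""

import numpy as np
import pandas as pd
import pytest
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon

import spatialniche as sn
from spatialniche.integration import (
    AlignmentError,
    DegenerateLandmarksError,
    ReflectionError,
)
from conftest import make_cells


def hex_grid(n=10, pitch=100.0):
    rows = []
    sid = 1
    for i in range(n):
        off = pitch / 2 if i % 2 else 0.0
        for j in range(n):
            rows.append((sid, j * pitch + off, i * pitch * np.sqrt(3) / 2))
            sid += 1
    df = pd.DataFrame(rows, columns=["spot_id", "x", "y"])
    df["in_tissue"] = True
    return sn.SpotGrid(df, diameter=55.0, pitch=pitch)


class TestTransform2D:
    def test_apply_inverse_round_trip(self):
        tf = sn.Transform2D(theta=0.4, scale=1.7, tx=3.0, ty=-8.0)
        pts = np.random.default_rng(0).normal(size=(20, 2))
        np.testing.assert_allclose(tf.inverse().apply(tf.apply(pts)), pts,
                                   atol=1e-12)

    def test_compose_associative(self):
        a = sn.Transform2D(0.3, 1.2, 1, 2)
        b = sn.Transform2D(-0.7, 0.8, -4, 0.5)
        c = sn.Transform2D(1.1, 2.0, 0, 3)
        pts = np.random.default_rng(1).normal(size=(10, 2))
        left = a.compose(b).compose(c)
        right = a.compose(b.compose(c))
        np.testing.assert_allclose(left.apply(pts), right.apply(pts), atol=1e-9)

    def test_json_round_trip(self, tmp_path):
        tf = sn.Transform2D(0.52, 1.2, 10.0, -5.0)
        tf.to_json(tmp_path / "t.json")
        back = sn.Transform2D.from_json(tmp_path / "t.json")
        assert back == tf


class TestFitSimilarity:
    def test_identity(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [2, 2]], float)
        tf, res = sn.fit_similarity_transform(pts, pts)
        assert res == pytest.approx(0.0, abs=1e-12)
        assert tf.theta == pytest.approx(0.0, abs=1e-12)
        assert tf.scale == pytest.approx(1.0)

    def test_recovers_known_transform(self):
        rng = np.random.default_rng(2)
        src = rng.uniform(-50, 50, size=(5, 2))
        truth = sn.Transform2D(theta=np.deg2rad(30), scale=1.2, tx=10.0, ty=-5.0)
        dst = truth.apply(src)
        tf, res = sn.fit_similarity_transform(src, dst)
        assert res < 1e-9
        assert tf.theta == pytest.approx(truth.theta, abs=1e-6)
        assert tf.scale == pytest.approx(truth.scale, abs=1e-6)
        assert tf.tx == pytest.approx(truth.tx, abs=1e-6)
        assert tf.ty == pytest.approx(truth.ty, abs=1e-6)

    def test_rigid_mode_fixes_scale(self):
        rng = np.random.default_rng(3)
        src = rng.uniform(-50, 50, size=(6, 2))
        truth = sn.Transform2D(theta=0.9, scale=1.0, tx=-3.0, ty=7.0)
        tf, res = sn.fit_similarity_transform(src, truth.apply(src),
                                              allow_scale=False)
        assert tf.scale == 1.0
        assert res < 1e-9

    def test_reflection_rejected(self):
        src = np.array([[0, 0], [1, 0], [0, 1]], float)
        dst = src.copy()
        dst[:, 0] *= -1  # mirror
        with pytest.raises(ReflectionError):
            sn.fit_similarity_transform(src, dst)

    def test_coincident_landmarks_degenerate(self):
        src = np.zeros((3, 2))
        with pytest.raises(DegenerateLandmarksError):
            sn.fit_similarity_transform(src, src + 1.0)


class TestCrop:
    def _dataset(self, n=200, seed=4):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 100, size=(n, 2))
        cells = make_cells(xy, ["t"] * n)
        return sn.SpatialCellSet(cells)

    def test_full_extent_is_identity(self):
        ds = self._dataset()
        out = sn.crop_region(ds, (0.0, 0.0, 100.0, 100.0))
        assert out.n_cells == ds.n_cells

    def test_half_split(self):
        xy = np.column_stack([np.linspace(0, 99, 100) + 0.5, np.full(100, 1.0)])
        ds = sn.SpatialCellSet(make_cells(xy, ["t"] * 100))
        out = sn.crop_region(ds, (0.0, 0.0, 50.0, 2.0))
        assert out.n_cells == 50

    def test_polygon_matches_point_in_polygon_oracle(self):
        ds = self._dataset(200)
        poly = Polygon([(10, 10), (90, 20), (70, 80), (20, 60)])
        out = sn.crop_region(ds, poly)
        oracle = MplPath(np.asarray(poly.exterior.coords)).contains_points(
            ds.cells[["x", "y"]].to_numpy(float), radius=1e-9)
        assert set(out.cells["cell_id"]) == set(
            ds.cells.loc[oracle, "cell_id"])

    def test_empty_intersection_warns(self):
        ds = self._dataset()
        with pytest.warns(UserWarning, match="no cells"):
            out = sn.crop_region(ds, (1000.0, 1000.0, 1001.0, 1001.0))
        assert out.n_cells == 0


class TestAssignToSpots:
    def test_point_at_center(self):
        grid = hex_grid()
        center = grid.spots.loc[17, ["x", "y"]].to_numpy(float)
        got = sn.assign_to_spots(center[None, :], grid)
        assert got[0] == grid.spots.loc[17, "spot_id"]

    def test_tie_breaks_to_smaller_id(self):
        spots = pd.DataFrame({"spot_id": [7, 3], "x": [0.0, 10.0],
                              "y": [0.0, 0.0], "in_tissue": True})
        grid = sn.SpotGrid(spots, diameter=5.0, pitch=10.0)
        got = sn.assign_to_spots(np.array([[5.0, 0.0]]), grid)
        assert got[0] == 3

    def test_matches_brute_force(self):
        grid = hex_grid()
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 900, size=(100, 2))
        got = sn.assign_to_spots(pts, grid)
        centers = grid.spots[["x", "y"]].to_numpy(float)
        ids = grid.spots["spot_id"].to_numpy()
        d = np.sqrt(((pts[:, None] - centers[None]) ** 2).sum(-1))
        brute = ids[d.argmin(axis=1)]
        np.testing.assert_array_equal(got, brute)

    def test_rigid_motion_applied_jointly_preserves_assignment(self):
        grid = hex_grid()
        rng = np.random.default_rng(7)
        pts = rng.uniform(100, 800, size=(50, 2))
        base = sn.assign_to_spots(pts, grid)
        tf = sn.Transform2D(theta=0.3, tx=40.0, ty=-60.0)
        moved_spots = grid.spots.copy()
        moved_spots[["x", "y"]] = tf.apply(
            grid.spots[["x", "y"]].to_numpy(float))
        moved_grid = sn.SpotGrid(moved_spots, grid.diameter, grid.pitch)
        got = sn.assign_to_spots(tf.apply(pts), moved_grid)
        np.testing.assert_array_equal(got, base)

    def test_max_distance_unassigns(self):
        grid = hex_grid()
        far = np.array([[5000.0, 5000.0]])
        assert sn.assign_to_spots(far, grid, max_distance=50.0)[0] == -1

    def test_empty_grid_raises(self):
        spots = pd.DataFrame({"spot_id": [], "x": [], "y": [], "in_tissue": []})
        grid = sn.SpotGrid(spots, diameter=55.0, pitch=100.0)
        with pytest.raises(ValueError):
            sn.assign_to_spots(np.array([[0.0, 0.0]]), grid)

    def test_diameter_cannot_exceed_pitch(self):
        spots = pd.DataFrame({"spot_id": [1], "x": [0.0], "y": [0.0],
                              "in_tissue": [True]})
        with pytest.raises(ValueError):
            sn.SpotGrid(spots, diameter=60.0, pitch=55.0)

    def test_grid_csv_round_trip(self, tmp_path):
        grid = hex_grid(4)
        grid.to_csv(tmp_path / "spots.csv")
        back = sn.SpotGrid.from_csv(tmp_path / "spots.csv")
        assert back.diameter == grid.diameter and back.pitch == grid.pitch
        pd.testing.assert_frame_equal(back.spots, grid.spots)


class TestSpotComposition:
    def test_direct_normalization(self):
        comp = sn.spot_composition(np.array([1, 1, 1, 1]),
                                   np.array(["PT", "PT", "PT", "TAL"]))
        assert comp.proportions.loc[1, "PT"] == pytest.approx(0.75)
        assert comp.proportions.loc[1, "TAL"] == pytest.approx(0.25)

    def test_empty_spot_flagged_and_excluded(self):
        comp = sn.spot_composition(np.array([1, 1]), np.array(["A", "B"]),
                                   spot_ids=np.array([1, 2]))
        assert list(comp.empty_spots) == [2]
        assert 2 not in comp.proportions.index
        assert comp.counts.loc[2].sum() == 0

    def test_count_conservation(self):
        rng = np.random.default_rng(8)
        assign = rng.integers(1, 20, 500)
        labels = rng.choice(list("QRS"), 500)
        comp = sn.spot_composition(assign, labels)
        assert comp.total_cells == 500


class TestBenchmark:
    def _measured(self):
        rng = np.random.default_rng(9)
        raw = rng.random((12, 4))
        prop = raw / raw.sum(axis=1, keepdims=True)
        return pd.DataFrame(prop, index=pd.Index(range(1, 13), name="spot_id"),
                            columns=["PT", "TAL", "CD", "Uro"])

    def test_identity_gives_r_one(self):
        m = self._measured()
        report = sn.benchmark_predictions(m, m.copy(), scope="pooled")
        assert report["r"].iloc[0] == pytest.approx(1.0)
        for scope in ("per-type", "per-spot"):
            rep = sn.benchmark_predictions(m, m.copy(), scope=scope)
            np.testing.assert_allclose(rep["r"], 1.0)

    def test_shuffled_rows_match_direct_correlation(self):
        m = self._measured()
        rng = np.random.default_rng(10)
        pred = m.copy()
        pred[:] = m.to_numpy()[rng.permutation(len(m))]
        report = sn.benchmark_predictions(m, pred, scope="pooled")
        oracle = np.corrcoef(m.to_numpy().ravel(), pred.to_numpy().ravel())[0, 1]
        assert report["r"].iloc[0] == pytest.approx(oracle)

    def test_constant_column_reports_nan_with_reason(self):
        m = self._measured()
        pred = m.copy()
        pred["PT"] = 0.25
        report = sn.benchmark_predictions(m, pred, scope="per-type")
        row = report.set_index("unit").loc["PT"]
        assert np.isnan(row["r"])
        assert row["reason"] == "zero variance"

    def test_label_map_applied(self):
        m = self._measured()
        pred = m.rename(columns={"PT": "proximal_tubule"})
        report = sn.benchmark_predictions(
            m, pred, scope="pooled", label_map={"proximal_tubule": "PT"})
        assert report["r"].iloc[0] == pytest.approx(1.0)

    def test_no_overlapping_spots_raises(self):
        m = self._measured()
        pred = m.copy()
        pred.index = pred.index + 1000
        with pytest.raises(AlignmentError):
            sn.benchmark_predictions(m, pred)

    def test_disjoint_spots_dropped_and_counted(self):
        m = self._measured()
        pred = m.iloc[:8].copy()
        report = sn.benchmark_predictions(m, pred, scope="pooled")
        assert report.attrs["n_spots_used"] == 8
        assert report.attrs["n_spots_dropped"] == 4
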