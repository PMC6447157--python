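"""Geometry measurements: region properties, neighbour distances, hull
metrics, mitotic-event mapping, and the per-cell feature table."""

import math

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk

from clonoscope.lineage import ObjectMatrix, build_forest
from clonoscope.measure import (
    build_feature_table,
    colony_hull_metrics,
    measure_frame,
    mitotic_event_map,
    neighbor_stats,
    tracks_from_experiment,
    ColonyMetrics,
)


def test_solid_square_properties():
    img = np.zeros((20, 20), dtype=int)
    img[5:15, 5:15] = 1
    df = measure_frame(img, pixel_size_um=2.0)
    row = df.loc[1]
    assert row.area_px2 == 100
    assert row.area_um2 == 400.0
    assert row.extent == 1.0
    assert row.solidity == 1.0
    assert row.centroid_x_px == pytest.approx(9.5)
    assert row.centroid_y_px == pytest.approx(9.5)


def test_disk_form_factor_near_one():
    img = np.zeros((64, 64), dtype=int)
    rr, cc = disk((32, 32), 20)
    img[rr, cc] = 1
    df = measure_frame(img)
    # perimeter discretisation biases the ratio a few percent below 1
    assert df.loc[1, "form_factor"] == pytest.approx(1.0, abs=0.07)
    assert df.loc[1, "compactness"] == pytest.approx(1.0, abs=0.07)
    assert 0 <= df.loc[1, "eccentricity"] < 1


def test_empty_image_empty_measurements():
    assert len(measure_frame(np.zeros((10, 10), dtype=int))) == 0


def test_measure_agrees_with_pixel_scan():
    """Area and centroid match a brute-force pixel scan on small images."""
    rng = np.random.default_rng(0)
    img = np.zeros((64, 64), dtype=int)
    for lab in (1, 2, 3):
        r, c = rng.integers(5, 50, size=2)
        img[r : r + rng.integers(3, 10), c : c + rng.integers(3, 10)] = lab
    df = measure_frame(img)
    for lab in np.unique(img[img > 0]):
        rows, cols = np.nonzero(img == lab)
        assert df.loc[lab, "area_px2"] == len(rows)
        assert df.loc[lab, "centroid_x_px"] == pytest.approx(cols.mean())
        assert df.loc[lab, "centroid_y_px"] == pytest.approx(rows.mean())


def _two_squares(gap):
    img = np.zeros((40, 80), dtype=int)
    img[10:20, 5:15] = 1
    img[10:20, 15 + gap : 25 + gap] = 2
    return img


def test_neighbors_within_threshold():
    stats = neighbor_stats(_two_squares(10), threshold_px=15)
    assert stats.loc[1, "n_neighbors"] == 1
    assert stats.loc[2, "n_neighbors"] == 1
    assert stats.loc[1, "first_closest_distance"] == pytest.approx(10.0)


def test_neighbors_beyond_threshold():
    stats = neighbor_stats(_two_squares(20), threshold_px=15)
    assert stats.loc[1, "n_neighbors"] == 0
    assert stats.loc[1, "first_closest_distance"] == pytest.approx(20.0)


def test_single_object_no_neighbors():
    img = np.zeros((20, 20), dtype=int)
    img[5:10, 5:10] = 1
    stats = neighbor_stats(img)
    assert stats.loc[1, "n_neighbors"] == 0
    assert np.isnan(stats.loc[1, "first_closest_distance"])


def test_neighbor_relation_symmetric():
    rng = np.random.default_rng(1)
    img = np.zeros((60, 60), dtype=int)
    for lab in range(1, 6):
        r, c = rng.integers(0, 50, size=2)
        img[r : r + 8, c : c + 8] = lab
    labels = sorted(np.unique(img[img > 0]))
    stats = neighbor_stats(img, threshold_px=12)
    # recompute the pairwise relation from the distance matrix outputs
    for li in labels:
        for lj in labels:
            if li >= lj:
                continue
            img_ij = np.where(np.isin(img, [li, lj]), img, 0)
            s = neighbor_stats(img_ij, threshold_px=12)
            assert s.loc[li, "n_neighbors"] == s.loc[lj, "n_neighbors"]


def test_hull_of_disk_diameter():
    img = np.zeros((200, 200), dtype=int)
    rr, cc = disk((100, 100), 60)
    img[rr, cc] = 1
    met = colony_hull_metrics(img, pixel_size_um=10.0)
    # hull ~ circle of radius 600 um -> equal-area diameter ~ 1.2 mm
    assert met.approx_diameter_mm == pytest.approx(1.2, rel=0.02)
    assert met.confluency == pytest.approx(1.0, abs=0.02)


def test_members_tiling_their_hull_are_fully_confluent():
    img = np.zeros((30, 30), dtype=int)
    img[10:20, 10:15] = 1
    img[10:20, 15:20] = 2
    met = colony_hull_metrics(img)
    assert met.confluency == pytest.approx(1.0)
    assert met.occupied_area_um2 <= met.hull_area_um2 + 1e-9


def test_l_shaped_colony_hull_matches_shoelace():
    """Hull of an L of three 10x10 squares equals the shoelace area of the
    polygon over the outermost pixel corners."""
    img = np.zeros((40, 40), dtype=int)
    img[0:10, 0:10] = 1
    img[0:10, 10:20] = 2
    img[10:20, 0:10] = 3
    met = colony_hull_metrics(img)
    # pixel-corner vertices of the convex hull [x, y]
    verts = [(-0.5, -0.5), (19.5, -0.5), (19.5, 9.5), (9.5, 19.5),
             (-0.5, 19.5)]
    shoelace = 0.5 * abs(
        sum(
            x1 * y2 - x2 * y1
            for (x1, y1), (x2, y2) in zip(verts, verts[1:] + verts[:1])
        )
    )
    assert met.hull_area_um2 == pytest.approx(shoelace)


def test_confluency_never_exceeds_one():
    rng = np.random.default_rng(2)
    img = np.zeros((80, 80), dtype=int)
    for lab in range(1, 8):
        r, c = rng.integers(0, 70, size=2)
        img[r : r + 6, c : c + 6] = lab
    met = colony_hull_metrics(img)
    assert met.occupied_area_um2 <= met.hull_area_um2


def test_mitotic_events_one_per_division(toy_division_matrix):
    f = build_forest(toy_division_matrix)
    positions = {("a", 10): (3.0, 4.0)}
    metrics = {
        10: ColonyMetrics(
            hull_area_um2=1.0, occupied_area_um2=0.5, confluency=0.5,
            approx_diameter_mm=0.1, centroid_x_um=0.0, centroid_y_um=0.0,
        )
    }
    events = mitotic_event_map(f, positions, metrics)
    assert len(events) == f.n_divisions == 1
    assert events[0].distance_from_centroid_um == pytest.approx(5.0)  # 3-4-5
    assert events[0].confluency == 0.5
    # division at the centroid itself has distance zero
    events0 = mitotic_event_map(f, {("a", 10): (0.0, 0.0)}, metrics)
    assert events0[0].distance_from_centroid_um == 0.0


def _forest_and_tracks(areas_by_cell, n_frames=200):
    """Forest with one founder dividing at frame 95 plus custom area series."""
    values = np.zeros((n_frames, 3), dtype=int)
    values[0:96, 0] = 1
    values[96:n_frames, 1] = 1
    values[96:n_frames, 2] = 2
    f = build_forest(ObjectMatrix(values=values, cells=["a", "b", "c"]))
    rows = []
    for cid, (first, last) in {"a": (0, 95), "b": (96, n_frames - 1),
                               "c": (96, n_frames - 1)}.items():
        frames = np.arange(first, last + 1)
        area = areas_by_cell(cid, frames)
        rows.append(pd.DataFrame({
            "cell_id": cid, "frame": frames,
            "x_um": np.linspace(0, 10, len(frames)),
            "y_um": 0.0, "area_um2": area,
        }))
    return f, pd.concat(rows, ignore_index=True)


def test_feature_table_constant_area_cell():
    f, tracks = _forest_and_tracks(lambda cid, fr: np.full(len(fr), 500.0))
    t = build_feature_table(f, tracks)
    row = t.data.loc["a"]
    assert row["avg_area_um2"] == 500.0
    assert row["max_area_um2"] == 500.0
    assert row["avg_area_first_0.83d_um2"] == 500.0
    assert row["area_before_division_um2"] == 500.0
    assert (t.data["avg_area_um2"] <= t.data["max_area_um2"]).all()


def test_feature_table_masks_founder_columns():
    f, tracks = _forest_and_tracks(lambda cid, fr: np.full(len(fr), 500.0))
    t = build_feature_table(f, tracks)
    assert not t.mask.loc["a", "lifetime_d"]  # founder: no documented lifetime
    assert not t.mask.loc["a", "birth_time_d"]
    # generation-2 cells have an observable parent only from generation 3 on
    for cid in ("a", "b", "c"):
        assert not t.mask.loc[cid, "parent_max_area_um2"]
        assert not t.mask.loc[cid, "parent_lifetime_d"]


def test_feature_table_early_window_mean():
    """A linearly growing cell's early-area equals the mean of its first 80
    samples (arithmetic series)."""
    def areas(cid, frames):
        return 100.0 + 2.0 * np.arange(len(frames))

    f, tracks = _forest_and_tracks(areas, n_frames=260)
    t = build_feature_table(f, tracks)
    # cell b spans 164 frames; first 80 samples are 100, 102, ..., 258
    assert t.data.loc["b", "avg_area_first_0.83d_um2"] == pytest.approx(
        (100.0 + 258.0) / 2.0
    )


def test_total_distance_bounds_displacement(small_experiment, small_forest):
    tracks = tracks_from_experiment(small_experiment)
    t = build_feature_table(small_forest, tracks)
    for cid, grp in tracks.groupby("cell_id"):
        g = grp.sort_values("frame")
        straight = math.hypot(
            g.x_um.iloc[-1] - g.x_um.iloc[0], g.y_um.iloc[-1] - g.y_um.iloc[0]
        )
        assert t.data.loc[str(cid), "total_distance_traveled_um"] >= straight - 1e-9
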