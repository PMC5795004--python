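"""Tests for score-map post-processing into detections."""

import numpy as np
import pytest

import glomlbp as g
from glomlbp.errors import ConfigError, DegenerateScoreMapError


def make_map(grid, stride=64, window=576, cal=1.0, slide_shape=None):
    grid = np.asarray(grid, dtype=float)
    if slide_shape is None:
        h = (grid.shape[0] - 1) * stride + window
        w = (grid.shape[1] - 1) * stride + window
        slide_shape = (int(h / cal), int(w / cal))
    ch = int(round(slide_shape[0] * cal))
    cw = int(round(slide_shape[1] * cal))
    return g.ScoreMap(
        grid=grid,
        window_side=window,
        stride=stride,
        calibration=cal,
        slide_shape=slide_shape,
        calibrated_shape=(ch, cw),
        slide_id="test",
    )


# --------------------------------------------------------------------------
# normalization and masks


def test_normalize_examples():
    np.testing.assert_allclose(
        g.normalize_map(np.array([[-2.0, 0.0, 2.0]])), [[0.0, 0.5, 1.0]]
    )
    np.testing.assert_allclose(
        g.normalize_map(np.array([[-1.0, -0.5, 3.0]])), [[0.0, 0.125, 1.0]]
    )


def test_normalize_bounds():
    rng = np.random.default_rng(0)
    grid = rng.normal(size=(8, 8))
    norm = g.normalize_map(grid)
    assert norm.min() == 0.0 and norm.max() == 1.0


def test_normalize_constant_grid_raises():
    with pytest.raises(DegenerateScoreMapError):
        g.normalize_map(np.full((4, 4), 1.5))


def test_candidate_mask():
    assert not g.candidate_mask(np.array([[0.5, 2.0]]), 0.0).any()
    np.testing.assert_array_equal(
        g.candidate_mask(np.array([[-1.0, 1.0]]), 0.0), [[True, False]]
    )
    assert g.candidate_mask(np.array([[-1.0, 1.0]]), np.inf).all()


# --------------------------------------------------------------------------
# area filter


def flood_fill_areas(mask):
    """Independent 8-connected component areas by BFS flood fill."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    areas = {}
    label = 0
    for si in range(mask.shape[0]):
        for sj in range(mask.shape[1]):
            if mask[si, sj] and not seen[si, sj]:
                label += 1
                stack = [(si, sj)]
                seen[si, sj] = True
                cells = []
                while stack:
                    i, j = stack.pop()
                    cells.append((i, j))
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = i + di, j + dj
                            if (
                                0 <= ni < mask.shape[0]
                                and 0 <= nj < mask.shape[1]
                                and mask[ni, nj]
                                and not seen[ni, nj]
                            ):
                                seen[ni, nj] = True
                                stack.append((ni, nj))
                areas[label] = cells
    return areas


def oracle_area_filter(mask, amin, amax):
    out = np.zeros_like(np.asarray(mask, bool))
    for cells in flood_fill_areas(mask).values():
        if amin <= len(cells) <= amax:
            for i, j in cells:
                out[i, j] = True
    return out


def test_area_filter_removes_small_and_large():
    mask = np.zeros((20, 40), dtype=bool)
    mask[1:3, 1:3] = True  # area 4 -> removed
    mask[6:8, 10:15] = True  # area 10 -> kept
    mask[10:16, 20:30] = True  # area 60 -> removed
    out = g.area_filter(mask, 6, 50)
    expected = np.zeros_like(mask)
    expected[6:8, 10:15] = True
    np.testing.assert_array_equal(out, expected)


def test_area_filter_single_component_below_min():
    mask = np.zeros((10, 10), dtype=bool)
    mask[2:3, 2:7] = True  # area 5
    assert not g.area_filter(mask, 6, 50).any()


def test_area_filter_identity_bounds():
    rng = np.random.default_rng(1)
    mask = rng.random((15, 15)) < 0.4
    np.testing.assert_array_equal(g.area_filter(mask, 1, mask.size), mask)


def test_area_filter_idempotent_and_matches_oracle():
    rng = np.random.default_rng(2)
    for _ in range(20):
        h, w = rng.integers(5, 51, size=2)
        mask = rng.random((h, w)) < rng.uniform(0.2, 0.6)
        amin, amax = 3, 20
        out = g.area_filter(mask, amin, amax)
        np.testing.assert_array_equal(out, oracle_area_filter(mask, amin, amax))
        np.testing.assert_array_equal(g.area_filter(out, amin, amax), out)


# --------------------------------------------------------------------------
# final detections


def test_single_blob_detection_and_centroid_arithmetic():
    grid = np.full((20, 20), 1.0)
    grid[5:7, 8:13] = -1.0  # compact blob of area 10
    sm = make_map(grid)
    det = g.final_detections(sm)
    assert len(det) == 1
    # centroid of cells rows {5,6} cols {8..12} -> (5.5, 10.0)
    x, y = sm.cell_to_slide(5.5, 10.0)
    np.testing.assert_allclose(det.centroids_xy[0], [x, y])
    assert det.scores[0] < 0.25


def test_oversized_blob_is_filtered_out():
    grid = np.full((20, 20), 1.0)
    grid[5:11, 5:15] = -1.0  # area 60 > 50
    det = g.final_detections(make_map(grid))
    assert len(det) == 0


def test_empty_result_is_not_an_error():
    grid = np.full((10, 10), 1.0)
    grid[0, 0] = 0.5  # non-constant, nothing below 0
    det = g.final_detections(make_map(grid))
    assert len(det) == 0
    assert det.provenance["raw_threshold"] == 0.0


def test_detection_count_monotone_in_final_threshold():
    rng = np.random.default_rng(3)
    grid = np.full((30, 30), 1.0) + rng.normal(0, 0.01, (30, 30))
    # two well-separated blobs of different depths
    grid[4:6, 4:9] = -1.0
    grid[20:22, 20:25] = -0.3
    sm = make_map(grid)
    counts = [
        len(g.final_detections(sm, g.PostprocessConfig(final_threshold=t)))
        for t in (0.05, 0.25, 0.5, 0.9)
    ]
    assert counts == sorted(counts)
    assert counts[-1] == 2


def test_every_centroid_score_below_final_threshold():
    rng = np.random.default_rng(4)
    grid = rng.normal(0.5, 0.5, size=(25, 25))
    grid[3:5, 3:8] = -2.0
    cfg = g.PostprocessConfig(final_threshold=0.3)
    det = g.final_detections(make_map(grid), cfg)
    assert len(det) >= 1
    assert (det.scores < 0.3).all()


def test_postprocess_config_validation():
    with pytest.raises(ConfigError):
        g.PostprocessConfig(area_min=50, area_max=6)
    with pytest.raises(ConfigError):
        g.PostprocessConfig(final_threshold=1.5)


# --------------------------------------------------------------------------
# crops


def test_crop_centered_full_size():
    slide = np.zeros((2000, 2000, 3), dtype=np.uint8)
    det = g.DetectionSet(
        centroids_xy=np.array([[1000.0, 1000.0]]),
        boxes=np.array([[712, 712, 1288, 1288]]),
        scores=np.array([0.1]),
    )
    (crop,) = g.crop_detections(slide, det)
    assert crop.shape == (576, 576, 3)


def test_crop_clipped_at_edge():
    # detection 10 px from the left edge: box clips to width 10 + 288 = 298
    grid = np.full((20, 20), 1.0)
    grid[9:11, 0:5] = -1.0
    sm = make_map(grid)
    det = g.final_detections(sm)
    assert len(det) == 1
    # move the centroid manually to exercise the clipping arithmetic
    det.centroids_xy[0] = [10.0, 1000.0]
    half = 288
    x0 = max(0, round(10 - half))
    det.boxes[0] = [x0, 1000 - half, round(10 - half) + 576, 1000 + half]
    slide = np.zeros((1800, 1800, 3), dtype=np.uint8)
    (crop,) = g.crop_detections(slide, det)
    assert crop.shape[1] == 10 + half


def test_crop_empty_detection_set():
    assert g.crop_detections(np.zeros((10, 10, 3)), g.DetectionSet.empty()) == []


def test_boxes_clipped_to_slide_bounds():
    grid = np.full((20, 20), 1.0)
    grid[0:2, 0:5] = -1.0  # blob near the top-left of the grid
    det = g.final_detections(make_map(grid))
    assert len(det) == 1
    assert (det.boxes >= 0).all()
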