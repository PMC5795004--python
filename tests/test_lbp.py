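"""Unit and property tests for the circular LBP core."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import glomlbp as g
from glomlbp.errors import NeighborhoodOutOfBoundsError, RegionTooSmallError
from glomlbp.lbp import lbp_bin_map, lbp_code_map, neighbor_offsets

# --------------------------------------------------------------------------
# independent brute-force oracle (kept deliberately naive)

_TOL = 1e-6  # tie rule: neighbors equal to the center count as 1


def oracle_code(img, row, col, radius):
    import math

    c = float(img[row, col])
    value = 0
    for k in range(8):
        ang = 2.0 * math.pi * k / 8.0
        dy, dx = radius * math.sin(ang), radius * math.cos(ang)
        if abs(dy - round(dy)) < 1e-9:
            dy = round(dy)
        if abs(dx - round(dx)) < 1e-9:
            dx = round(dx)
        y, x = row + dy, col + dx
        y0, x0 = int(math.floor(y)), int(math.floor(x))
        fy, fx = y - y0, x - x0
        val = 0.0
        for ey, wy in ((0, 1 - fy), (1, fy)):
            for ex, wx in ((0, 1 - fx), (1, fx)):
                if wy and wx:
                    val += wy * wx * float(img[y0 + ey, x0 + ex])
        if val >= c - _TOL:
            value |= 1 << k
    return value


def oracle_histogram(img, radius):
    h, w = img.shape
    counts = np.zeros(10)
    for row in range(radius, h - radius):
        for col in range(radius, w - radius):
            counts[g.bin_index(oracle_code(img, row, col, radius))] += 1
    return counts


# --------------------------------------------------------------------------
# codes


def test_constant_patch_gives_all_ones():
    code = g.lbp_code(np.full((7, 7), 42.0), (3, 3), 1)
    assert code.bits == (1,) * 8
    assert code.value == 255


def test_linear_ramp_code():
    # I(x, y) = x: neighbors at angles 0,45,315 are brighter, 90/270 equal
    # (ties count as 1), 135/180/225 darker -> exactly five 1-bits
    img = np.tile(np.arange(9, dtype=float), (9, 1))
    code = g.lbp_code(img, (4, 4), 1)
    assert code.bits == (1, 1, 1, 0, 0, 0, 1, 1)
    assert sum(code.bits) == 5


def test_code_matches_bruteforce_on_fixed_patch():
    rng = np.random.default_rng(123)
    img = rng.integers(0, 256, size=(5, 5)).astype(float)
    assert g.lbp_code(img, (2, 2), 1).value == oracle_code(img, 2, 2, 1)


def test_out_of_bounds_center_is_an_error():
    img = np.zeros((10, 10))
    with pytest.raises(NeighborhoodOutOfBoundsError, match=r"\(0, 5\)"):
        g.lbp_code(img, (0, 5), 3)


# --------------------------------------------------------------------------
# transitions, uniformity, binning


@pytest.mark.parametrize(
    "value, expected",
    [(0b00000000, 0), (0b00001111, 2), (0b01010101, 8), (0b11111111, 0)],
)
def test_circular_transitions(value, expected):
    assert g.circular_transitions(value) == expected


@pytest.mark.parametrize(
    "value, uniform", [(0b11111111, True), (0b00001111, True), (0b01010101, False)]
)
def test_is_uniform(value, uniform):
    assert g.is_uniform(value) is uniform


def test_exactly_58_uniform_codes():
    assert sum(g.is_uniform(v) for v in range(256)) == 58


@pytest.mark.parametrize(
    "value, expected", [(0b00000000, 0), (0b11111111, 8), (0b01010101, 9)]
)
def test_bin_index(value, expected):
    assert g.bin_index(value) == expected


def test_bins_0_and_8_hold_single_patterns():
    by_bin = {}
    for v in range(256):
        by_bin.setdefault(g.bin_index(v), []).append(v)
    assert by_bin[0] == [0]
    assert by_bin[8] == [255]
    assert len(by_bin[9]) == 256 - 58


@given(st.integers(0, 255))
@settings(derandomize=True, deadline=None)
def test_transitions_are_even(value):
    assert g.circular_transitions(value) % 2 == 0
    assert g.circular_transitions(value) in {0, 2, 4, 6, 8}


# --------------------------------------------------------------------------
# histograms


def test_constant_patch_histogram_all_mass_in_bin8():
    block = g.lbp_histogram(np.full((20, 20), 7.0), 1)
    expected = np.zeros(10)
    expected[8] = 1.0
    np.testing.assert_allclose(block.bins, expected)


def test_prenormalization_counts_equal_valid_centers():
    rng = np.random.default_rng(5)
    img = rng.integers(0, 256, size=(17, 23)).astype(float)
    for r in (1, 3):
        counts = np.bincount(lbp_bin_map(img, r).ravel(), minlength=10)
        assert counts.sum() == (17 - 2 * r) * (23 - 2 * r)


def test_histogram_unit_norm():
    rng = np.random.default_rng(6)
    for _ in range(5):
        img = rng.integers(0, 256, size=(15, 15)).astype(float)
        assert np.linalg.norm(g.lbp_histogram(img, 3).bins) == pytest.approx(
            1.0, abs=1e-9
        )


def test_histogram_matches_bruteforce():
    rng = np.random.default_rng(42)
    img = rng.integers(0, 256, size=(12, 12)).astype(float)
    expected = oracle_histogram(img, 3)
    expected = expected / np.linalg.norm(expected)
    np.testing.assert_allclose(g.lbp_histogram(img, 3).bins, expected, atol=1e-12)


def test_code_map_matches_per_pixel_codes():
    rng = np.random.default_rng(9)
    img = rng.integers(0, 256, size=(11, 13)).astype(float)
    for r in (1, 3):
        cm = lbp_code_map(img, r)
        for row in (r, r + 2, img.shape[0] - r - 1):
            for col in (r, img.shape[1] - r - 1):
                assert cm[row - r, col - r] == g.lbp_code(img, (row, col), r).value


def test_monotone_shift_invariance():
    rng = np.random.default_rng(77)
    img = rng.integers(0, 200, size=(14, 14)).astype(float)
    for shift in (1.0, 17.0, 55.0):
        np.testing.assert_array_equal(
            lbp_code_map(img, 1), lbp_code_map(img + shift, 1)
        )


def test_region_too_small_raises():
    with pytest.raises(RegionTooSmallError):
        g.lbp_histogram(np.zeros((6, 6)), 3)


def test_neighbor_zero_lies_along_plus_x():
    off = neighbor_offsets(3)
    np.testing.assert_allclose(off[0], [0.0, 3.0])  # (dy, dx)
    np.testing.assert_allclose(off[2], [3.0, 0.0])  # quarter turn toward +y
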