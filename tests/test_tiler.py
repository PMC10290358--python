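import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reedcover.tiler import (
    TilePlan,
    TileWindow,
    extract_tiles,
    plan_tiles,
    stitch_probabilities,
)


def brute_force_starts(dim, size, stride):
    """Independent enumeration: walk every stride position, clamp to the edge."""
    starts = set()
    pos = 0
    while True:
        starts.add(min(pos, dim - size))
        if pos >= dim - size:
            break
        pos += stride
    return sorted(starts)


class TestPlanTiles:
    @pytest.mark.parametrize(
        "h, w, size, overlap, n_windows, starts",
        [
            (64, 64, 32, 0.5, 9, [0, 16, 32]),
            (32, 32, 32, 0.5, 1, [0]),
            (70, 70, 32, 0.5, 16, [0, 16, 32, 38]),
        ],
    )
    def test_worked_examples(self, h, w, size, overlap, n_windows, starts):
        plan = plan_tiles(h, w, size, overlap)
        assert len(plan) == n_windows
        assert sorted({win.row0 for win in plan.windows}) == starts
        assert sorted({win.col0 for win in plan.windows}) == starts

    def test_row_major_and_no_duplicates(self):
        plan = plan_tiles(70, 70, 32, 0.5)
        coords = [(w.row0, w.col0) for w in plan.windows]
        assert coords == sorted(coords)  # row-major
        assert len(set(coords)) == len(coords)

    def test_raster_too_small(self):
        with pytest.raises(ValueError, match="too small"):
            plan_tiles(30, 64, 32)

    def test_stride_below_one_pixel(self):
        with pytest.raises(ValueError, match="stride"):
            plan_tiles(64, 64, 2, 0.9)

    def test_invalid_overlap(self):
        with pytest.raises(ValueError):
            plan_tiles(64, 64, 32, 1.0)

    def test_counts_match_brute_force_and_cover_everything(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            h, w = rng.integers(32, 101, size=2)
            size = int(rng.choice([16, 32]))
            overlap = float(rng.choice([0.0, 0.25, 0.5]))
            plan = plan_tiles(h, w, size, overlap)
            stride = round(size * (1 - overlap))
            expected = len(brute_force_starts(h, size, stride)) * len(
                brute_force_starts(w, size, stride)
            )
            assert len(plan) == expected
            cover = np.zeros((h, w), dtype=int)
            for win in plan.windows:
                cover[win.rows, win.cols] += 1
            assert (cover >= 1).all()

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        h=st.integers(32, 100),
        w=st.integers(32, 100),
        size=st.sampled_from([16, 32]),
        overlap=st.sampled_from([0.0, 0.25, 0.5]),
    )
    def test_every_pixel_covered_and_windows_in_bounds(self, h, w, size, overlap):
        plan = plan_tiles(h, w, size, overlap)
        cover = np.zeros((h, w), dtype=int)
        for win in plan.windows:
            assert 0 <= win.row0 and win.row0 + win.size <= h
            assert 0 <= win.col0 and win.col0 + win.size <= w
            cover[win.rows, win.cols] += 1
        assert cover.min() >= 1

    def test_window_invariants(self):
        with pytest.raises(ValueError):
            TileWindow(-1, 0, 32)
        with pytest.raises(ValueError):
            TileWindow(0, 0, 0)

    def test_csv_serialization(self, tmp_path):
        plan = plan_tiles(64, 64, 32, 0.5)
        out = tmp_path / "plan.csv"
        plan.to_csv(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "tile_id,row0,col0,size"
        assert len(lines) == 1 + len(plan)
        assert lines[1] == "0,0,0,32"


class TestExtractTiles:
    def test_constant_image(self):
        img = np.full((64, 64, 3), 7, dtype=np.uint8)
        tiles = extract_tiles(img, plan_tiles(64, 64, 32, 0.5))
        assert len(tiles) == 9
        assert all(np.all(t == 7) and t.shape == (32, 32, 3) for t in tiles)

    def test_checkerboard_corners_are_single_colour(self):
        board = np.kron(np.array([[0, 1], [1, 0]], dtype=np.uint8) * 255, np.ones((32, 32), np.uint8))
        plan = plan_tiles(64, 64, 32, 0.5)
        tiles = extract_tiles(board, plan)
        # corner windows: indices 0, 2, 6, 8 in the 3x3 row-major grid
        for idx, value in [(0, 0), (2, 255), (6, 255), (8, 0)]:
            assert np.all(tiles[idx] == value)

    def test_last_tile_is_flush_slice(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(70, 70, 3), dtype=np.uint8)
        tiles = extract_tiles(img, plan_tiles(70, 70, 32, 0.5))
        np.testing.assert_array_equal(tiles[15], img[38:70, 38:70])

    def test_dimension_mismatch(self):
        plan = plan_tiles(64, 64, 32, 0.5)
        with pytest.raises(ValueError, match="built for"):
            extract_tiles(np.zeros((70, 70, 3), np.uint8), plan)


class TestStitch:
    def test_single_window(self):
        plan = plan_tiles(32, 32, 32, 0.5)
        field = stitch_probabilities(plan, [0.8])
        assert field.shape == (32, 32)
        np.testing.assert_allclose(field, 0.8)

    def test_two_overlapping_windows_average(self):
        plan = TilePlan(32, 48, 32, 0.5, (TileWindow(0, 0, 32), TileWindow(0, 16, 32)))
        field = stitch_probabilities(plan, [0.0, 1.0])
        np.testing.assert_allclose(field[:, :16], 0.0)
        np.testing.assert_allclose(field[:, 16:32], 0.5)
        np.testing.assert_allclose(field[:, 32:], 1.0)

    def test_uniform_probabilities_give_uniform_field(self):
        plan = plan_tiles(64, 64, 32, 0.5)
        field = stitch_probabilities(plan, [0.3] * len(plan))
        np.testing.assert_allclose(field, 0.3)

    def test_length_mismatch(self):
        plan = plan_tiles(64, 64, 32, 0.5)
        with pytest.raises(ValueError, match="expected 9"):
            stitch_probabilities(plan, [0.5] * 8)

    def test_extract_then_stitch_constant_roundtrip(self):
        img = np.full((70, 70, 3), 120, dtype=np.uint8)
        plan = plan_tiles(70, 70, 32, 0.5)
        means = [t.mean() / 255 for t in extract_tiles(img, plan)]
        field = stitch_probabilities(plan, means)
        np.testing.assert_allclose(field, 120 / 255)
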