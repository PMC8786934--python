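import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from binplex.binning import (
    BinGrid,
    GridError,
    bin_median_nonzero,
    build_pseudo_counts,
    compute_bin_grid,
)
from binplex.io import MarkerImage, MarkerStack


def brute_force_counts(pixels: np.ndarray, grid: BinGrid) -> np.ndarray:
    """Independent oracle: per-bin loop, non-zero median, round half away."""
    b = grid.bin_side_px
    out = np.full(grid.n_bins, np.nan)
    for i in range(grid.n_rows):
        for j in range(grid.n_cols):
            block = pixels[i * b : (i + 1) * b, j * b : (j + 1) * b]
            pos = block[block > 0]
            if pos.size:
                out[i * grid.n_cols + j] = np.floor(np.median(pos) * 100.0 + 0.5)
    return out


class TestComputeBinGrid:
    def test_ten_micron_bin_at_0325_resolution_is_31px(self):
        grid = compute_bin_grid(465, 465, resolution_um=0.325, bin_side_um=10.0)
        assert grid.bin_side_px == 31

    @pytest.mark.parametrize(
        "w, h, expected",
        [((93, 62), None, (2, 3)), ((100, 62), None, (2, 3))],
        ids=["exact-division", "trailing-pixels-dropped"],
    )
    def test_grid_dimensions_floor_rule(self, w, h, expected):
        (width, height) = w
        grid = compute_bin_grid(width, height, resolution_um=10 / 31, bin_side_um=10.0)
        assert (grid.n_rows, grid.n_cols) == expected
        assert grid.bin_side_px == 31

    def test_image_smaller_than_one_bin_rejected(self):
        with pytest.raises(GridError):
            compute_bin_grid(30, 62, resolution_um=10 / 31, bin_side_um=10.0)

    def test_coordinates_are_row_major_bin_centres(self):
        grid = compute_bin_grid(62, 62, resolution_um=1.0, bin_side_um=31.0)
        coords = grid.coordinates()
        assert list(coords["bin_row"]) == [0, 0, 1, 1]
        assert list(coords["bin_col"]) == [0, 1, 0, 1]
        assert coords["x_um"].iloc[0] == pytest.approx(15.5)


class TestBinMedianNonzero:
    def test_zeros_excluded_from_median(self):
        grid = BinGrid(bin_side_px=2, n_rows=1, n_cols=1, resolution_um=1.0)
        img = np.array([[0.0, 0.0], [0.2, 0.4]])
        assert bin_median_nonzero(img, grid)[0] == pytest.approx(0.3)

    def test_all_zero_bin_is_missing(self):
        grid = BinGrid(bin_side_px=2, n_rows=1, n_cols=2, resolution_um=1.0)
        img = np.array([[0.0, 0.0, 0.5, 0.5], [0.0, 0.0, 0.5, 0.5]])
        med = bin_median_nonzero(img, grid)
        assert np.isnan(med[0]) and med[1] == pytest.approx(0.5)

    def test_constant_bin(self):
        grid = BinGrid(bin_side_px=3, n_rows=1, n_cols=1, resolution_um=1.0)
        assert bin_median_nonzero(np.full((3, 3), 0.1), grid)[0] == pytest.approx(0.1)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, width=32), min_size=9, max_size=9)
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_numpy_median_of_positive_values(self, values):
        grid = BinGrid(bin_side_px=3, n_rows=1, n_cols=1, resolution_um=1.0)
        img = np.array(values, dtype=float).reshape(3, 3)
        got = bin_median_nonzero(img, grid)[0]
        pos = img[img > 0]
        if pos.size == 0:
            assert np.isnan(got)
        else:
            assert got == pytest.approx(np.median(pos), abs=1e-12)


def _stack_from_arrays(arrays, markers, resolution=1.0):
    images = tuple(
        MarkerImage(m, a, resolution_um=resolution) for m, a in zip(markers, arrays)
    )
    return MarkerStack(section_id="S", group="g", images=images, marker_order=tuple(markers))


class TestBuildPseudoCounts:
    def test_rounding_half_away_from_zero(self):
        grid = BinGrid(bin_side_px=2, n_rows=1, n_cols=1, resolution_um=1.0)
        stack = _stack_from_arrays([np.full((2, 2), 0.305)], ["m"])
        mat = build_pseudo_counts(stack, grid)
        assert mat.counts[0, 0] == 31  # 30.5 rounds up, not to even

    def test_boundary_and_missing(self):
        grid = BinGrid(bin_side_px=2, n_rows=1, n_cols=2, resolution_um=1.0)
        img = np.array([[1.0, 1.0, 0.0, 0.0], [1.0, 1.0, 0.0, 0.0]])
        mat = build_pseudo_counts(_stack_from_arrays([img], ["m"]), grid)
        assert mat.counts[0, 0] == 100
        assert np.isnan(mat.counts[1, 0])

    def test_matches_brute_force_on_random_images(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            H = int(rng.integers(31, 101))
            W = int(rng.integers(31, 101))
            img = rng.random((H, W))
            img[rng.random((H, W)) < 0.3] = 0.0
            grid = compute_bin_grid(W, H, resolution_um=10 / 31, bin_side_um=10.0)
            mat = build_pseudo_counts(_stack_from_arrays([img], ["m"], 10 / 31), grid)
            np.testing.assert_array_equal(mat.counts[:, 0], brute_force_counts(img, grid))

    def test_row_count_is_grid_size_regardless_of_content(self):
        grid = BinGrid(bin_side_px=31, n_rows=2, n_cols=3, resolution_um=10 / 31)
        mat = build_pseudo_counts(_stack_from_arrays([np.zeros((62, 93))], ["m"], 10 / 31), grid)
        assert mat.counts.shape == (6, 1)

    def test_intensity_scaling_never_increases_counts(self):
        rng = np.random.default_rng(3)
        img = rng.random((62, 62))
        img[rng.random((62, 62)) < 0.2] = 0.0
        grid = compute_bin_grid(62, 62, resolution_um=1.0, bin_side_um=31.0)
        base = build_pseudo_counts(_stack_from_arrays([img], ["m"]), grid).counts
        for k in (0.2, 0.7, 1.0):
            scaled = build_pseudo_counts(_stack_from_arrays([img * k], ["m"]), grid).counts
            ok = ~np.isnan(base)
            assert (scaled[ok] <= base[ok]).all()
            np.testing.assert_array_equal(np.isnan(scaled), np.isnan(base))

    def test_marker_permutation_permutes_columns(self):
        rng = np.random.default_rng(5)
        a, b = rng.random((62, 62)), rng.random((62, 62))
        grid = compute_bin_grid(62, 62, resolution_um=1.0, bin_side_um=31.0)
        m1 = build_pseudo_counts(_stack_from_arrays([a, b], ["A", "B"]), grid)
        m2 = build_pseudo_counts(_stack_from_arrays([b, a], ["B", "A"]), grid)
        np.testing.assert_array_equal(m1.counts[:, 0], m2.counts[:, 1])
        np.testing.assert_array_equal(m1.counts[:, 1], m2.counts[:, 0])


def test_tsv_roundtrip_preserves_counts_and_missing(tmp_path):
    rng = np.random.default_rng(9)
    img = rng.random((62, 93))
    img[:, :31] = 0.0
    grid = compute_bin_grid(93, 62, resolution_um=1.0, bin_side_um=31.0)
    mat = build_pseudo_counts(_stack_from_arrays([img, img * 0.5], ["A", "B"]), grid)
    path = tmp_path / "S.tsv"
    mat.to_tsv(path)
    from binplex.binning import PseudoCountMatrix

    back = PseudoCountMatrix.from_tsv(path)
    np.testing.assert_array_equal(back.counts, mat.counts)
    assert back.markers == mat.markers
    assert back.grid == mat.grid


def test_mtx_export_roundtrip(tmp_path):
    from scipy import io as scio

    rng = np.random.default_rng(13)
    img = rng.random((62, 62))
    img[:31, :31] = 0.0
    grid = compute_bin_grid(62, 62, resolution_um=1.0, bin_side_um=31.0)
    mat = build_pseudo_counts(_stack_from_arrays([img], ["A"]), grid)
    mat.to_mtx(tmp_path)
    back = scio.mmread(tmp_path / "matrix.mtx").toarray()
    np.testing.assert_array_equal(back, np.nan_to_num(mat.counts, nan=0.0))
    assert (tmp_path / "bins.tsv").exists() and (tmp_path / "markers.tsv").exists()
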