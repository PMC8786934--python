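"""Fixed square pixel bins and per-section pseudo-count matrices.

Each image is partitioned into complete, non-overlapping ``b x b`` pixel
bins ("blunt-ended": trailing partial rows/columns of pixels are
excluded).  For every bin and marker the median of the strictly positive
pixel intensities is taken (all-zero bins are MISSING), multiplied by 100
and rounded half-away-from-zero to an integer pseudo-count in {0..100}.
The result is the bins x markers pseudo-count matrix that all downstream
analyses consume, analogous to a spot-by-gene count matrix in spatial
transcriptomics.

MISSING entries are stored as NaN in the float count matrix and encoded
as ``"NA"`` in TSV output; they are never imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from binplex.io import MarkerImage, MarkerStack


class GridError(ValueError):
    """Image too small for a single bin, or inconsistent grid usage."""


@dataclass(frozen=True)
class BinGrid:
    """Square bin grid over an image.

    Bin ``(i, j)`` covers pixel rows ``[i*b, (i+1)*b)`` and columns
    ``[j*b, (j+1)*b)`` (0-based, origin top-left, x = column, y = row).
    """

    bin_side_px: int
    n_rows: int
    n_cols: int
    resolution_um: float

    @property
    def n_bins(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def bin_side_um(self) -> float:
        return self.bin_side_px * self.resolution_um

    def coordinates(self) -> pd.DataFrame:
        """Per-bin coordinate table, row-for-row aligned with count matrices.

        Columns: ``bin_row``, ``bin_col`` (grid indices, row-major order)
        and ``x_um``, ``y_um`` (physical bin centres).
        """
        rows, cols = np.divmod(np.arange(self.n_bins), self.n_cols)
        half = self.bin_side_px / 2.0
        return pd.DataFrame(
            {
                "bin_row": rows,
                "bin_col": cols,
                "x_um": (cols * self.bin_side_px + half) * self.resolution_um,
                "y_um": (rows * self.bin_side_px + half) * self.resolution_um,
            }
        )


@dataclass(frozen=True)
class PseudoCountMatrix:
    """Bins x markers integer pseudo-counts (NaN = MISSING) for one section."""

    section_id: str
    counts: np.ndarray  # float64, integer-valued where not NaN
    markers: tuple[str, ...]
    grid: BinGrid
    coords: pd.DataFrame

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.float64)
        if counts.shape != (self.grid.n_bins, len(self.markers)):
            raise ValueError(
                f"counts shape {counts.shape} != "
                f"({self.grid.n_bins}, {len(self.markers)})"
            )
        valid = counts[~np.isnan(counts)]
        if valid.size and (
            (valid < 0).any() or (valid > 100).any() or (valid != np.round(valid)).any()
        ):
            raise ValueError("pseudo-counts must be integers in [0, 100] or NaN")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "markers", tuple(self.markers))

    def to_frame(self) -> pd.DataFrame:
        df = self.coords.copy()
        for j, m in enumerate(self.markers):
            df[m] = self.counts[:, j]
        return df

    def to_tsv(self, path: str | Path) -> None:
        """Persist as TSV (MISSING as "NA") plus a JSON grid sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")
        meta = {
            "section_id": self.section_id,
            "bin_side_px": self.grid.bin_side_px,
            "n_rows": self.grid.n_rows,
            "n_cols": self.grid.n_cols,
            "resolution_um": self.grid.resolution_um,
            "markers": list(self.markers),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    def to_mtx(self, outdir: str | Path) -> None:
        """Sparse Matrix Market export (bins x markers) for single-cell
        toolchains, with row (bin) and column (marker) TSV sidecars.

        MISSING entries are omitted from the sparse matrix (explicit
        zeros are kept), which matches how downstream tools treat absent
        counts.
        """
        from scipy import io as scio
        from scipy import sparse

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dense = np.nan_to_num(self.counts, nan=0.0)
        scio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(dense))
        self.coords.to_csv(outdir / "bins.tsv", sep="\t", index=False)
        pd.Series(self.markers, name="marker").to_csv(
            outdir / "markers.tsv", sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PseudoCountMatrix":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        markers = tuple(meta["markers"])
        grid = BinGrid(
            bin_side_px=meta["bin_side_px"],
            n_rows=meta["n_rows"],
            n_cols=meta["n_cols"],
            resolution_um=meta["resolution_um"],
        )
        return cls(
            section_id=meta["section_id"],
            counts=df[list(markers)].to_numpy(dtype=np.float64),
            markers=markers,
            grid=grid,
            coords=df[["bin_row", "bin_col", "x_um", "y_um"]].copy(),
        )


def compute_bin_grid(
    width_px: int, height_px: int, resolution_um: float, bin_side_um: float = 10.0
) -> BinGrid:
    """Derive the bin grid for an image.

    The bin side in pixels is ``round(bin_side_um / resolution_um)`` —
    e.g. a 10 um bin at 0.325 um/px gives 31 px.  Trailing partial rows
    and columns of pixels are excluded from all bins.
    """
    if bin_side_um <= 0 or resolution_um <= 0:
        raise GridError("bin_side_um and resolution_um must be > 0")
    b = int(round(bin_side_um / resolution_um))
    b = max(b, 1)
    n_rows = height_px // b
    n_cols = width_px // b
    if n_rows < 1 or n_cols < 1:
        raise GridError(
            f"image {width_px}x{height_px} px smaller than one {b}x{b} px bin"
        )
    return BinGrid(bin_side_px=b, n_rows=n_rows, n_cols=n_cols, resolution_um=resolution_um)


def bin_median_nonzero(image: MarkerImage | np.ndarray, grid: BinGrid) -> np.ndarray:
    """Per-bin median of strictly positive intensities; NaN where all pixels are 0.

    The median of an even number of values is the mean of the two central
    order statistics.  Returns a flat array of length ``grid.n_bins`` in
    row-major bin order.
    """
    px = image.pixels if isinstance(image, MarkerImage) else np.asarray(image, float)
    b = grid.bin_side_px
    H, W = grid.n_rows * b, grid.n_cols * b
    if px.shape[0] < H or px.shape[1] < W:
        raise GridError(f"image shape {px.shape} smaller than grid extent ({H}, {W})")
    # (n_bins, b*b) view of the blunt-ended region, then a sort-based
    # median over the non-zero suffix of each row (vectorised).
    blocks = (
        px[:H, :W]
        .reshape(grid.n_rows, b, grid.n_cols, b)
        .transpose(0, 2, 1, 3)
        .reshape(grid.n_bins, b * b)
    )
    srt = np.sort(blocks, axis=1)
    n_zero = (srt <= 0.0).sum(axis=1)
    n_pos = b * b - n_zero
    out = np.full(grid.n_bins, np.nan)
    has = n_pos > 0
    lo = n_zero[has] + (n_pos[has] - 1) // 2
    hi = n_zero[has] + n_pos[has] // 2
    rows = np.nonzero(has)[0]
    out[has] = 0.5 * (srt[rows, lo] + srt[rows, hi])
    return out


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round is banker's rounding; pseudo-counts are defined with
    # half-away-from-zero (values here are always >= 0).
    return np.floor(x + 0.5)


def build_pseudo_counts(stack: MarkerStack, grid: BinGrid | None = None,
                        bin_side_um: float = 10.0) -> PseudoCountMatrix:
    """Build the bins x markers pseudo-count matrix for one section.

    Entry = round(100 * median non-zero intensity), half away from zero;
    all-zero bins propagate to MISSING (NaN).
    """
    H, W = stack.shape
    if grid is None:
        grid = compute_bin_grid(W, H, stack.resolution_um, bin_side_um)
    cols = []
    for im in stack.images:
        med = bin_median_nonzero(im, grid)
        counts = np.where(np.isnan(med), np.nan, _round_half_away(med * 100.0))
        cols.append(counts)
    return PseudoCountMatrix(
        section_id=stack.section_id,
        counts=np.column_stack(cols),
        markers=stack.marker_order,
        grid=grid,
        coords=grid.coordinates(),
    )
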