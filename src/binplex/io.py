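"""Reading, validating and normalising aligned per-marker grayscale images.

One tissue section is represented as a :class:`MarkerStack`: an ordered
list of same-shaped :class:`MarkerImage` arrays, one per antibody label,
already aligned upstream (registration across staining rounds is out of
scope here; this module only verifies dimensional consistency).

Intensities are always stored as float64 in [0, 1].  Integer images are
rescaled by their dtype maximum; RGB images are collapsed to luminance;
floating-point images must already be in [0, 1] (no silent clipping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import io as skio
from skimage.color import rgb2gray, rgba2rgb


class StackAlignmentError(ValueError):
    """Marker images of one section disagree in shape or resolution."""


class DesignError(ValueError):
    """Cohort design table is inconsistent (missing files, empty groups...)."""


@dataclass(frozen=True)
class MarkerImage:
    """A single marker's grayscale intensity image.

    Attributes
    ----------
    marker_name : str
        Antibody / label name (e.g. ``"GFAP"``).
    pixels : ndarray
        2-D float array, intensities in [0, 1]; rows = image y, cols = x.
    resolution_um : float
        Micrometres per pixel, isotropic.
    """

    marker_name: str
    pixels: np.ndarray
    resolution_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(
                f"marker {self.marker_name!r}: expected a 2-D image of at "
                f"least 1x1 pixels, got shape {px.shape}"
            )
        if not np.isfinite(px).all():
            raise ValueError(f"marker {self.marker_name!r}: non-finite intensities")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError(
                f"marker {self.marker_name!r}: intensities outside [0, 1] "
                f"(min={px.min():.4g}, max={px.max():.4g}); refusing to clip"
            )
        if not self.resolution_um > 0:
            raise ValueError("resolution_um must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class MarkerStack:
    """Aligned per-marker images for one tissue section.

    ``marker_order`` is the canonical column order used by every
    downstream matrix and co-occurrence string.
    """

    section_id: str
    group: str
    images: tuple[MarkerImage, ...]
    marker_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        images = tuple(self.images)
        if not images:
            raise DesignError(f"section {self.section_id!r}: empty marker list")
        order = tuple(self.marker_order) or tuple(im.marker_name for im in images)
        names = [im.marker_name for im in images]
        if sorted(names) != sorted(order) or len(set(names)) != len(names):
            raise DesignError(
                f"section {self.section_id!r}: marker names {names} do not "
                f"match marker_order {list(order)}"
            )
        by_name = {im.marker_name: im for im in images}
        images = tuple(by_name[name] for name in order)
        ref = images[0]
        bad = [
            im.marker_name
            for im in images
            if im.shape != ref.shape or im.resolution_um != ref.resolution_um
        ]
        if bad:
            raise StackAlignmentError(
                f"section {self.section_id!r}: markers {bad} disagree with "
                f"{ref.marker_name!r} in shape/resolution "
                f"(expected {ref.shape} @ {ref.resolution_um} um/px)"
            )
        object.__setattr__(self, "images", images)
        object.__setattr__(self, "marker_order", order)

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].shape

    @property
    def resolution_um(self) -> float:
        return self.images[0].resolution_um

    def __getitem__(self, marker: str) -> MarkerImage:
        for im in self.images:
            if im.marker_name == marker:
                return im
        raise KeyError(marker)


@dataclass
class CohortDesign:
    """Cohort design: one row per (section, marker) image file.

    Columns: ``section_id``, ``group``, ``marker``, ``path``.
    """

    table: pd.DataFrame
    marker_order: tuple[str, ...]

    def __post_init__(self) -> None:
        required = {"section_id", "group", "marker", "path"}
        missing = required - set(self.table.columns)
        if missing:
            raise DesignError(f"design table missing columns: {sorted(missing)}")
        self.marker_order = tuple(self.marker_order)
        for sec, sub in self.table.groupby("section_id"):
            have = set(sub["marker"])
            lacking = [m for m in self.marker_order if m not in have]
            if lacking:
                raise DesignError(f"section {sec!r} lacks files for markers {lacking}")
        groups = self.table.groupby("group")["section_id"].nunique()
        if (groups < 1).any() or len(groups) < 2:
            raise DesignError("design must contain at least 2 groups with >=1 section")

    @classmethod
    def from_csv(cls, path: str | Path, marker_order=None) -> "CohortDesign":
        table = pd.read_csv(path)
        if marker_order is None:
            marker_order = tuple(dict.fromkeys(table["marker"]))
        return cls(table=table, marker_order=tuple(marker_order))

    @property
    def sections(self) -> list[str]:
        return list(dict.fromkeys(self.table["section_id"]))

    def group_of(self, section_id: str) -> str:
        sub = self.table.loc[self.table["section_id"] == section_id, "group"]
        if sub.empty:
            raise DesignError(f"unknown section {section_id!r}")
        return str(sub.iloc[0])


def load_marker_image(
    path: str | Path, marker_name: str, resolution_um: float = 0.325
) -> MarkerImage:
    """Load one marker image, converting to grayscale intensities in [0, 1].

    Multi-channel (RGB/RGBA) rasters are collapsed to luminance; integer
    pixel types are rescaled by the dtype maximum; floating-point inputs
    must already be in [0, 1] and pass through unchanged.

    Raises
    ------
    IOError
        If the file is missing or cannot be decoded.
    ValueError
        If a floating-point input has values outside [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"marker image not found: {path}")
    try:
        raw = skio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface decoder failures as I/O
        raise IOError(f"could not decode image {path}: {exc}") from exc

    if raw.ndim == 3 and raw.shape[-1] == 4:
        raw = rgba2rgb(raw)  # returns float in [0, 1]
    if raw.ndim == 3 and raw.shape[-1] == 3:
        raw = rgb2gray(raw)  # ITU-R 601 luminance, float in [0, 1]
    elif raw.ndim != 2:
        raise IOError(
            f"{path}: expected a 2-D grayscale or RGB(A) raster, got shape {raw.shape}"
        )

    if np.issubdtype(raw.dtype, np.integer):
        pixels = raw.astype(np.float64) / np.iinfo(raw.dtype).max
    elif np.issubdtype(raw.dtype, np.bool_):
        pixels = raw.astype(np.float64)
    else:
        pixels = np.asarray(raw, dtype=np.float64)
        if pixels.size and (pixels.min() < 0.0 or pixels.max() > 1.0):
            raise ValueError(
                f"{path}: floating-point intensities outside [0, 1] "
                f"(min={pixels.min():.4g}, max={pixels.max():.4g})"
            )
    return MarkerImage(marker_name=marker_name, pixels=pixels, resolution_um=resolution_um)


def assemble_stack(
    design: CohortDesign, section_id: str, resolution_um: float = 0.325
) -> MarkerStack:
    """Load all marker images for one section into an aligned stack.

    Images are ordered by ``design.marker_order``; shape and resolution
    consistency is enforced by :class:`MarkerStack`.
    """
    sub = design.table.loc[design.table["section_id"] == section_id]
    if sub.empty:
        raise DesignError(f"section {section_id!r} not present in design")
    paths = dict(zip(sub["marker"], sub["path"]))
    images = [
        load_marker_image(paths[m], m, resolution_um=resolution_um)
        for m in design.marker_order
    ]
    return MarkerStack(
        section_id=section_id,
        group=design.group_of(section_id),
        images=tuple(images),
        marker_order=design.marker_order,
    )
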