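"""Synthetic multi-marker tissue phantoms with ground truth.

The phantom emulates a mid-sagittal olfactory-bulb section as concentric
annular layers (glomerular layer outermost, then external plexiform,
granule cell, lateral olfactory tract, and an AON-like core), each
expressing a signature marker set at a high mean intensity over a low
non-zero baseline.  Focal structures — glomerulus-like disks and
vessel-like streaks — can be planted with their own marker signatures,
optionally confined to a layer and with group-dependent counts.  Noise
comprises additive Gaussian pixel noise and speckle dropout (random
pixels set to exactly zero, exercising the non-zero-median / MISSING-bin
path downstream).

Sections of a cohort differ by reproducible sub-seeded randomness:
pixel noise, focal placement, a small jitter of the layer radii and
centre, and a per-marker log-normal staining intensity factor.  This
inter-section variability is what gives positive-bin ratios a
non-degenerate distribution across sections, as real cohorts have.

Group-level abundance effects are expressed per (group, marker) as

* an ``intensity`` factor multiplying the marker's mean image, and/or
* a ``coverage`` factor scaling the width of the annular bands in which
  the marker is expressed.

Coverage is the effect that moves the positive-bin *fraction*: because
the Poisson threshold is derived from each section's own trimmed-mean
rate, a uniform intensity rescaling largely cancels out of the coding,
whereas enlarging the expressing area changes the fraction directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from binplex.io import MarkerImage, MarkerStack
from binplex.binning import BinGrid


@dataclass(frozen=True)
class LayerSpec:
    """One annular band: radii are fractions of the image half-side.

    ``r_outer`` may be ``inf`` for the outermost band (which then also
    claims the image corners).  ``levels`` maps signature markers to
    mean intensities in [0, 1].
    """

    name: str
    r_inner: float
    r_outer: float
    levels: dict[str, float]


@dataclass(frozen=True)
class BlobSpec:
    """Glomerulus-like disks: ``count`` per section (overridable per group)."""

    name: str
    levels: dict[str, float]
    count: int
    radius_px: int
    layer: str | None = None  # confine centres to this band (with margin)
    count_by_group: dict[str, int] | None = None
    min_separation_px: float | None = None  # default: one radius


@dataclass(frozen=True)
class StreakSpec:
    """Vessel-like straight streaks crossing the section."""

    name: str
    levels: dict[str, float]
    count: int
    width_px: int


@dataclass(frozen=True)
class GroupEffect:
    intensity: float = 1.0
    coverage: float = 1.0


@dataclass(frozen=True)
class PhantomConfig:
    markers: tuple[str, ...]
    layers: tuple[LayerSpec, ...]
    image_size: tuple[int, int] = (465, 465)  # (height, width) px
    resolution_um: float = 0.325
    baseline: float = 0.04  # non-zero floor for every marker
    blobs: tuple[BlobSpec, ...] = ()
    streaks: tuple[StreakSpec, ...] = ()
    noise_sd: float = 0.02
    dropout_p: float = 0.10
    texture_sd: float = 0.06  # bin-scale multiplicative texture variability
    texture_scale_px: int = 31  # patch size of the texture field
    band_jitter_sd: float = 0.03  # relative jitter of each band radius
    center_jitter_frac: float = 0.02  # centre offset SD, fraction of half-side
    intensity_jitter_sd: float = 0.05  # per-section per-marker log-normal SD
    group_effects: dict[str, dict[str, GroupEffect]] = field(default_factory=dict)
    groups: dict[str, int] = field(default_factory=lambda: {"NSP": 5, "AD": 5, "PD": 5})
    seed: int = 0

    def __post_init__(self) -> None:
        for spec in list(self.layers) + list(self.blobs) + list(self.streaks):
            for m, level in spec.levels.items():
                if m not in self.markers:
                    raise ValueError(f"{spec.name!r} references unknown marker {m!r}")
                if not 0.0 <= level <= 1.0:
                    raise ValueError(
                        f"{spec.name!r}: mean intensity {level} for {m!r} "
                        f"outside [0, 1]"
                    )
        if not 0.0 <= self.baseline <= 1.0:
            raise ValueError("baseline must be in [0, 1]")
        if any(l.r_outer <= l.r_inner for l in self.layers):
            raise ValueError("layer widths must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Per-pixel layer and focal-structure labels for one section."""

    layer_labels: np.ndarray  # int, index into layer_names
    focal_labels: np.ndarray  # int, 0 = none, else 1-based index into focal_names
    layer_names: tuple[str, ...]
    focal_names: tuple[str, ...]
    expressed_fraction: pd.Series  # marker -> fraction of pixels above baseline

    def bin_labels(self, grid: BinGrid, include_focal: bool = True) -> np.ndarray:
        """Majority ground-truth label per bin (row-major), as strings.

        A bin whose pixels are majority-covered by a focal structure is
        labelled ``"focal:<name>"`` when ``include_focal``; otherwise the
        majority annular layer wins.
        """
        b = grid.bin_side_px
        H, W = grid.n_rows * b, grid.n_cols * b

        def _majority(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            blocks = (
                img[:H, :W]
                .reshape(grid.n_rows, b, grid.n_cols, b)
                .transpose(0, 2, 1, 3)
                .reshape(grid.n_bins, b * b)
            )
            n_max = img.max() + 1
            votes = np.stack([(blocks == v).sum(axis=1) for v in range(n_max)], axis=1)
            return votes.argmax(axis=1), votes.max(axis=1)

        layer_idx, _ = _majority(self.layer_labels)
        labels = np.array([self.layer_names[i] for i in layer_idx], dtype=object)
        if include_focal and self.focal_names:
            focal_idx, focal_votes = _majority(self.focal_labels)
            focal = (focal_idx > 0) & (focal_votes > (b * b) / 2)
            for i in np.nonzero(focal)[0]:
                labels[i] = f"focal:{self.focal_names[focal_idx[i] - 1]}"
        return labels


def _radius_field(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    R = 0.5 * min(H, W)
    return np.hypot(yy - center[0], xx - center[1]) / R


def _effective_band(
    layer: LayerSpec, marker: str, effect: GroupEffect
) -> tuple[float, float]:
    cov = effect.coverage
    if np.isinf(layer.r_outer):
        # outermost band: widen/narrow inward
        return layer.r_inner / cov, layer.r_outer
    return layer.r_inner, layer.r_inner + cov * (layer.r_outer - layer.r_inner)


def _sample_blob_centers(
    rng: np.random.Generator,
    spec: BlobSpec,
    count: int,
    layers: list[LayerSpec],
    radii: np.ndarray,
    center: tuple[float, float],
    R: float,
) -> list[tuple[float, float]]:
    """Uniform centres in the confining annulus, full disk inside the band,
    with sequential minimum-separation rejection (biology: glomeruli do
    not pile up)."""
    if spec.layer is None:
        r_lo, r_hi = 0.0, 1.0
    else:
        idx = [l.name for l in layers].index(spec.layer)
        r_lo = radii[idx - 1] if idx > 0 else 0.0
        r_hi = min(radii[idx], 1.0)
    margin = spec.radius_px / R
    lo = max(r_lo + (margin if r_lo > 0 else 0.0), 0.0)
    hi = max(r_hi - margin, lo + 1e-6)
    min_sep = spec.min_separation_px if spec.min_separation_px is not None else spec.radius_px
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < count and tries < 200 * max(count, 1):
        tries += 1
        r = np.sqrt(rng.uniform(lo**2, hi**2)) * R
        theta = rng.uniform(0, 2 * np.pi)
        cy, cx = center[0] + r * np.sin(theta), center[1] + r * np.cos(theta)
        if all(np.hypot(cy - y, cx - x) >= min_sep for y, x in centers):
            centers.append((cy, cx))
    return centers


def _section_rng(config: PhantomConfig, section_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, section_index]))


def generate_section(
    config: PhantomConfig, group: str, section_index: int
) -> tuple[MarkerStack, GroundTruth]:
    """Render one synthetic section, deterministic for (seed, section_index).

    Group effects are applied to the noiseless mean images; Gaussian
    noise and dropout follow; everything is clipped to [0, 1].
    """
    rng = _section_rng(config, section_index)
    H, W = config.image_size
    R = 0.5 * min(H, W)
    layers = sorted(config.layers, key=lambda l: l.r_outer)
    effects = config.group_effects.get(group, {})

    # per-section geometry jitter: common centre offset, per-band radius jitter
    center = (
        H / 2.0 + rng.normal(0.0, config.center_jitter_frac * R),
        W / 2.0 + rng.normal(0.0, config.center_jitter_frac * R),
    )
    radii = np.array([l.r_outer for l in layers], dtype=float)
    finite = np.isfinite(radii)
    radii[finite] = np.sort(
        radii[finite] * (1.0 + rng.normal(0.0, config.band_jitter_sd, finite.sum()))
    )
    jittered = [
        replace(l, r_inner=(radii[i - 1] if i > 0 else 0.0), r_outer=radii[i])
        for i, l in enumerate(layers)
    ]
    rfield = _radius_field((H, W), center)

    layer_labels = np.zeros((H, W), dtype=np.int16)
    for i, l in enumerate(jittered):
        mask = (rfield >= l.r_inner) & (rfield < l.r_outer)
        layer_labels[mask] = i

    # noiseless mean image per marker
    means = {m: np.full((H, W), config.baseline, dtype=np.float64) for m in config.markers}
    for l in jittered:
        for m, level in l.levels.items():
            eff = effects.get(m, GroupEffect())
            r_in, r_out = _effective_band(l, m, eff)
            mask = (rfield >= r_in) & (rfield < r_out)
            np.maximum(means[m], np.where(mask, level, 0.0), out=means[m])

    focal_names: list[str] = []
    focal_labels = np.zeros((H, W), dtype=np.int16)
    yy, xx = np.mgrid[0:H, 0:W]
    for spec in config.blobs:
        count = (spec.count_by_group or {}).get(group, spec.count)
        focal_names.append(spec.name)
        fid = len(focal_names)
        for cy, cx in _sample_blob_centers(rng, spec, count, jittered, radii, center, R):
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.radius_px**2
            focal_labels[disk] = fid
            for m, level in spec.levels.items():
                np.maximum(means[m], np.where(disk, level, 0.0), out=means[m])
    for spec in config.streaks:
        focal_names.append(spec.name)
        fid = len(focal_names)
        for _ in range(spec.count):
            theta = rng.uniform(0, np.pi)
            offset = rng.uniform(-0.8 * R, 0.8 * R)
            dist = np.abs(
                (xx - center[1]) * np.cos(theta) + (yy - center[0]) * np.sin(theta) - offset
            )
            band = dist < spec.width_px / 2.0
            focal_labels[band] = fid
            for m, level in spec.levels.items():
                np.maximum(means[m], np.where(band, level, 0.0), out=means[m])

    expressed = pd.Series(
        {m: float((means[m] > config.baseline).mean()) for m in config.markers}
    )

    images = []
    for m in config.markers:
        eff = effects.get(m, GroupEffect())
        stain = np.exp(rng.normal(0.0, config.intensity_jitter_sd))
        img = means[m] * eff.intensity * stain
        if config.texture_sd > 0:
            # biological texture: smooth bin-scale variation of labelling
            # intensity (real tissue is not uniformly stained within a layer)
            s = config.texture_scale_px
            ny, nx = -(-H // s), -(-W // s)
            field = np.kron(
                rng.normal(1.0, config.texture_sd, (ny, nx)), np.ones((s, s))
            )[:H, :W]
            img = img * np.clip(field, 0.0, None)
        img = np.clip(img, 0.0, 1.0)
        img = np.clip(img + rng.normal(0.0, config.noise_sd, (H, W)), 0.0, 1.0)
        if config.dropout_p > 0:
            img[rng.random((H, W)) < config.dropout_p] = 0.0
        images.append(
            MarkerImage(marker_name=m, pixels=img, resolution_um=config.resolution_um)
        )
    section_id = f"{group}{section_index:02d}"
    stack = MarkerStack(
        section_id=section_id,
        group=group,
        images=tuple(images),
        marker_order=config.markers,
    )
    truth = GroundTruth(
        layer_labels=layer_labels,
        focal_labels=focal_labels,
        layer_names=tuple(l.name for l in jittered),
        focal_names=tuple(focal_names),
        expressed_fraction=expressed,
    )
    return stack, truth


def generate_cohort(
    config: PhantomConfig,
) -> tuple[pd.DataFrame, list[MarkerStack], list[GroundTruth]]:
    """Generate every section of the configured cohort.

    Returns (design, stacks, truths); ``design`` has one row per section
    (section_id, group).  Sub-seeds derive from (config.seed, global
    section index), so single sections can be re-rendered independently.
    """
    rows, stacks, truths = [], [], []
    index = 0
    for group, n in config.groups.items():
        if n < 1:
            raise ValueError(f"group {group!r} must have >=1 section")
        for _ in range(n):
            stack, truth = generate_section(config, group, index)
            rows.append({"section_id": stack.section_id, "group": group})
            stacks.append(stack)
            truths.append(truth)
            index += 1
    return pd.DataFrame(rows), stacks, truths


def write_cohort(config: PhantomConfig, outdir) -> pd.DataFrame:
    """Render the cohort to TIFF files plus a design CSV (for the CLI)."""
    import tifffile
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design_rows = []
    design, stacks, _ = generate_cohort(config)
    for stack in stacks:
        for im in stack.images:
            safe = im.marker_name.replace("/", "_").replace(" ", "_")
            path = outdir / f"{stack.section_id}_{safe}.tif"
            tifffile.imwrite(path, (im.pixels * 65535).astype(np.uint16))
            design_rows.append(
                {
                    "section_id": stack.section_id,
                    "group": stack.group,
                    "marker": im.marker_name,
                    "path": str(path),
                }
            )
    table = pd.DataFrame(design_rows)
    table.to_csv(outdir / "design.csv", index=False)
    return table


# ---------------------------------------------------------------------------
# Stock configurations


def default_layer_config(seed: int = 0, groups: dict[str, int] | None = None) -> PhantomConfig:
    """Five concentric olfactory-bulb-like layers with signature markers.

    Outermost to innermost: GL, EPL, GCL, LOT, AON-like core, with
    signatures following the conserved olfactory-bulb layer markers
    (glomerular layer: OMP, UEA-I lectin, PGP9.5, MAP2; and so on).
    """
    markers = (
        "DAPI", "histones", "PGP9.5", "calbindin", "synaptophysin",
        "GFAP", "S100", "MBP", "OMP", "UEA-I lectin", "MAP2", "tau",
    )
    # Band radii give each layer a comparable share of the field (about a
    # fifth of the bins each), so no layer is small relative to the
    # clustering neighbourhood size.
    layers = (
        LayerSpec("AON", 0.0, 0.505,
                  {"PGP9.5": 0.60, "calbindin": 0.65, "synaptophysin": 0.55}),
        LayerSpec("LOT", 0.505, 0.714,
                  {"GFAP": 0.55, "S100": 0.60, "PGP9.5": 0.50, "MBP": 0.65}),
        LayerSpec("GCL", 0.714, 0.874, {"DAPI": 0.70, "histones": 0.60}),
        LayerSpec("EPL", 0.874, 1.0, {"GFAP": 0.60, "synaptophysin": 0.60}),
        LayerSpec("GL", 1.0, np.inf,
                  {"OMP": 0.65, "UEA-I lectin": 0.60, "PGP9.5": 0.55, "MAP2": 0.60}),
    )
    return PhantomConfig(
        markers=markers,
        layers=layers,
        groups=groups or {"NSP": 5, "AD": 5, "PD": 5},
        seed=seed,
    )


def two_group_effect_config(
    delta: float = 0.15,
    effect_marker: str = "GFAP",
    seed: int = 0,
    n_per_group: int = 5,
) -> PhantomConfig:
    """Compact two-group cohort planting a positive-fraction difference.

    ``effect_marker`` is expressed in the annulus [0.55, 0.85); in the
    affected group its band is widened by the coverage factor that (by
    annulus geometry, area fraction pi (b^2 - a^2) / 4 of the square
    field) raises the expressing-area fraction by ``delta``.  With
    ``delta = 0`` the two groups are exchangeable (null calibration).
    """
    a, b = 0.55, 0.85
    f0 = np.pi * (b**2 - a**2) / 4.0
    b_new = np.sqrt(a**2 + 4.0 * (f0 + delta) / np.pi)
    if b_new > 0.99:
        raise ValueError(f"delta={delta} pushes the band outside the field")
    coverage = (b_new - a) / (b - a)
    markers = ("NeuN", effect_marker, "S100", "MAP2")
    layers = (
        LayerSpec("core", 0.0, 0.55, {"NeuN": 0.60, "MAP2": 0.55}),
        LayerSpec("band", 0.55, 0.85, {effect_marker: 0.60}),
        LayerSpec("rim", 0.85, np.inf, {"S100": 0.50, "MAP2": 0.45}),
    )
    return PhantomConfig(
        markers=markers,
        layers=layers,
        image_size=(465, 465),
        groups={"NSP": n_per_group, "AD": n_per_group},
        group_effects={"AD": {effect_marker: GroupEffect(coverage=float(coverage))}},
        seed=seed,
    )


def tau_string_config(
    seed: int = 0,
    n_per_group: int = 5,
    blob_counts: dict[str, int] | None = None,
) -> PhantomConfig:
    """Two-group cohort planting tau-positive foci enriched in AD.

    Tau blobs (radius 26 px — each disk majority-covers at least one
    31-px bin) are confined to the AON-like core; the AD group carries
    5x as many as NSP, so the tau co-occurrence string's per-section bin
    counts separate between groups.
    """
    markers = ("PGP9.5", "calbindin", "synaptophysin", "GFAP", "tau")
    layers = (
        LayerSpec("AON", 0.0, 0.50,
                  {"PGP9.5": 0.60, "calbindin": 0.65, "synaptophysin": 0.55}),
        LayerSpec("outer", 0.50, np.inf, {"GFAP": 0.60}),
    )
    blobs = (
        BlobSpec(
            name="tau_focus",
            levels={"tau": 0.70},
            count=2,
            radius_px=26,
            layer="AON",
            count_by_group=blob_counts or {"NSP": 2, "AD": 10},
        ),
    )
    return PhantomConfig(
        markers=markers,
        layers=layers,
        blobs=blobs,
        image_size=(465, 465),
        groups={"NSP": n_per_group, "AD": n_per_group},
        seed=seed,
    )
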