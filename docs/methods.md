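# Methods

## Overview

`binplex` quantifies aligned multiplexed-immunohistochemistry (MP-IHC)
images without segmenting cells.  Each tissue section arrives as one
grayscale intensity image per antibody label, all pre-aligned to the
same pixel dimensions.  The section is partitioned into fixed square
pixel bins — the unit of quantification, analogous to a spot in spatial
transcriptomics — and every downstream analysis operates on the
resulting bins × markers matrix.  Three analyses are supported: a
differential-abundance screen of markers across case groups, a
differential screen of marker co-occurrence strings with spatial
re-plotting, and unsupervised discovery of tissue layers by graph
clustering of bins.

## Pseudo-count matrices

The bin side in pixels is `round(bin_side_um / resolution_um)`; at the
default 10 µm bin and 0.325 µm/px imaging resolution this gives 31 px.
Bins are "blunt-ended": only complete, non-overlapping b×b blocks are
used and trailing partial rows/columns of pixels are discarded —
partial bins would bias the medians through smaller pixel samples.

For each bin and marker we take the **median of the strictly positive
pixel intensities** (intensities live in [0, 1]; integer images are
rescaled by their dtype maximum on load).  Zero pixels are treated as
"no signal" and excluded; a bin with no positive pixels is MISSING (NA),
never 0 and never imputed.  The median is multiplied by 100 and rounded
half-away-from-zero (the rounding convention is fixed and documented
because "round to integer" alone is ambiguous), giving integer
pseudo-counts in {0..100} that behave like counts for Poisson coding.

## Poisson coding and differential labels

Within each section, each marker's rate λ is the 5 %-trimmed mean of its
non-missing pseudo-counts (trim = `floor(0.05 · n)` values dropped per
side, the convention of R's `mean(trim=)`).  λ is computed **per marker
within each section**: the per-bin p-values are per label, so a pooled
λ across markers would mix scales.  A bin is coded positive (1) when
its strict upper-tail probability `P(X > c)` under Poisson(λ) is below
α_bin = 0.05 (strict inequality); MISSING bins code to 0.

Positive bins are tallied per section and divided by the **full grid
size** (bins MISSING for that marker stay in the denominator), giving a
positive-bin ratio r ∈ [0, 1] per section and marker.  Ratios are
screened marker-by-marker with one-way fixed-effects ANOVA across
groups; raw p-values are Benjamini–Hochberg-adjusted across markers, and
Tukey HSD (Tukey–Kramer for unequal n) supplies pairwise contrasts.  A
marker is flagged differential at raw p < 0.10 (the screen is
deliberately liberal; both raw and adjusted p are always reported, and a
switch flags on adjusted p instead).  Markers whose ratios are identical
in every section have no defined F statistic and are reported
untestable rather than significant.  Case-level structure is visualised
by covariance-based PCA (columns centred, not variance-scaled) of the
sections × ratios matrix, optionally restricted to flagged markers.

## Co-occurrence strings

Each bin's 0/1 codes are concatenated in `marker_order` into a binary
string; identical strings denote identical marker co-occurrence
signatures.  String counts per section (strings observed in any section
enter all sections with zero fill) are tested across groups with the
tie-corrected Kruskal–Wallis test — all-tied counts are defined as
H = 0, p = 1 — plus Dunn's pairwise post hoc z tests (implemented
in-package: pooled-rank differences with the tie-corrected variance; for
two groups z² equals H, which the tests exploit as a cross-check).
Strings are flagged at raw p < 0.05, with BH-adjusted p reported
alongside.  Strings observed in fewer than 10 bins in total (default,
configurable) are excluded from testing to guard against the
combinatorial tail of rare signatures; exclusions are logged.  Counts
are tested raw by default; a switch normalises by each section's bin
total.  Flagged strings can be filtered by a marker of interest,
mapped back to bin coordinates (as both figure and machine-readable
table), and summarised as a marker × string membership matrix with
average-linkage/Jaccard ordering.

## Layer discovery

Pseudo-counts are variance-stabilised by `log1p`, then per-marker
centred and scaled to unit variance with values clipped at ±10
("log1p_scale"; the recipe id is recorded in outputs).  MISSING entries
are treated as zero counts; bins missing every marker are dropped and
logged; zero-variance markers scale to all-zero columns with a warning.
The regularised-negative-binomial normalisation of single-cell
toolchains is intentionally not reproduced — the clustering contract is
tested by layer recovery against ground truth, not by matching any
specific tool.

Full PCA follows; the number of retained components is the count of
components with standard deviation > 1 (the classic elbow criterion on
unit-scaled data), floored at 2 so low-variance inputs still yield a
usable space.  A shared nearest-neighbour graph is built on the
retained components: k = 20 neighbours (reduced with a warning when
there are fewer bins), an edge between every pair of bins sharing at
least one neighbour, pruned when the Jaccard overlap of their
(self-inclusive) neighbour sets falls below 1/15.  Communities are
found by Leiden optimisation of RB-configuration modularity at
resolution 0.8 with a recorded seed.  **The Jaccard weights serve only
as the edge-admission rule; modularity is optimised on the unweighted
pruned graph.**  Weighted modularity fragments homogeneous regions —
weight gradients inside a uniform blob masquerade as substructure — and
fails the basic contract that two well-separated blobs come out as two
clusters.  Even unweighted, homogeneous regions much larger than about
three times the neighbourhood size can subdivide at the default
resolution (measured: stable to ~70 bins at k = 20, splitting from ~80);
this mirrors the familiar over-clustering of large uniform populations
in single-cell practice and is resolved by merging clusters or lowering
the resolution.  A 2-D UMAP embedding on the same components and seed
accompanies the assignment.

Clusters are profiled by the mean pseudo-count per marker (MISSING
ignored), z-scored across clusters per marker with the sample SD (R's
`scale` convention; a marker equal in all clusters gets an all-zero
row), and ordered by an average-linkage Euclidean tree for display.
Named layers are assigned from a signature table (layer → marker list;
the built-in `OLFACTORY_BULB_SIGNATURES` carries the conserved
olfactory-bulb signatures, e.g. glomerular layer: OMP, UEA-I lectin,
PGP9.5, MAP2): each layer scores every cluster by the mean z of its
signature markers and takes the arg-max cluster; a cluster can win at
most one layer, contested clusters go to the layer with the larger
score margin (remaining ties to the lower cluster id), and displaced
layers fall back to their next-best cluster.

## The tissue phantom

The phantom renders an olfactory-bulb-like section as five concentric
annular bands (AON-like core, lateral olfactory tract, granule cell
layer, external plexiform layer, glomerular layer outermost, the outer
band claiming the image corners), each expressing its signature markers
at mean intensities around 0.55–0.7 over a 0.04 non-zero baseline.  The
default field is 465×465 px at 0.325 µm/px → a 15×15 grid of 31-px
bins.  Band radii are equal-area by design, so every layer holds ~45 of
the 225 bins: comfortably above the clustering neighbourhood size
(tiny layers acquire forced cross-band kNN edges and merge) and below
the homogeneous-region subdivision regime described above.

Focal structures are available as glomerulus-like disks (uniform
centres within a confining band, sequential minimum-separation
rejection so foci do not pile up, per-group counts) and vessel-like
straight streaks.  Noise comprises, in order: a per-section per-marker
log-normal staining factor (SD 0.05 on the log scale), a bin-scale
multiplicative texture field (iid N(1, 0.06) patches the size of one
bin — real staining is not uniform within a layer, and without
bin-level variability the integer medians of a layer collapse onto
identical vectors, which both degenerates the kNN structure and removes
all within-group ratio variance), additive Gaussian pixel noise
(SD 0.02), clipping to [0, 1], and speckle dropout (each pixel set to
exactly 0 with probability 0.10), which exercises the non-zero-median /
MISSING path.  Sections of a cohort further differ by a small jitter of
the band radii (3 % relative SD) and centre (2 % of the half-side),
emulating inter-individual laminar variability; this is what gives
positive-bin ratios a continuous distribution across sections.

Group abundance effects are declared per (group, marker) as an
`intensity` factor and/or a `coverage` factor.  Intensity rescales the
marker's mean image; note that because the Poisson threshold derives
from each section's own trimmed mean, a uniform intensity change
largely cancels out of the coding.  Coverage scales the width of the
bands in which the marker is expressed and is the effect that moves the
positive-bin fraction; `two_group_effect_config` solves the coverage
factor in closed form from annulus geometry so that a requested
fraction difference (default 0.15) is planted exactly in expectation.
The planted tau-string configuration uses foci of radius 26 px on the
31-px grid: such a disk always majority-covers at least one bin
(worst-case quarter = 531 of 961 px) and two disks can never
majority-cover the same bin, so a 2-vs-10 count enrichment separates
per-section string counts structurally.

Determinism: one master seed; each section's generator is seeded by
`SeedSequence([master, section_index])`, so sections re-render
independently and cohorts are bit-reproducible.

## What the phantom does and does not show

Passing recovery tests on the phantom demonstrates that the pipeline's
statistics behave as designed under known ground truth: planted layers
are recovered and named, planted abundance and co-occurrence effects are
detected at the advertised error rates, and the null is calibrated.  The
phantom does **not** emulate autofluorescence, round-to-round alignment
error, staining-batch structure, anisotropic point-spread, or the
fractal texture of real neuropil; performance on real MP-IHC data
depends on those factors and on upstream alignment quality.

## Problem sizes and numerical choices

Benchmark runs use desk-scale problems: single 465×465 px sections
(225 bins, 12 markers) for layer recovery, and 100-replicate two-group
cohorts (5 sections/group, 465×465 px, 4–5 markers) for the
differential and string screens.  Tolerances: Poisson tail and rank
statistics are validated against independent oracles to 1e-10;
ANOVA/BH to 1e-9.  Degenerate inputs are defined rather than erroneous
wherever a convention exists (all-tied Kruskal–Wallis H = 0; zero-
variance markers all-zero after scaling; all-identical ANOVA
untestable); hard errors are reserved for contract violations
(out-of-range intensities, misaligned stacks, unknown markers).
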