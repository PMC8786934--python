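"""End-to-end convenience wrappers over the analysis stages."""

from __future__ import annotations

import numpy as np
import pandas as pd

from binplex.binning import PseudoCountMatrix, build_pseudo_counts
from binplex.clustering import (
    assign_layers,
    cluster_bins,
    cluster_zscore_profiles,
    normalize_counts,
    pca_and_select_dims,
)
from binplex.differential import (
    ALPHA_BIN_DEFAULT,
    ALPHA_LABEL_DEFAULT,
    BinaryCoding,
    DifferentialResult,
    RatioTable,
    anova_by_label,
    code_bins,
    label_ratios,
)
from binplex.io import MarkerStack
from binplex.strings import (
    ALPHA_STRING_DEFAULT,
    StringTestResult,
    kruskal_dunn_by_string,
    tally_strings,
)


def cohort_counts(stacks: list[MarkerStack], bin_side_um: float = 10.0) -> list[PseudoCountMatrix]:
    """Pseudo-count matrix per section."""
    return [build_pseudo_counts(s, bin_side_um=bin_side_um) for s in stacks]


def cohort_codings(
    matrices: list[PseudoCountMatrix],
    groups: pd.Series | dict,
    alpha_bin: float = ALPHA_BIN_DEFAULT,
) -> list[BinaryCoding]:
    """Poisson-threshold coding per section (section-level trimmed-mean rates)."""
    groups = dict(groups)
    return [
        code_bins(m, alpha_bin=alpha_bin, group=groups[m.section_id]) for m in matrices
    ]


def differential_analysis(
    stacks: list[MarkerStack],
    bin_side_um: float = 10.0,
    alpha_bin: float = ALPHA_BIN_DEFAULT,
    alpha_label: float = ALPHA_LABEL_DEFAULT,
) -> tuple[RatioTable, DifferentialResult, list[BinaryCoding]]:
    """Stacks -> counts -> codings -> ratios -> per-marker ANOVA screen."""
    matrices = cohort_counts(stacks, bin_side_um=bin_side_um)
    codings = cohort_codings(matrices, {s.section_id: s.group for s in stacks}, alpha_bin)
    ratios = label_ratios(codings)
    result = anova_by_label(ratios, alpha_label=alpha_label)
    return ratios, result, codings


def string_analysis(
    codings: list[BinaryCoding],
    alpha: float = ALPHA_STRING_DEFAULT,
    min_total_count: int = 10,
) -> StringTestResult:
    """Codings -> string tallies -> Kruskal-Wallis/Dunn screen."""
    return kruskal_dunn_by_string(
        tally_strings(codings), alpha=alpha, min_total_count=min_total_count
    )


def layer_analysis(
    matrix: PseudoCountMatrix,
    signatures: dict[str, tuple[str, ...]],
    k_neighbors: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
    compute_embedding: bool = True,
):
    """Single-section layer discovery: normalize -> PCA -> cluster -> name.

    Returns (assignment, profile, layer_map).
    """
    norm = normalize_counts(matrix)
    pca, n_dims = pca_and_select_dims(norm)
    assignment = cluster_bins(
        pca, n_dims, k_neighbors=k_neighbors, resolution=resolution,
        seed=seed, compute_embedding=compute_embedding,
    )
    profile = cluster_zscore_profiles(matrix, assignment)
    layer_map = assign_layers(profile, signatures)
    return assignment, profile, layer_map
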