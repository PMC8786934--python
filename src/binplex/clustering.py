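"""Unsupervised tissue-layer discovery from pseudo-count bins.

The bins x markers pseudo-count matrix is variance-stabilised (log1p,
then per-marker centring and unit-variance scaling, clipped at +/-10),
reduced by PCA (components retained while their standard deviation
exceeds 1, floored at 2), and clustered on a shared nearest-neighbour
graph with Leiden modularity optimisation.  Clusters are profiled by the
z-score of mean pseudo-count per marker across clusters, and named
layers are assigned by arg-max of the mean z over each layer's signature
markers (e.g. glomerular layer: OMP, UEA-I lectin, PGP9.5, MAP2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from binplex.binning import PseudoCountMatrix

logger = logging.getLogger(__name__)

K_NEIGHBORS_DEFAULT = 20
RESOLUTION_DEFAULT = 0.8
SNN_PRUNE = 1.0 / 15.0  # drop SNN edges with Jaccard weight below this

#: Olfactory-bulb layer signatures (marker sets whose joint high
#: expression identifies each anatomical layer).
OLFACTORY_BULB_SIGNATURES: dict[str, tuple[str, ...]] = {
    "AON": ("PGP9.5", "calbindin", "synaptophysin"),
    "LOT": ("GFAP", "S100", "NF-L", "NF-H", "PGP9.5", "MBP"),
    "GCL": ("DAPI", "histones"),
    "EPL": ("GFAP", "synaptophysin"),
    "GL": ("OMP", "UEA-I lectin", "PGP9.5", "MAP2"),
}


@dataclass(frozen=True)
class NormalizedMatrix:
    """Variance-stabilised bins x markers values (finite only)."""

    values: np.ndarray
    markers: tuple[str, ...]
    kept_rows: np.ndarray  # indices into the source matrix rows
    recipe: str


@dataclass(frozen=True)
class PCAResult:
    """Component scores, loadings and per-component standard deviations."""

    scores: np.ndarray  # bins x components
    loadings: np.ndarray  # markers x components
    sdev: np.ndarray  # non-increasing
    kept_rows: np.ndarray


@dataclass(frozen=True)
class ClusterAssignment:
    """Bin -> cluster labels with 2-D embedding and run parameters."""

    labels: np.ndarray  # dense integer ids from 0, length = kept bins
    embedding: np.ndarray | None  # kept bins x 2, or None if not computed
    kept_rows: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def normalize_counts(
    matrix: PseudoCountMatrix, clip: float = 10.0, recipe: str = "log1p_scale"
) -> NormalizedMatrix:
    """Default recipe: log1p of pseudo-counts, then per-marker z-scaling.

    MISSING entries are treated as zero counts; bins missing every marker
    are dropped (and logged).  Zero-variance markers scale to all-zero
    columns with a warning rather than being dropped.
    """
    if recipe != "log1p_scale":
        raise ValueError(f"unknown normalization recipe {recipe!r}")
    counts = matrix.counts
    keep = ~np.isnan(counts).all(axis=1)
    if not keep.all():
        logger.info("dropping %d all-MISSING bins", int((~keep).sum()))
    if not keep.any():
        raise ValueError("every bin is all-MISSING; nothing to normalize")
    X = np.log1p(np.nan_to_num(counts[keep], nan=0.0))
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    flat = sd == 0.0
    if flat.any():
        warnings.warn(
            f"zero-variance markers scaled to all-zero: "
            f"{[m for m, f in zip(matrix.markers, flat) if f]}"
        )
    sd = np.where(flat, 1.0, sd)
    Z = np.clip((X - mu) / sd, -clip, clip)
    return NormalizedMatrix(
        values=Z,
        markers=matrix.markers,
        kept_rows=np.nonzero(keep)[0],
        recipe=recipe,
    )


def select_dims(sdev: np.ndarray, floor: int = 2) -> int:
    """Number of components with standard deviation > 1, floored at ``floor``."""
    return max(int((np.asarray(sdev) > 1.0).sum()), floor)


def pca_and_select_dims(norm: NormalizedMatrix) -> tuple[PCAResult, int]:
    """Full PCA of the normalised matrix plus the >1-SD dimension rule."""
    n, m = norm.values.shape
    if m < 2 or n < 3:
        raise ValueError("need >=2 markers and >=3 bins for PCA")
    k = min(n - 1, m)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(norm.values)
    sdev = np.sqrt(pca.explained_variance_)
    result = PCAResult(
        scores=scores,
        loadings=pca.components_.T,
        sdev=sdev,
        kept_rows=norm.kept_rows,
    )
    n_dims = min(select_dims(sdev), k)
    return result, n_dims


def _snn_edges(X: np.ndarray, k: int) -> tuple[list[tuple[int, int]], list[float]]:
    """Shared nearest-neighbour graph: every pair of bins sharing at least
    one neighbour, weighted by Jaccard overlap of their kNN sets (self
    included) and pruned below ``SNN_PRUNE``."""
    from scipy import sparse

    n = X.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(X)
    knn = nn.kneighbors(return_distance=False)
    rows = np.repeat(np.arange(n), k + 1)
    cols = np.concatenate([knn, np.arange(n)[:, None]], axis=1).ravel()
    A = sparse.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    inter = sparse.triu(A @ A.T, k=1).tocoo()
    union = 2.0 * (k + 1) - inter.data
    jaccard = inter.data / union
    keep = jaccard >= SNN_PRUNE
    edges = list(zip(inter.row[keep].tolist(), inter.col[keep].tolist()))
    return edges, jaccard[keep].tolist()


def cluster_bins(
    pca: PCAResult,
    n_dims: int,
    k_neighbors: int = K_NEIGHBORS_DEFAULT,
    resolution: float = RESOLUTION_DEFAULT,
    seed: int = 0,
    compute_embedding: bool = True,
) -> ClusterAssignment:
    """Leiden clustering of bins on an SNN graph over leading components.

    The graph is built from the first ``n_dims`` component scores with
    ``k_neighbors`` neighbours (reduced with a warning when there are
    fewer bins); Leiden optimises RB-configuration modularity at
    ``resolution`` with a fixed seed.  A 2-D UMAP embedding on the same
    components and seed is attached unless ``compute_embedding`` is off.
    """
    import igraph
    import leidenalg

    if n_dims > pca.scores.shape[1]:
        raise ValueError(
            f"n_dims={n_dims} exceeds available components {pca.scores.shape[1]}"
        )
    X = pca.scores[:, :n_dims]
    n = X.shape[0]
    k = k_neighbors
    if n <= k:
        k = max(n - 1, 1)
        warnings.warn(f"only {n} bins; reducing k_neighbors to {k}")
    edges, _weights = _snn_edges(X, k)
    # Jaccard overlap serves as the edge admission rule only; modularity is
    # optimised on the unweighted pruned graph.  Weighted modularity
    # fragments homogeneous regions (weight gradients inside a uniform
    # blob masquerade as substructure), splitting well-separated blobs
    # that should come out as single clusters.
    g = igraph.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(part.membership, dtype=int)
    # re-index cluster ids densely by decreasing size
    order = pd.Series(labels).value_counts(sort=True).index
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[v] for v in labels])
    embedding = None
    if compute_embedding:
        from umap import UMAP

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            embedding = UMAP(
                n_components=2,
                n_neighbors=min(15, max(n - 1, 2)),
                random_state=seed,
            ).fit_transform(X)
    return ClusterAssignment(
        labels=labels,
        embedding=embedding,
        kept_rows=pca.kept_rows,
        params={
            "n_dims": n_dims,
            "k_neighbors": k,
            "resolution": resolution,
            "seed": seed,
            "snn_prune": SNN_PRUNE,
        },
    )


def cluster_zscore_profiles(
    matrix: PseudoCountMatrix, assignment: ClusterAssignment
) -> pd.DataFrame:
    """Clusters x markers z-scores of mean pseudo-count, tree-ordered.

    Means ignore MISSING entries.  z-scores are taken across clusters per
    marker (sample SD, as R's ``scale``); markers equal in all clusters
    get an all-zero row.  Cluster rows are ordered by an average-linkage
    Euclidean hierarchical tree on the profiles (ids unchanged).
    """
    counts = matrix.counts[assignment.kept_rows]
    labels = assignment.labels
    ids = np.arange(assignment.n_clusters)
    means = np.vstack([
        np.nanmean(np.where(np.isnan(counts[labels == c]), np.nan, counts[labels == c]), axis=0)
        for c in ids
    ])
    means = np.nan_to_num(means, nan=0.0)  # cluster x marker all-MISSING -> 0
    mu = means.mean(axis=0)
    ddof = 1 if means.shape[0] > 1 else 0
    sd = means.std(axis=0, ddof=ddof)  # across clusters, as R scale() does
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (means - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    profile = pd.DataFrame(z, index=ids, columns=list(matrix.markers))
    if len(ids) > 2:
        order = leaves_list(linkage(profile.to_numpy(), method="average", metric="euclidean"))
        profile = profile.iloc[order]
    return profile


def assign_layers(
    profile: pd.DataFrame, signatures: dict[str, tuple[str, ...] | list[str]]
) -> dict[int, str | None]:
    """Map clusters to named layers by signature-marker mean z-score.

    Each layer scores every cluster by the mean z of its signature
    markers; the arg-max cluster is assigned.  A cluster can win at most
    one layer: when two layers pick the same cluster, the layer with the
    larger score margin (best minus runner-up) keeps it and the other
    falls back to its next-best cluster; remaining ties go to the lower
    cluster id.  Unmatched clusters map to None.
    """
    markers = list(profile.columns)
    for layer, sig in signatures.items():
        unknown = [m for m in sig if m not in markers]
        if unknown:
            raise ValueError(f"layer {layer!r} references unknown markers {unknown}")
    clusters = list(profile.index)
    scores = {
        layer: profile[list(sig)].mean(axis=1) for layer, sig in signatures.items()
    }
    assignment: dict[str, int] = {}
    available = set(clusters)
    pending = list(signatures)
    while pending and available:
        # each pending layer's best available cluster and its margin
        best = {}
        for layer in pending:
            s = scores[layer][sorted(available)]
            ranked = s.sort_values(ascending=False, kind="mergesort")
            margin = (
                ranked.iloc[0] - ranked.iloc[1] if len(ranked) > 1 else np.inf
            )
            best[layer] = (ranked.index[0], ranked.iloc[0], margin)
        # resolve: for each contested cluster keep the layer with larger margin
        taken: dict[int, str] = {}
        for layer in pending:
            c, _, margin = best[layer]
            if c not in taken:
                taken[c] = layer
            else:
                other = taken[c]
                o_margin = best[other][2]
                if (margin, -clusters.index(c)) > (o_margin, -clusters.index(c)):
                    taken[c] = layer
        for c, layer in taken.items():
            assignment[layer] = c
            available.discard(c)
            pending.remove(layer)
    layer_map: dict[int, str | None] = {int(c): None for c in clusters}
    for layer, c in assignment.items():
        layer_map[int(c)] = layer
    return layer_map


def plot_clusters_spatial(
    assignment: ClusterAssignment,
    coords: pd.DataFrame,
    layer_map: dict[int, str | None] | None = None,
):
    """Per-cluster slide plots plus a combined layer-coloured plot.

    Returns (figures, table): ``figures`` maps ``"cluster_<i>"`` and
    ``"combined"`` to matplotlib figures; ``table`` lists
    (bin_row, bin_col, x_um, y_um, cluster, layer) for every retained
    bin.  Clusters without a layer render gray in the combined plot.
    """
    import matplotlib.pyplot as plt

    kept = coords.iloc[assignment.kept_rows].reset_index(drop=True)
    table = kept.copy()
    table["cluster"] = assignment.labels
    table["layer"] = [
        (layer_map or {}).get(int(c), None) for c in assignment.labels
    ]
    figures = {}
    for c in range(assignment.n_clusters):
        fig, ax = plt.subplots(figsize=(4, 4))
        sub = table[table["cluster"] == c]
        ax.scatter(sub["x_um"], sub["y_um"], s=10, marker="s")
        ax.set_title(f"cluster {c}" + (f" ({sub['layer'].iloc[0]})" if sub["layer"].iloc[0] else ""))
        ax.invert_yaxis()
        ax.set_aspect("equal")
        figures[f"cluster_{c}"] = fig
    fig, ax = plt.subplots(figsize=(5, 5))
    cmap = plt.get_cmap("tab10")
    layers = sorted({l for l in table["layer"] if l is not None})
    color_of = {l: cmap(i % 10) for i, l in enumerate(layers)}
    for layer, sub in table.groupby("layer", dropna=False):
        color = color_of.get(layer, (0.6, 0.6, 0.6, 1.0))
        ax.scatter(sub["x_um"], sub["y_um"], s=10, marker="s", color=color,
                   label=layer if layer is not None else "unassigned")
    ax.legend(fontsize=7)
    ax.invert_yaxis()
    ax.set_aspect("equal")
    figures["combined"] = fig
    return figures, table
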