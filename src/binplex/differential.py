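"""Differential label analysis across case groups.

For each section and marker, bins are declared "positive" when their
pseudo-count sits in the strict Poisson upper tail relative to a
section-level rate: lambda is the 5%-trimmed mean pseudo-count of the
marker's non-missing bins, and a bin is coded 1 iff
``P(X > count) < alpha_bin`` for ``X ~ Poisson(lambda)`` (default
alpha_bin = 0.05, strict).  Positive-bin counts are divided by the total
number of grid bins to give a per-section, per-marker positive-bin
ratio.  Ratios are tested marker-by-marker across groups with one-way
ANOVA (BH adjustment across markers, Tukey HSD post hocs); a marker is
flagged differential at raw p < 0.10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from binplex.binning import PseudoCountMatrix

ALPHA_BIN_DEFAULT = 0.05
ALPHA_LABEL_DEFAULT = 0.10
TRIM_DEFAULT = 0.05


@dataclass(frozen=True)
class BinaryCoding:
    """Bins x markers 0/1 coding from Poisson upper-tail thresholding."""

    section_id: str
    group: str
    values: np.ndarray  # uint8, same shape as source counts
    markers: tuple[str, ...]
    coords: pd.DataFrame
    alpha_bin: float
    lambdas: pd.Series  # per-marker trimmed-mean rate used for coding


@dataclass(frozen=True)
class RatioTable:
    """Sections x markers positive-bin ratios with group labels."""

    ratios: pd.DataFrame  # index = section_id, columns = markers
    groups: pd.Series  # index = section_id -> group label

    def __post_init__(self) -> None:
        vals = self.ratios.to_numpy()
        if vals.size and ((vals < 0).any() or (vals > 1).any()):
            raise ValueError("ratios must lie in [0, 1]")


@dataclass(frozen=True)
class DifferentialResult:
    """Per-marker ANOVA screen with BH correction and Tukey post hocs."""

    by_label: pd.DataFrame  # marker, F, p_raw, p_bh, differential, testable
    tukey: pd.DataFrame  # marker, group1, group2, meandiff, p_adj, lower, upper
    alpha_label: float

    @property
    def differential_markers(self) -> list[str]:
        return list(self.by_label.loc[self.by_label["differential"], "marker"])


def trimmed_mean_lambda(
    matrix: PseudoCountMatrix, trim: float = TRIM_DEFAULT
) -> pd.Series:
    """Per-marker trimmed mean pseudo-count over non-missing bins.

    ``floor(trim * n)`` smallest and largest values are dropped on each
    side before averaging (the convention of R's ``mean(trim=)``).

    Raises
    ------
    ValueError
        If ``trim`` is outside [0, 0.5) or a marker has no non-missing bins.
    """
    if not 0.0 <= trim < 0.5:
        raise ValueError(f"trim must be in [0, 0.5), got {trim}")
    out = {}
    for j, m in enumerate(matrix.markers):
        vals = matrix.counts[:, j]
        vals = np.sort(vals[~np.isnan(vals)])
        if vals.size == 0:
            raise ValueError(
                f"marker {m!r}: all bins MISSING, trimmed mean undefined"
            )
        k = int(np.floor(trim * vals.size))
        kept = vals[k : vals.size - k] if k else vals
        out[m] = float(kept.mean())
    return pd.Series(out, name="lambda")


def poisson_upper_tail(count, lam) -> np.ndarray | float:
    """Strict upper-tail Poisson probability ``P(X > count)``.

    Vectorised over ``count`` and ``lam``; NaN counts give NaN.
    """
    count = np.asarray(count, dtype=float)
    p = np.where(np.isnan(count), np.nan, stats.poisson.sf(count, np.asarray(lam, float)))
    return p if p.ndim else float(p)


def code_bins(
    matrix: PseudoCountMatrix,
    lambdas: pd.Series | None = None,
    alpha_bin: float = ALPHA_BIN_DEFAULT,
    group: str = "",
    trim: float = TRIM_DEFAULT,
) -> BinaryCoding:
    """Code each bin 1 iff its strict Poisson upper-tail p is below alpha_bin.

    MISSING pseudo-counts code to 0.  ``lambdas`` defaults to the
    per-marker trimmed means of ``matrix`` itself.
    """
    if lambdas is None:
        lambdas = trimmed_mean_lambda(matrix, trim=trim)
    lam = lambdas.reindex(list(matrix.markers)).to_numpy(dtype=float)
    p = stats.poisson.sf(np.nan_to_num(matrix.counts, nan=0.0), lam[None, :])
    coded = (p < alpha_bin) & ~np.isnan(matrix.counts)
    return BinaryCoding(
        section_id=matrix.section_id,
        group=group,
        values=coded.astype(np.uint8),
        markers=matrix.markers,
        coords=matrix.coords,
        alpha_bin=alpha_bin,
        lambdas=lambdas,
    )


def label_ratios(codings: list[BinaryCoding]) -> RatioTable:
    """Positive-bin ratio per section and marker.

    The denominator is the full grid size of each section, including bins
    that were MISSING for the marker.
    """
    if not codings:
        raise ValueError("need at least one section coding")
    markers = codings[0].markers
    rows, groups = {}, {}
    for c in codings:
        if c.markers != markers:
            raise ValueError("codings disagree in marker order")
        rows[c.section_id] = c.values.sum(axis=0) / c.values.shape[0]
        groups[c.section_id] = c.group
    ratios = pd.DataFrame.from_dict(rows, orient="index", columns=list(markers))
    return RatioTable(ratios=ratios, groups=pd.Series(groups, name="group"))


def anova_by_label(
    ratios: RatioTable,
    alpha_label: float = ALPHA_LABEL_DEFAULT,
    flag_on_adjusted: bool = False,
) -> DifferentialResult:
    """One-way ANOVA per marker on positive-bin ratios across groups.

    Raw p-values are BH-adjusted across markers; Tukey HSD pairwise
    comparisons (Tukey-Kramer for unequal n) are computed for every
    testable marker.  The differential flag uses raw p < ``alpha_label``
    by default (set ``flag_on_adjusted`` to flag on BH-adjusted p).

    Markers whose ratios are identical in every section have no defined F
    statistic and are reported as untestable rather than significant.
    """
    grp = ratios.groups
    levels = list(dict.fromkeys(grp))
    if len(levels) < 2:
        raise ValueError("need >=2 groups for ANOVA")
    records, tukey_rows = [], []
    for m in ratios.ratios.columns:
        vals = ratios.ratios[m]
        samples = [vals[grp == g].to_numpy() for g in levels]
        if np.ptp(vals.to_numpy()) == 0.0:
            records.append((m, np.nan, np.nan, False))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, p = stats.f_oneway(*samples)
        if np.isnan(F):
            records.append((m, np.nan, np.nan, False))
            continue
        records.append((m, float(F), float(p), True))
        try:
            res = pairwise_tukeyhsd(vals.to_numpy(), grp.to_numpy(), alpha=0.05)
            tuk = pd.DataFrame(
                res.summary().data[1:],
                columns=[c.strip() for c in res.summary().data[0]],
            )
            for _, r in tuk.iterrows():
                tukey_rows.append(
                    (m, r["group1"], r["group2"], float(r["meandiff"]),
                     float(r["p-adj"]), float(r["lower"]), float(r["upper"]))
                )
        except Exception:  # degenerate layouts (e.g. n=1 groups)
            pass
    by_label = pd.DataFrame(records, columns=["marker", "F", "p_raw", "testable"])
    p_bh = np.full(len(by_label), np.nan)
    mask = by_label["testable"].to_numpy()
    if mask.any():
        p_bh[mask] = multipletests(by_label.loc[mask, "p_raw"], method="fdr_bh")[1]
    by_label["p_bh"] = p_bh
    key = "p_bh" if flag_on_adjusted else "p_raw"
    by_label["differential"] = (by_label[key] < alpha_label).fillna(False)
    tukey = pd.DataFrame(
        tukey_rows,
        columns=["marker", "group1", "group2", "meandiff", "p_adj", "lower", "upper"],
    )
    return DifferentialResult(by_label=by_label, tukey=tukey, alpha_label=alpha_label)


def case_pca(
    ratios: RatioTable,
    result: DifferentialResult | None = None,
    differential_only: bool = False,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Covariance-based PCA of sections on their positive-bin ratios.

    Columns are centred but not variance-scaled (the ``prcomp`` default).
    Returns (scores, explained) where ``scores`` holds the first two
    component scores per section plus group labels, and ``explained`` the
    explained-variance fractions of those components.
    """
    X = ratios.ratios
    if differential_only:
        if result is None:
            raise ValueError("differential_only requires a DifferentialResult")
        keep = result.differential_markers
        if not keep:
            raise ValueError("no differential markers to project")
        X = X[keep]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sections for PCA")
    k = min(2, n - 1, X.shape[1]) or 1
    pca = PCA(n_components=k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Z = pca.fit_transform(X.to_numpy())
    scores = pd.DataFrame(index=X.index)
    scores["PC1"] = Z[:, 0]
    scores["PC2"] = Z[:, 1] if k > 1 else 0.0
    scores["group"] = ratios.groups.reindex(X.index)
    total = pca.explained_variance_.sum()
    if total > 0:
        explained = pca.explained_variance_ratio_[:2]
    else:  # all sections identical: scores are all zero
        explained = np.zeros(min(2, k))
    return scores, explained


def plot_ratio_heatmap(ratios: RatioTable, ax=None):
    """Clustered heat map of the sections x markers ratio matrix."""
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list, linkage

    X = ratios.ratios
    row_order = (
        leaves_list(linkage(X.to_numpy(), method="average")) if len(X) > 2
        else range(len(X))
    )
    X = X.iloc[list(row_order)]
    if ax is None:
        fig, ax = plt.subplots(figsize=(1 + 0.4 * X.shape[1], 1 + 0.3 * X.shape[0]))
    else:
        fig = ax.figure
    im = ax.imshow(X.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(X.shape[1]), X.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(X.shape[0]),
                  [f"{s} ({ratios.groups[s]})" for s in X.index], fontsize=7)
    fig.colorbar(im, ax=ax, label="positive-bin ratio")
    return fig


def plot_case_pca(scores: pd.DataFrame, explained: np.ndarray, ax=None):
    """Scatter of section scores on the first two principal components."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    for g, sub in scores.groupby("group"):
        ax.scatter(sub["PC1"], sub["PC2"], label=g)
    for sec, row in scores.iterrows():
        ax.annotate(str(sec), (row["PC1"], row["PC2"]), fontsize=6)
    pct = [f"{100 * e:.1f}%" for e in explained] + ["0%"] * 2
    ax.set_xlabel(f"PC1 ({pct[0]})")
    ax.set_ylabel(f"PC2 ({pct[1]})")
    ax.legend(title="group")
    return fig
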