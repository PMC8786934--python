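"""Marker co-occurrence string analysis.

Every bin's 0/1 marker coding is concatenated (in ``marker_order``) into
a binary string — identical strings denote identical marker
co-occurrence signatures.  String frequencies per section are tested
across groups with Kruskal-Wallis (tie-corrected) and Dunn post hocs;
strings with raw KW p < 0.05 are flagged differential.  Flagged strings
can be filtered by a marker of interest (e.g. tau) and mapped back to
tissue space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from binplex.differential import BinaryCoding

logger = logging.getLogger(__name__)

ALPHA_STRING_DEFAULT = 0.05
MIN_TOTAL_COUNT_DEFAULT = 10


@dataclass(frozen=True)
class StringFrequencyTable:
    """Sections x strings integer counts (zero-filled for absent strings)."""

    counts: pd.DataFrame  # index = section_id, columns = strings
    groups: pd.Series  # section_id -> group
    markers: tuple[str, ...]


@dataclass(frozen=True)
class StringTestResult:
    """Kruskal-Wallis screen per string with Dunn pairwise post hocs."""

    by_string: pd.DataFrame  # string, H, p_raw, p_bh, differential
    dunn: pd.DataFrame  # string, group1, group2, z, p, p_bh
    markers: tuple[str, ...]
    alpha: float

    @property
    def differential_strings(self) -> list[str]:
        return list(self.by_string.loc[self.by_string["differential"], "string"])


def encode_strings(coding: BinaryCoding) -> pd.Series:
    """Per-bin binary string; character i follows ``marker_order``."""
    chars = coding.values.astype("U1")
    joined = np.apply_along_axis("".join, 1, chars) if chars.size else np.array([], "U1")
    return pd.Series(joined, name="string")


def tally_strings(codings: list[BinaryCoding]) -> StringFrequencyTable:
    """Count each observed string per section; absent strings count 0."""
    if not codings:
        raise ValueError("need at least one section coding")
    markers = codings[0].markers
    rows, groups = {}, {}
    for c in codings:
        if c.markers != markers:
            raise ValueError("codings disagree in marker order")
        rows[c.section_id] = encode_strings(c).value_counts()
        groups[c.section_id] = c.group
    counts = (
        pd.DataFrame.from_dict(rows, orient="index")
        .fillna(0)
        .astype(int)
        .sort_index(axis=1)
    )
    return StringFrequencyTable(
        counts=counts, groups=pd.Series(groups, name="group"), markers=markers
    )


def _dunn_pairwise(samples: dict[str, np.ndarray]) -> list[tuple[str, str, float, float]]:
    """Dunn's post hoc z tests on pooled ranks with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups; two-sided normal p.
    """
    names = list(samples)
    pooled = np.concatenate([samples[g] for g in names])
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank, i = {}, 0
    for g in names:
        n = samples[g].size
        mean_rank[g] = ranks[i : i + n].mean()
        i += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    T = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)) if N > 1 else 0.0
    var_term = N * (N + 1) / 12.0 - T
    out = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            g1, g2 = names[a], names[b]
            se2 = var_term * (1.0 / samples[g1].size + 1.0 / samples[g2].size)
            if se2 <= 0:
                z, p = 0.0, 1.0
            else:
                z = (mean_rank[g1] - mean_rank[g2]) / np.sqrt(se2)
                p = 2.0 * stats.norm.sf(abs(z))
            out.append((g1, g2, float(z), float(p)))
    return out


def kruskal_dunn_by_string(
    freqs: StringFrequencyTable,
    alpha: float = ALPHA_STRING_DEFAULT,
    min_total_count: int = MIN_TOTAL_COUNT_DEFAULT,
    normalize_by_total: bool = False,
) -> StringTestResult:
    """Kruskal-Wallis per string on per-section counts grouped by cohort group.

    Tie-corrected H; a string with identical counts in every section gets
    H = 0, p = 1.  Strings observed in fewer than ``min_total_count``
    bins in total are excluded (logged), guarding against the
    combinatorial tail of rare signatures.  ``normalize_by_total``
    divides each section's counts by its total bin count before testing.
    """
    grp = freqs.groups
    levels = list(dict.fromkeys(grp))
    if len(levels) < 2:
        raise ValueError("need >=2 groups for Kruskal-Wallis")
    counts = freqs.counts
    data = counts.div(counts.sum(axis=1), axis=0) if normalize_by_total else counts
    records, dunn_rows = [], []
    n_skipped = 0
    for s in counts.columns:
        if counts[s].sum() < min_total_count:
            n_skipped += 1
            continue
        vals = data[s]
        samples = {g: vals[grp == g].to_numpy(dtype=float) for g in levels}
        if np.ptp(vals.to_numpy()) == 0.0:
            records.append((s, 0.0, 1.0))
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                H, p = stats.kruskal(*samples.values())
            records.append((s, float(H), float(p)))
        for g1, g2, z, p_pair in _dunn_pairwise(samples):
            dunn_rows.append((s, g1, g2, z, p_pair))
    if n_skipped:
        logger.info(
            "excluded %d rare strings (< %d total bins) from testing",
            n_skipped, min_total_count,
        )
    by_string = pd.DataFrame(records, columns=["string", "H", "p_raw"])
    by_string["p_bh"] = (
        multipletests(by_string["p_raw"], method="fdr_bh")[1]
        if len(by_string)
        else np.array([])
    )
    by_string["differential"] = by_string["p_raw"] < alpha
    dunn = pd.DataFrame(dunn_rows, columns=["string", "group1", "group2", "z", "p"])
    dunn["p_bh"] = multipletests(dunn["p"], method="fdr_bh")[1] if len(dunn) else np.array([])
    return StringTestResult(
        by_string=by_string, dunn=dunn, markers=freqs.markers, alpha=alpha
    )


def filter_strings_by_marker(
    result: StringTestResult, marker: str, present: bool = True
) -> StringTestResult:
    """Keep strings whose character at ``marker``'s position is '1' (or '0')."""
    if marker not in result.markers:
        raise ValueError(f"unknown marker {marker!r}; have {list(result.markers)}")
    pos = result.markers.index(marker)
    want = "1" if present else "0"
    keep = result.by_string["string"].str[pos] == want
    strings = set(result.by_string.loc[keep, "string"])
    return StringTestResult(
        by_string=result.by_string.loc[keep].reset_index(drop=True),
        dunn=result.dunn.loc[result.dunn["string"].isin(strings)].reset_index(drop=True),
        markers=result.markers,
        alpha=result.alpha,
    )


def string_bin_table(coding: BinaryCoding, selected: list[str]) -> pd.DataFrame:
    """Per-bin table (bin_row, bin_col, x_um, y_um, string) for selected strings."""
    strings = encode_strings(coding)
    mask = strings.isin(selected).to_numpy()
    df = coding.coords.loc[mask].copy()
    df["string"] = strings.to_numpy()[mask]
    return df.reset_index(drop=True)


def plot_string_bins(
    coding: BinaryCoding, selected: list[str], ax=None
) -> tuple["object", pd.DataFrame]:
    """Plot bins carrying the selected strings in image space.

    One colour per unique string; y is flipped for display so the image
    origin (top-left) appears at the top.  Returns (figure, table); an
    empty selection yields a blank figure and an empty table (warning
    logged).
    """
    import matplotlib.pyplot as plt

    table = string_bin_table(coding, selected)
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        fig = ax.figure
    if table.empty:
        logger.warning(
            "no bins carry the selected strings in section %s", coding.section_id
        )
    else:
        for s, sub in table.groupby("string"):
            ax.scatter(sub["x_um"], sub["y_um"], s=12, marker="s", label=s)
        ax.legend(fontsize=6, title="string")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"section {coding.section_id}")
    ax.invert_yaxis()
    ax.set_aspect("equal")
    return fig, table


def string_composition_matrix(selected: list[str], markers: tuple[str, ...]) -> pd.DataFrame:
    """Markers x strings 0/1 membership matrix, hierarchically ordered.

    Rows and columns are ordered by average-linkage clustering on Jaccard
    distance when there is more than one string (single strings and
    single markers keep their input order).
    """
    if not selected:
        raise ValueError("need at least one selected string")
    if any(len(s) != len(markers) for s in selected):
        raise ValueError("string length must equal number of markers")
    mat = pd.DataFrame(
        {s: [int(ch) for ch in s] for s in selected}, index=list(markers)
    )

    def _order(frame: pd.DataFrame, axis: int) -> list:
        labels = frame.columns if axis == 1 else frame.index
        if len(labels) < 3:
            return list(labels)
        X = (frame.T if axis == 1 else frame).to_numpy(dtype=bool)
        with np.errstate(invalid="ignore"):
            d = pdist(X, metric="jaccard")
        d = np.nan_to_num(d, nan=1.0)
        return [labels[i] for i in leaves_list(linkage(d, method="average"))]

    if len(selected) > 1:
        mat = mat.loc[_order(mat, axis=0), _order(mat, axis=1)]
    return mat


def string_composition_heatmap(
    selected: list[str], markers: tuple[str, ...], ax=None
) -> tuple["object", pd.DataFrame]:
    """Heat map of the marker x string membership matrix (plus the matrix)."""
    import matplotlib.pyplot as plt

    mat = string_composition_matrix(selected, markers)
    if ax is None:
        fig, ax = plt.subplots(figsize=(1 + 0.4 * mat.shape[1], 1 + 0.3 * mat.shape[0]))
    else:
        fig = ax.figure
    ax.imshow(mat.to_numpy(), cmap="Greys", aspect="auto", vmin=0, vmax=1)
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=7)
    ax.set_xlabel("string")
    return fig, mat
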