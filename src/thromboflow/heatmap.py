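"""Comparative heatmap statistics for the multiparameter assay.

The phenotyping workflow compares parameter sets across surfaces and
conditions on a common scale: per parameter, mean values are linearly scaled
to 0-10 across the comparison set; scaled matrices are subtracted cellwise
to visualize intervention effects; differences are kept only when they fall
outside a mean +/- SD relevance band; retained effects can be summed into a
single "summed scaled effect" per contrast.  Rows are ordered by
agglomerative clustering (Euclidean distance, complete linkage), and
donor-wise correlation across surfaces quantifies how reproducible a
thrombus signature is between related coatings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "ScaledMatrix",
    "RelevanceFilteredDiff",
    "scale_rows",
    "subtraction_heatmap",
    "interval_deltas",
    "summed_scaled_effect",
    "cluster_rows",
    "correlate_surfaces",
    "render_heatmap",
]

SCALE_MAX = 10.0


@dataclass
class ScaledMatrix:
    """Row-wise 0-10 scaled table with its scaling provenance.

    Each row's minimum maps to 0 and maximum to 10; constant rows map to
    all-0 and are flagged.  The original (min, max) per row makes the
    transform invertible.
    """

    data: pd.DataFrame
    row_min: pd.Series
    row_max: pd.Series
    constant_rows: pd.Series  # bool per row

    def inverse(self) -> pd.DataFrame:
        """Recover the original values (constant rows return their min)."""
        span = (self.row_max - self.row_min).replace(0.0, np.nan)
        raw = self.data.mul(span / SCALE_MAX, axis=0).add(self.row_min, axis=0)
        const = self.constant_rows[self.constant_rows].index
        raw.loc[const] = np.broadcast_to(
            self.row_min.loc[const].to_numpy()[:, None], raw.loc[const].shape
        )
        return raw


def scale_rows(table: pd.DataFrame) -> ScaledMatrix:
    """Linearly scale each row of *table* to the 0-10 range.

    x -> 10 * (x - min) / (max - min) per row.  Requires at least two
    columns; an empty table raises.
    """
    if table.size == 0:
        raise ValueError("cannot scale an empty table")
    if table.shape[1] < 2:
        raise ValueError("need at least 2 columns per row to scale")
    row_min = table.min(axis=1)
    row_max = table.max(axis=1)
    span = row_max - row_min
    constant = span == 0
    safe_span = span.replace(0.0, 1.0)
    scaled = table.sub(row_min, axis=0).div(safe_span, axis=0) * SCALE_MAX
    scaled.loc[constant] = 0.0
    return ScaledMatrix(scaled, row_min, row_max, constant)


@dataclass
class RelevanceFilteredDiff:
    """Cellwise difference retained only outside the mean +/- SD band.

    Nonzero cells satisfy |delta - band_mean| > band_sd exactly; positive
    retained values are relevant increases, negative ones relevant
    decreases.
    """

    delta: pd.DataFrame  # filtered differences (0 where irrelevant)
    raw_delta: pd.DataFrame
    band_mean: pd.DataFrame | float
    band_sd: pd.DataFrame | float

    @property
    def retained_mask(self) -> pd.DataFrame:
        return self.delta != 0.0


def subtraction_heatmap(
    scaled_a: ScaledMatrix | pd.DataFrame,
    scaled_b: ScaledMatrix | pd.DataFrame,
    band_sd: pd.DataFrame | float = 0.0,
    band_mean: pd.DataFrame | float = 0.0,
) -> RelevanceFilteredDiff:
    """Relevance-filtered subtraction heatmap: delta = A - B, cellwise.

    Cells with |delta - band_mean| <= band_sd are zeroed (irrelevant); the
    default band (mean 0, SD 0) keeps every nonzero difference.  The band is
    typically the replicate mean/SD of the reference condition.
    """
    a = scaled_a.data if isinstance(scaled_a, ScaledMatrix) else scaled_a
    b = scaled_b.data if isinstance(scaled_b, ScaledMatrix) else scaled_b
    if a.shape != b.shape:
        raise ValueError("matrices must have matching shapes")
    delta = a - b.to_numpy()
    mean = band_mean if np.isscalar(band_mean) else band_mean.to_numpy()
    sd = band_sd if np.isscalar(band_sd) else band_sd.to_numpy()
    outside = (delta - mean).abs() > sd
    return RelevanceFilteredDiff(delta.where(outside, 0.0), delta, band_mean, band_sd)


def interval_deltas(
    frame: pd.DataFrame,
    anchors: tuple[float, float, float] = (0.0, 4.0, 8.0),
    value: str = "value",
) -> pd.DataFrame:
    """Early vs late increase per parameter: dt1 = v(4) - v(0), dt2 = v(8) - v(4).

    *frame* is a tidy table with columns (parameter, time, value[, group
    columns]); deltas are computed within each group x parameter.  Missing
    anchor times leave the cell absent (NaN).
    """
    t0, t1, t2 = anchors
    group_cols = [
        c for c in frame.columns if c not in ("time", value)
    ]
    wide = frame.pivot_table(index=group_cols, columns="time", values=value, aggfunc="mean")
    wide.columns = wide.columns.astype(float)
    out = pd.DataFrame(index=wide.index)
    out["dt1"] = wide.get(t1) - wide.get(t0) if t1 in wide and t0 in wide else np.nan
    out["dt2"] = wide.get(t2) - wide.get(t1) if t2 in wide and t1 in wide else np.nan
    return out.reset_index()


def summed_scaled_effect(
    diff: RelevanceFilteredDiff,
    rows: list | pd.Index | None = None,
    cols: list | pd.Index | None = None,
) -> float:
    """Sum of retained signed scaled differences over a scope.

    The scope (row and column subsets) must be explicit and non-empty: the
    quantity only has meaning for a stated set of parameters x time points
    of one surface/condition contrast.
    """
    sub = diff.delta
    if rows is not None:
        if len(rows) == 0:
            raise ValueError("row scope must be non-empty")
        sub = sub.loc[rows]
    if cols is not None:
        if len(cols) == 0:
            raise ValueError("column scope must be non-empty")
        sub = sub[cols]
    if sub.size == 0:
        raise ValueError("scope selects no cells")
    return float(sub.to_numpy().sum())


@dataclass
class RowClustering:
    linkage: np.ndarray  # scipy linkage matrix
    order: list  # row labels in dendrogram leaf order
    labels: list


def cluster_rows(matrix: ScaledMatrix | pd.DataFrame) -> RowClustering:
    """Agglomerative clustering of rows: Euclidean metric, complete linkage.

    Deterministic: scipy's implementation breaks distance ties by lowest
    cluster index.  Rows containing missing values raise (impute first).
    """
    data = matrix.data if isinstance(matrix, ScaledMatrix) else matrix
    if data.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if data.isna().any().any():
        raise ValueError("matrix contains missing values; impute before clustering")
    z = hierarchy.linkage(pdist(data.to_numpy(), metric="euclidean"), method="complete")
    leaves = hierarchy.leaves_list(z)
    labels = list(data.index)
    return RowClustering(z, [labels[i] for i in leaves], labels)


def linkage_to_newick(clustering: RowClustering) -> str:
    """Serialize a row clustering as a Newick tree with branch heights."""
    z = clustering.linkage
    labels = [str(label) for label in clustering.labels]
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (i, j, h, _) in enumerate(z):
        i, j = int(i), int(j)
        left = f"{nodes[i]}:{h - heights[i]:.6g}"
        right = f"{nodes[j]}:{h - heights[j]:.6g}"
        nodes[n + k] = f"({left},{right})"
        heights[n + k] = h
    return nodes[n + len(z) - 1] + ";"


def correlate_surfaces(
    frame_a: pd.DataFrame,
    frame_b: pd.DataFrame,
    subject: str = "subject",
    value: str = "value",
) -> pd.DataFrame:
    """Pearson correlation per (parameter, time) cell, pairing subjects
    across two surfaces.

    Returns a table keyed by parameter and time with columns (r, p, n);
    cells with fewer than 3 paired subjects or zero variance report NaN.
    """
    keys = ["parameter", "time"]
    a = frame_a.set_index(keys + [subject])[value]
    b = frame_b.set_index(keys + [subject])[value]
    rows = []
    cells = sorted(
        set(a.index.droplevel(subject)) & set(b.index.droplevel(subject)),
        key=lambda c: (str(c[0]), float(c[1]) if pd.notna(c[1]) else -1.0),
    )
    for cell in cells:
        xa = a.loc[cell]
        xb = b.loc[cell]
        common = xa.index.intersection(xb.index)
        va, vb = xa.loc[common].to_numpy(float), xb.loc[common].to_numpy(float)
        if len(common) < 3 or va.std() == 0 or vb.std() == 0:
            r = p = np.nan
        else:
            r, p = stats.pearsonr(va, vb)
        rows.append(
            {"parameter": cell[0], "time": cell[1], "r": r, "p": p, "n": len(common)}
        )
    return pd.DataFrame(rows)


def render_heatmap(
    diff: RelevanceFilteredDiff | pd.DataFrame, path: str, title: str = ""
) -> None:
    """Render a subtraction heatmap to PNG/SVG.

    Convention: green = relevant decrease, red = relevant increase, white =
    filtered / no change.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = diff.delta if isinstance(diff, RelevanceFilteredDiff) else diff
    vmax = max(1e-9, float(np.abs(data.to_numpy()).max()))
    fig, ax = plt.subplots(
        figsize=(max(4, 0.35 * data.shape[1]), max(3, 0.3 * data.shape[0]))
    )
    im = ax.imshow(data.to_numpy(), cmap="PiYG_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels([str(c) for c in data.columns], rotation=90, fontsize=6)
    ax.set_yticks(range(data.shape[0]))
    ax.set_yticklabels([str(i) for i in data.index], fontsize=6)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
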