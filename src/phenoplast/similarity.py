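"""Pairwise phenotype similarity: correlation matrix, ordering, grouping.

Entities (subclusters or individual animals, each summarized by its vector
of plasticity features) are compared by Pearson correlation across
features.  The correlation matrix is then ordered by hierarchical
clustering of the **rows of the r matrix** under Euclidean distance (the
original workflow's convention — not 1−r, though that metric is available)
with complete linkage (Ward.D2 selectable), and cut into a user-chosen
number of groups by descending merge height.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .expression_io import PhenoplastError

LINKAGE_METHODS = {"complete": "complete", "ward.d2": "ward"}


@dataclass
class CorrelationStructure:
    labels: list[str]
    r: pd.DataFrame
    linkage_method: str
    merge_children: np.ndarray  # scipy linkage matrix (n-1 x 4)
    merge_heights: np.ndarray
    leaf_order: list[int]
    groups: pd.Series  # entity -> group id (1..n_groups)


def correlation_matrix(vectors: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between every pair of entity rows, across feature columns."""
    values = vectors.to_numpy(dtype=float)
    if values.shape[1] < 3:
        raise PhenoplastError("need at least 3 feature columns for correlations")
    if np.isnan(values).any():
        raise PhenoplastError("entity vectors contain missing values")
    sds = values.std(axis=1)
    if np.any(sds == 0):
        bad = [vectors.index[i] for i in np.where(sds == 0)[0]]
        raise PhenoplastError(f"constant entity rows (correlation undefined): {bad}")
    r = np.corrcoef(values)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=vectors.index, columns=vectors.index)


def order_and_cut(
    r: pd.DataFrame,
    linkage: str = "complete",
    n_groups: int = 2,
    distance: str = "rows-of-r",
) -> CorrelationStructure:
    """Hierarchically order the correlation matrix and cut into groups.

    Distances are Euclidean between rows of r (default) or 1−r; the tree is
    cut into ``n_groups`` by descending merge height (scipy ``maxclust``).
    """
    if linkage not in LINKAGE_METHODS:
        raise PhenoplastError(f"unknown linkage: {linkage}")
    n = r.shape[0]
    if not (1 <= n_groups <= n):
        raise PhenoplastError(f"n_groups must be in [1, {n}]")
    if distance == "rows-of-r":
        d = pdist(r.to_numpy(dtype=float), metric="euclidean")
    elif distance == "one-minus-r":
        d = squareform(1.0 - r.to_numpy(dtype=float), checks=False)
    else:
        raise PhenoplastError(f"unknown distance: {distance}")
    Z = hierarchy.linkage(d, method=LINKAGE_METHODS[linkage])
    leaf_order = list(hierarchy.leaves_list(Z))
    cut = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
    return CorrelationStructure(
        labels=list(map(str, r.index)),
        r=r,
        linkage_method=linkage,
        merge_children=Z,
        merge_heights=Z[:, 2].copy(),
        leaf_order=leaf_order,
        groups=pd.Series(cut, index=r.index, name="group"),
    )


def dendrogram_dict(structure: CorrelationStructure) -> dict:
    """JSON-serializable merge tree (children, heights, leaf order)."""
    return {
        "labels": structure.labels,
        "children": structure.merge_children[:, :2].astype(int).tolist(),
        "heights": structure.merge_heights.tolist(),
        "leaf_order": [int(i) for i in structure.leaf_order],
        "groups": {str(k): int(v) for k, v in structure.groups.items()},
        "linkage": structure.linkage_method,
    }


def render_corr_heatmap(
    structure: CorrelationStructure,
    path,
    condition_colors: dict | None = None,
) -> None:
    """Correlation heatmap in leaf order with a dendrogram margin and black
    separators at group boundaries; leaf tips colored by entity condition."""
    order = structure.leaf_order
    r = structure.r.to_numpy(dtype=float)[np.ix_(order, order)]
    labels = [structure.labels[i] for i in order]
    groups = structure.groups.to_numpy()[order]

    fig = plt.figure(figsize=(2.2 + 0.35 * len(labels), 1.2 + 0.35 * len(labels)))
    ax_dendro = fig.add_axes([0.05, 0.76, 0.9, 0.2])
    with plt.rc_context({"lines.linewidth": 0.8}):
        hierarchy.dendrogram(
            structure.merge_children, ax=ax_dendro, no_labels=True,
            color_threshold=0, above_threshold_color="black",
        )
    ax_dendro.axis("off")
    ax = fig.add_axes([0.05, 0.05, 0.9, 0.68])
    ax.imshow(r, cmap="RdYlGn", vmin=-1, vmax=1, aspect="auto")
    # black separators at group boundaries along both axes
    for i in range(1, len(labels)):
        if groups[i] != groups[i - 1]:
            ax.axhline(i - 0.5, color="black", lw=1.5)
            ax.axvline(i - 0.5, color="black", lw=1.5)
    ax.set_xticks(range(len(labels)))
    ax.set_yticks(range(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_yticklabels(labels, fontsize=6)
    if condition_colors:
        for tick, label in zip(ax.get_yticklabels(), labels):
            for cond, color in condition_colors.items():
                if label.startswith(cond):
                    tick.set_color(color)
    plt.rcParams["svg.hashsalt"] = "phenoplast"
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
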