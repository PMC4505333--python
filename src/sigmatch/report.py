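"""Ranking perturbations against a query condition and clustering the distance matrix."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .distance import DistanceMatrix

__all__ = ["rank_perturbations", "cluster_distance_matrix", "plot_heatmap"]


def rank_perturbations(dm: DistanceMatrix, query_label: str) -> pd.DataFrame:
    """All non-query conditions sorted by ascending distance to the query.

    Small distance means the perturbation's transcriptional response
    resembles the query condition's.  Ties are broken by label ascending.
    Returns a DataFrame with columns ``condition`` and ``distance``.
    """
    if query_label not in dm.labels:
        raise KeyError(f"unknown query label: {query_label!r}")
    qi = dm.labels.index(query_label)
    rows = pd.DataFrame(
        {
            "condition": [lab for lab in dm.labels if lab != query_label],
            "distance": [dm.values[qi, j] for j, lab in enumerate(dm.labels) if lab != query_label],
        }
    )
    return rows.sort_values(["distance", "condition"], kind="stable").reset_index(drop=True)


def cluster_distance_matrix(dm: DistanceMatrix) -> tuple[np.ndarray, list[str]]:
    """Average-linkage (UPGMA) clustering on a precomputed dissimilarity.

    Returns the scipy linkage table — rows of (member_a, member_b, height,
    size) — and the dendrogram leaf labels left to right.
    """
    if len(dm.labels) < 2:
        raise ValueError("at least two conditions are required")
    condensed = squareform(dm.values, checks=True)
    linkage = hierarchy.linkage(condensed, method="average")
    leaves = hierarchy.leaves_list(linkage)
    return linkage, [dm.labels[i] for i in leaves]


def plot_heatmap(dm: DistanceMatrix, path: str | Path) -> None:
    """Static clustered heat map of the distance matrix (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    linkage, leaf_labels = cluster_distance_matrix(dm)
    order = [dm.labels.index(lab) for lab in leaf_labels]
    values = dm.values[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(max(4, len(order) * 0.3),) * 2)
    im = ax.imshow(values, cmap="viridis", vmin=0, vmax=2)
    ax.set_xticks(range(len(order)), leaf_labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(order)), leaf_labels, fontsize=6)
    fig.colorbar(im, ax=ax, label="GSEA distance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
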