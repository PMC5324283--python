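"""Hierarchical clustering of samples on the extreme-PIF panel.

After row-normalising the 40-gene panel matrix, samples are clustered
agglomeratively and the tree is cut at k = 2; purity against the known
treatment groups measures whether expression of the panel alone can
re-discover the design. Within-group mean pairwise distances ("dispersion")
compare the tightness of the two groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .matrices import ValidationError

DISTANCES = ("euclidean", "pearson")
LINKAGES = ("average", "complete", "ward")


def row_normalize(panel_matrix: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Centre each gene row to mean 0 and scale to unit (population) SD."""
    if panel_matrix.shape[1] < 2:
        raise ValidationError("need at least 2 columns to row-normalise")
    vals = panel_matrix.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=ddof, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        genes = list(panel_matrix.index[flat])
        raise ValidationError(f"zero-variance rows cannot be normalised: {genes[:10]}")
    return pd.DataFrame(
        (vals - mu) / sd, index=panel_matrix.index, columns=panel_matrix.columns
    )


def _sample_distances(panel_matrix: pd.DataFrame, distance: str) -> np.ndarray:
    cols = panel_matrix.to_numpy(dtype=float).T  # samples x genes
    if distance == "euclidean":
        return pdist(cols, metric="euclidean")
    # Pearson correlation distance 1 - r between sample profiles
    return pdist(cols, metric="correlation")


@dataclass
class ClusterReport:
    linkage_tree: str  # Newick with branch lengths
    assignment: dict[str, int]  # sample -> cluster id at k=2
    purity: float
    dispersion: dict[str, float]  # group -> mean pairwise within-group distance
    distance: str
    linkage: str

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.__dict__, indent=2, **kwargs)


def _newick(node, labels: list[str], parent_height: float | None = None) -> str:
    length = (
        "" if parent_height is None else f":{max(parent_height - node.dist, 0.0):.6g}"
    )
    if node.is_leaf():
        return f"{labels[node.id]}{length}"
    left = _newick(node.left, labels, node.dist)
    right = _newick(node.right, labels, node.dist)
    return f"({left},{right}){length}"


def cluster_samples(
    panel_matrix: pd.DataFrame,
    groups: pd.Series,
    distance: str = "pearson",
    linkage_method: str = "average",
) -> ClusterReport:
    """Agglomeratively cluster the columns (samples) of a panel matrix.

    Deterministic given its inputs; scipy breaks merge ties by cluster index.
    Ward linkage requires euclidean distances.
    """
    if distance not in DISTANCES:
        raise ValidationError(f"distance must be one of {DISTANCES}, got {distance!r}")
    if linkage_method not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}, got {linkage_method!r}")
    if linkage_method == "ward" and distance != "euclidean":
        raise ValidationError("ward linkage requires euclidean distance")
    n_s = panel_matrix.shape[1]
    if n_s < 3:
        raise ValidationError("need at least 3 samples to cluster")
    cond = _sample_distances(panel_matrix, distance)
    Z = linkage(cond, method=linkage_method)
    labels = fcluster(Z, t=2, criterion="maxclust")
    samples = list(panel_matrix.columns)
    assignment = {s: int(c) for s, c in zip(samples, labels)}

    grp = groups.reindex(samples)
    if grp.isna().any():
        raise ValidationError("every sample needs a group label")
    correct = 0
    for c in set(labels):
        members = grp[labels == c]
        correct += members.value_counts().max()
    purity = correct / n_s

    dmat = squareform(cond)
    dispersion: dict[str, float] = {}
    for g in sorted(grp.unique()):
        idx = np.flatnonzero((grp == g).to_numpy())
        if len(idx) < 2:
            dispersion[g] = float("nan")
            continue
        sub = dmat[np.ix_(idx, idx)]
        dispersion[g] = float(sub[np.triu_indices(len(idx), k=1)].mean())

    tree = to_tree(Z)
    newick = _newick(tree, samples) + ";"
    return ClusterReport(
        linkage_tree=newick,
        assignment=assignment,
        purity=float(purity),
        dispersion=dispersion,
        distance=distance,
        linkage=linkage_method,
    )
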