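"""Count normalisation chain: completeness filter, RPM, log2, quantile.

The analysis-ready matrix is log2 quantile-normalised reads-per-million.
``pca_group_check`` verifies that the normalised samples separate into
their treatment groups in PC1-PC2, the standard post-normalisation QC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .matrices import CountMatrix, ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


def filter_complete(cm: CountMatrix) -> CountMatrix:
    """Keep only genes with a positive count in every sample.

    Zero counts are the count-matrix analogue of missing values; genes with
    any zero are dropped, preserving gene order.
    """
    keep = (cm.counts.to_numpy() > 0).all(axis=1)
    if not keep.any():
        raise ValidationError("no complete genes: every gene has a zero count")
    return CountMatrix(counts=cm.counts.loc[keep], groups=cm.groups)


def to_rpm(cm: CountMatrix) -> pd.DataFrame:
    """Reads per million, denominator = column sums of the matrix as given."""
    totals = cm.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"zero total count for sample(s): {list(zero.index)}")
    return cm.counts / totals * 1e6


def log2_transform(rpm: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(rpm + pseudocount); pseudocount keeps zeros finite."""
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    shifted = rpm + pseudocount
    bad = shifted <= 0
    if bad.to_numpy().any():
        g = rpm.index[bad.any(axis=1)][0]
        s = rpm.columns[bad.any(axis=0)][0]
        raise ValidationError(
            f"non-positive value entering log2 at gene {g}, sample {s}"
        )
    return np.log2(shifted)


def quantile_normalize_frame(m: pd.DataFrame) -> pd.DataFrame:
    """Classic rank-mean quantile normalisation.

    Each column is replaced by the cross-column mean of the sorted values at
    its ranks; tied values receive the mean of the rank-means they span, so
    the procedure is well defined and idempotent in the presence of ties.
    """
    if m.isna().to_numpy().any():
        raise ValidationError("quantile normalisation requires no missing values")
    if m.shape[1] < 2:
        logger.warning("single-sample matrix: quantile normalisation is a no-op")
        return m.copy()
    vals = m.to_numpy(dtype=float)
    rank_means = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    n = vals.shape[0]
    for c in range(vals.shape[1]):
        col = vals[:, c]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = rank_means
        # ties: average the rank-means over each run of equal values
        _, inverse = np.unique(col, return_inverse=True)
        sums = np.bincount(inverse, weights=assigned)
        cnts = np.bincount(inverse)
        out[:, c] = (sums / cnts)[inverse]
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def normalize_counts(
    cm: CountMatrix,
    pseudocount: float = 1.0,
    rpm_before_filter: bool = True,
) -> ExpressionMatrix:
    """Full chain: (RPM | filter) -> log2 -> quantile normalisation.

    By default RPM denominators are the library totals over *all* detected
    genes, computed before the completeness filter; set
    ``rpm_before_filter=False`` to use post-filter totals instead.
    """
    provenance: list[str] = []
    if rpm_before_filter:
        rpm = to_rpm(cm)
        provenance.append("rpm(all-gene totals)")
        filtered = filter_complete(cm)
        rpm = rpm.loc[filtered.gene_ids]
        provenance.append("filter_complete")
    else:
        filtered = filter_complete(cm)
        provenance.append("filter_complete")
        rpm = to_rpm(filtered)
        provenance.append("rpm(post-filter totals)")
    logged = log2_transform(rpm, pseudocount)
    provenance.append(f"log2(+{pseudocount:g})")
    qn = quantile_normalize_frame(logged)
    provenance.append("quantile")
    return ExpressionMatrix(values=qn, groups=cm.groups, provenance=provenance)


def quantile_normalize(m: pd.DataFrame, groups: pd.Series) -> ExpressionMatrix:
    """Quantile-normalise an already log-transformed matrix."""
    return ExpressionMatrix(
        values=quantile_normalize_frame(m), groups=groups, provenance=["quantile"]
    )


@dataclass
class PCAReport:
    """Sample coordinates in PC1-PC2 and a linear-separability verdict."""

    coordinates: pd.DataFrame  # sample, pc1, pc2, group
    explained_variance_ratio: tuple[float, float]
    n_misclassified: int
    separated: bool


def pca_group_check(em: ExpressionMatrix, max_misclassified: int = 1) -> PCAReport:
    """Project samples on the top two PCs and test group separability.

    Genes are centred (no variance scaling); separability is judged by
    Fisher's linear discriminant on the PC1-PC2 coordinates: the groups count
    as separated when at most ``max_misclassified`` samples fall on the wrong
    side of the discriminant boundary.
    """
    n_s = len(em.sample_ids)
    if n_s < 3:
        raise ValidationError("PCA group check needs at least 3 samples")
    for g in sorted(em.groups.unique()):
        if len(em.samples_in(g)) < 2:
            raise ValidationError(f"group {g} has fewer than 2 samples")
    X = em.values.to_numpy(dtype=float).T  # samples x genes; PCA centres genes
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    labels = em.groups.to_numpy()
    lda = LinearDiscriminantAnalysis()
    pred = lda.fit(coords, labels).predict(coords)
    n_mis = int((pred != labels).sum())
    n_mis = min(n_mis, n_s - n_mis)  # boundary orientation is immaterial
    frame = pd.DataFrame(
        {
            "sample": em.sample_ids,
            "pc1": coords[:, 0],
            "pc2": coords[:, 1],
            "group": labels,
        }
    )
    evr = tuple(float(v) for v in pca.explained_variance_ratio_[:2])
    return PCAReport(
        coordinates=frame,
        explained_variance_ratio=evr,  # type: ignore[arg-type]
        n_misclassified=n_mis,
        separated=n_mis <= max_misclassified,
    )
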