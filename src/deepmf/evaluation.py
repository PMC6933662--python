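"""Clustering-based evaluation: silhouette width, Ward clustering, ARI.

Samples are points (matrix columns; features are coordinates).  Ward
clustering uses the ward.D2 criterion — squared Euclidean distances inside
the merge cost, heights on the distance scale — matching the identically
named R linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from .matrix import LabelVector, OmicsMatrix


@dataclass
class SubtypeEvaluation:
    """Per-sample silhouettes, their mean, cluster labels and ARI."""

    cluster_labels: LabelVector | None = None
    per_sample_silhouette: np.ndarray | None = None
    average_silhouette: float | None = None
    ari: float | None = None


def _as_points(m, transpose: bool) -> np.ndarray:
    """Columns of an OmicsMatrix / array as points (rows of the output)."""
    if isinstance(m, OmicsMatrix):
        if not m.is_fully_observed():
            raise ValueError("matrix has missing entries; impute or refine first")
        arr = m.values
    else:
        arr = np.asarray(m, dtype=np.float64)
    return arr.T if transpose else arr


def silhouette(m, labels: LabelVector) -> SubtypeEvaluation:
    """Silhouette widths of samples (columns) under ground-truth labels.

    Standard definition with Euclidean distance: a(i) = mean distance to
    own class (excluding self), b(i) = smallest mean distance to another
    class, s(i) = (b - a) / max(a, b); singleton classes score 0.
    """
    x = _as_points(m, transpose=True)
    if x.shape[0] != len(labels):
        raise ValueError(
            f"{x.shape[0]} samples but {len(labels)} labels"
        )
    codes = labels.as_codes()
    if labels.n_classes < 2:
        raise ValueError("silhouette undefined for a single class")
    per = silhouette_samples(x, codes, metric="euclidean")
    return SubtypeEvaluation(
        per_sample_silhouette=per,
        average_silhouette=float(per.mean()),
    )


def cluster_samples(v: np.ndarray, C: int, sample_ids: list[str] | None = None) -> LabelVector:
    """Ward (ward.D2) hierarchical clustering of the columns of ``v`` into C groups."""
    x = np.asarray(v, dtype=np.float64).T
    n = x.shape[0]
    if C < 2:
        raise ValueError(f"C must be >= 2, got {C}")
    if C > n:
        raise ValueError(f"cannot cut {n} samples into {C} clusters")
    z = linkage(x, method="ward")
    assign = fcluster(z, t=C, criterion="maxclust")
    ids = sample_ids if sample_ids is not None else [f"sample_{j + 1}" for j in range(n)]
    return LabelVector(list(ids), [str(a) for a in assign])


def cluster_features(u: np.ndarray, C: int, feature_ids: list[str] | None = None) -> LabelVector:
    """Ward clustering of the rows of ``u`` (feature latent factors)."""
    return cluster_samples(np.asarray(u, dtype=np.float64).T, C, feature_ids)


def _check_aligned(pred: LabelVector, truth: LabelVector) -> None:
    if len(pred) != len(truth) or pred.ids != truth.ids:
        raise ValueError("label vectors must cover identical ids in identical order")


def adjusted_rand_index(pred: LabelVector, truth: LabelVector) -> float:
    """Hubert–Arabie chance-corrected agreement between two partitions."""
    _check_aligned(pred, truth)
    return float(adjusted_rand_score(truth.as_codes(), pred.as_codes()))


def clustering_accuracy(pred: LabelVector, truth: LabelVector) -> float:
    """Fraction of items assigned to their ground-truth subgroup, maximizing
    over the cluster-to-class matching (Hungarian algorithm)."""
    from scipy.optimize import linear_sum_assignment

    _check_aligned(pred, truth)
    p, t = pred.as_codes(), truth.as_codes()
    cont = np.zeros((p.max() + 1, t.max() + 1), dtype=np.int64)
    np.add.at(cont, (p, t), 1)
    rows, cols = linear_sum_assignment(-cont)
    return float(cont[rows, cols].sum() / len(p))


def evaluate_subtypes(
    v: np.ndarray,
    truth: LabelVector,
    C: int | None = None,
    refined: OmicsMatrix | None = None,
) -> SubtypeEvaluation:
    """Cluster sample latent factors, score against ground truth, and
    optionally add silhouettes of the refined matrix."""
    C = C if C is not None else truth.n_classes
    pred = cluster_samples(v, C, sample_ids=list(truth.ids))
    ev = SubtypeEvaluation(cluster_labels=pred, ari=adjusted_rand_index(pred, truth))
    if refined is not None:
        sil = silhouette(refined, truth)
        ev.per_sample_silhouette = sil.per_sample_silhouette
        ev.average_silhouette = sil.average_silhouette
    return ev
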