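"""Similarity graphs and the graph-Laplacian local-proximity penalty.

Similarity between two feature rows (or sample columns) is
``1 / (1 + squared Euclidean distance)``.  Pairs whose similarity falls in
the low cluster of an exact 1-D two-means split are "remote" and zeroed so
the Laplacian penalty cannot pull genuinely dissimilar items together.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .matrix import OmicsMatrix

logger = logging.getLogger(__name__)

AXES = ("feature", "sample")


@dataclass
class ProximityGraph:
    """Similarity matrix with optional degree/Laplacian and remote-pair mask."""

    similarity: np.ndarray
    axis: str
    degree: np.ndarray | None = None
    laplacian: np.ndarray | None = None
    remote_mask: np.ndarray | None = None  # True = pair retained

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")

    @property
    def size(self) -> int:
        return self.similarity.shape[0]


def _masked_sq_distances(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pairwise-complete squared distances between rows of ``x``.

    Distances use only jointly observed coordinates and are rescaled by
    (total coords / jointly observed coords) so sparsity does not deflate
    them.  Pairs with zero joint coverage get distance +inf (similarity 0).
    """
    p = x.shape[1]
    w = mask.astype(np.float64)
    xz = np.where(mask, x, 0.0)
    sq = np.where(mask, x * x, 0.0)
    cross = xz @ xz.T
    a2 = sq @ w.T
    d2 = a2 + a2.T - 2.0 * cross
    counts = w @ w.T
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = d2 * (p / counts)
    empty = counts == 0
    if empty.any():
        n_empty = int(empty.sum() - np.trace(empty))
        if n_empty:
            warnings.warn(
                f"{n_empty // 2} pairs share no observed coordinates; "
                "their similarity is set to 0", stacklevel=3,
            )
        scaled[empty] = np.inf
    np.fill_diagonal(scaled, 0.0)
    return np.maximum(scaled, 0.0)  # guard tiny negative round-off


def pairwise_similarity(m: OmicsMatrix, axis: str) -> ProximityGraph:
    """Similarity graph over features (rows) or samples (columns) of ``m``."""
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    x = m.values if axis == "feature" else m.values.T
    msk = m.mask if axis == "feature" else m.mask.T
    if msk.all():
        d2 = squareform(pdist(np.ascontiguousarray(x), metric="sqeuclidean"))
    else:
        d2 = _masked_sq_distances(x, msk)
    with np.errstate(divide="ignore"):
        s = 1.0 / (1.0 + d2)
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 1.0)
    return ProximityGraph(similarity=s, axis=axis)


def two_means_split(values: np.ndarray) -> float | None:
    """Exact 1-D k-means with k=2: threshold separating the two clusters.

    Returns the midpoint between the two clusters of the optimal (minimum
    within-cluster sum of squares) 2-partition, or None when all values are
    identical (degenerate clustering).
    """
    v = np.sort(np.asarray(values, dtype=np.float64))
    n = v.size
    if n < 2 or v[0] == v[-1]:
        return None
    # prefix sums give each contiguous split's WCSS in O(1); the 1-D optimum
    # is always a contiguous split of the sorted values
    c1 = np.cumsum(v)
    c2 = np.cumsum(v * v)
    idx = np.arange(1, n)  # split: lower = v[:i], upper = v[i:]
    s1, s2 = c1[idx - 1], c2[idx - 1]
    wcss_lo = s2 - s1 * s1 / idx
    cnt_hi = n - idx
    s1h, s2h = c1[-1] - s1, c2[-1] - s2
    wcss_hi = s2h - s1h * s1h / cnt_hi
    best = int(np.argmin(wcss_lo + wcss_hi))
    i = best + 1
    return (v[i - 1] + v[i]) / 2.0


def mask_remote_pairs(g: ProximityGraph) -> ProximityGraph:
    """Zero out similarities in the low cluster of an exact 2-means split.

    The split is computed on off-diagonal upper-triangle values (the
    diagonal is never masked).  Degenerate inputs (all off-diagonal values
    equal) are returned unchanged with a warning.
    """
    s = g.similarity.copy()
    p = s.shape[0]
    iu = np.triu_indices(p, k=1)
    thr = two_means_split(s[iu])
    retained = np.ones_like(s, dtype=bool)
    if thr is None:
        logger.warning(
            "all off-diagonal similarities identical; no remote-pair masking applied"
        )
        return ProximityGraph(similarity=s, axis=g.axis, remote_mask=retained)
    remote = s < thr
    np.fill_diagonal(remote, False)
    s[remote] = 0.0
    retained = ~remote
    return ProximityGraph(similarity=s, axis=g.axis, remote_mask=retained)


def build_laplacian(g: ProximityGraph) -> ProximityGraph:
    """Fill in degree vector and Laplacian L = diag(degree) - similarity."""
    s = g.similarity
    if not np.allclose(s, s.T, atol=1e-12):
        raise ValueError("similarity matrix is not symmetric")
    degree = s.sum(axis=1)
    lap = np.diag(degree) - s
    return ProximityGraph(
        similarity=s, axis=g.axis, degree=degree, laplacian=lap,
        remote_mask=g.remote_mask,
    )


def local_penalty(latent: np.ndarray, g: ProximityGraph, axis: str) -> float:
    """Laplacian smoothness penalty of a latent matrix on graph ``g``.

    Feature axis: 2 * trace(U^T L U) with U of shape (P, K).
    Sample axis:  2 * trace(V L V^T) with V of shape (K, P).
    Equals the similarity-weighted sum of squared pairwise latent distances.
    """
    if g.laplacian is None:
        raise ValueError("graph has no Laplacian; call build_laplacian first")
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    x = latent if axis == "feature" else latent.T  # rows = graph nodes
    if x.shape[0] != g.size:
        raise ValueError(
            f"latent matrix has {x.shape[0]} {axis} rows, graph has {g.size}"
        )
    val = 2.0 * float(np.einsum("ik,ij,jk->", x, g.laplacian, x))
    return max(val, 0.0)


def feature_sample_graphs(m: OmicsMatrix) -> tuple[ProximityGraph, ProximityGraph]:
    """Full pipeline for both axes: similarity -> remote masking -> Laplacian."""
    out = []
    for axis in AXES:
        g = pairwise_similarity(m, axis)
        g = mask_remote_pairs(g)
        out.append(build_laplacian(g))
    return out[0], out[1]


def export_graph_tsv(g: ProximityGraph, path, what: str = "similarity"):
    """Write the similarity or Laplacian matrix as a headerless TSV."""
    mat = g.similarity if what == "similarity" else g.laplacian
    if mat is None:
        raise ValueError(f"graph has no {what} matrix")
    np.savetxt(path, mat, delimiter="\t")
    return path
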