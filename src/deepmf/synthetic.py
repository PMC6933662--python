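"""Block-structured synthetic matrices with additive noise and exact-count dropout.

Three canonical patterns are provided: pattern A has 3 feature x 3 sample
subgroups, pattern B has 2 feature x 3 sample subgroups, and pattern C is
the transpose of pattern B.  Canonical shapes are 1000x600, 100x60 and 10x6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import LabelVector, OmicsMatrix

CANONICAL_SHAPES = ((1000, 600), (100, 60), (10, 6))


def default_block_means(feature_groups: int, sample_groups: int, gap: float = 1.0) -> np.ndarray:
    """Equally spaced distinct block means: 1..G reshaped row-major, scaled by ``gap``."""
    g = feature_groups * sample_groups
    return gap * np.arange(1.0, g + 1.0).reshape(feature_groups, sample_groups)


@dataclass
class PatternSpec:
    """Recipe for one block-structured matrix.

    ``block_means`` defaults to an equally spaced grid with unit gap;
    ``noise_sd`` defaults to a quarter of the minimal between-block gap so
    blocks stay 4 standard deviations apart.
    """

    feature_groups: int
    sample_groups: int
    shape: tuple[int, int]
    block_means: np.ndarray | None = None
    noise_sd: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        m, n = self.shape
        if self.feature_groups < 1 or self.sample_groups < 1:
            raise ValueError("group counts must be >= 1")
        if self.feature_groups > m or self.sample_groups > n:
            raise ValueError(
                f"more groups than axis length: {self.feature_groups}x{self.sample_groups} "
                f"groups for a {m}x{n} matrix"
            )
        if self.block_means is None:
            self.block_means = default_block_means(self.feature_groups, self.sample_groups)
        self.block_means = np.asarray(self.block_means, dtype=np.float64)
        if self.block_means.shape != (self.feature_groups, self.sample_groups):
            raise ValueError("block_means shape must be (feature_groups, sample_groups)")
        bm = self.block_means
        if len({tuple(r) for r in bm}) < bm.shape[0] or len({tuple(c) for c in bm.T}) < bm.shape[1]:
            raise ValueError("block_means must have distinct rows and columns")
        if self.noise_sd is None:
            diffs = np.abs(bm.ravel()[:, None] - bm.ravel()[None, :])
            gaps = diffs[diffs > 0]
            self.noise_sd = 0.25 * float(gaps.min()) if gaps.size else 0.0
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def pattern_a(shape: tuple[int, int] = (100, 60), seed: int = 0, **kw) -> PatternSpec:
    """3 feature subgroups x 3 sample subgroups."""
    return PatternSpec(3, 3, shape, seed=seed, **kw)


def pattern_b(shape: tuple[int, int] = (100, 60), seed: int = 0, **kw) -> PatternSpec:
    """2 feature subgroups x 3 sample subgroups."""
    return PatternSpec(2, 3, shape, seed=seed, **kw)


def _partition(total: int, groups: int) -> np.ndarray:
    """Group index per position, sizes as even as possible."""
    sizes = [len(a) for a in np.array_split(np.arange(total), groups)]
    return np.repeat(np.arange(groups), sizes)


def generate_pattern(spec: PatternSpec) -> tuple[OmicsMatrix, LabelVector, LabelVector]:
    """Draw one matrix from ``spec``: block mean + N(0, noise_sd) noise.

    Returns the matrix and ground-truth feature / sample label vectors.
    Deterministic given ``spec.seed``.
    """
    m, n = spec.shape
    rng = np.random.default_rng(spec.seed)
    fg = _partition(m, spec.feature_groups)
    sg = _partition(n, spec.sample_groups)
    base = spec.block_means[np.ix_(fg, sg)]
    noise = rng.normal(0.0, spec.noise_sd, size=(m, n)) if spec.noise_sd > 0 else 0.0
    values = base + noise
    feature_ids = [f"feature_{i + 1}" for i in range(m)]
    sample_ids = [f"sample_{j + 1}" for j in range(n)]
    om = OmicsMatrix(values, np.ones((m, n), dtype=bool), feature_ids, sample_ids)
    f_labels = LabelVector(feature_ids, [f"F{g + 1}" for g in fg])
    s_labels = LabelVector(sample_ids, [f"S{g + 1}" for g in sg])
    return om, f_labels, s_labels


def transpose_pattern(
    m: OmicsMatrix, f_labels: LabelVector, s_labels: LabelVector
) -> tuple[OmicsMatrix, LabelVector, LabelVector]:
    """Transpose a generated pattern; axis labels swap, ids get a '_t' suffix."""
    mt = m.transpose()
    mt.feature_ids = [f"{i}_t" for i in mt.feature_ids]
    mt.sample_ids = [f"{i}_t" for i in mt.sample_ids]
    new_f = LabelVector(list(mt.feature_ids), list(s_labels.labels))
    new_s = LabelVector(list(mt.sample_ids), list(f_labels.labels))
    return mt, new_f, new_s


def apply_dropout(m: OmicsMatrix, rate: float, seed: int = 0) -> OmicsMatrix:
    """Mask exactly round(rate * M * N) currently observed cells, chosen uniformly.

    Deterministic given ``seed``.  Errors if no observed entry would remain.
    """
    if not 0 <= rate < 1:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    out = m.copy()
    n_drop = int(round(rate * m.n_features * m.n_samples))
    if n_drop == 0:
        return out
    obs_flat = np.flatnonzero(out.mask.ravel())
    if n_drop >= obs_flat.size:
        raise ValueError(
            f"dropout of {n_drop} cells would leave no observed entries "
            f"({obs_flat.size} observed)"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(obs_flat, size=n_drop, replace=False)
    flat_mask = out.mask.ravel()
    flat_mask[chosen] = False
    out.mask = flat_mask.reshape(out.mask.shape)
    out.values = np.where(out.mask, out.values, np.nan)
    return out
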