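"""Imputation baselines: feature-mean substitution and iterative SVD refill."""

from __future__ import annotations

import warnings

import numpy as np

from .matrix import OmicsMatrix


def mean_impute(m: OmicsMatrix) -> OmicsMatrix:
    """Replace each missing cell by the mean of its feature row's observed values."""
    counts = m.mask.sum(axis=1)
    if (counts == 0).any():
        bad = int(np.argmin(counts))
        raise ValueError(
            f"feature {m.feature_ids[bad]!r} has no observed values; cannot mean-impute"
        )
    sums = m.observed_values().sum(axis=1)
    row_means = sums / counts
    values = np.where(m.mask, m.values, row_means[:, None])
    return OmicsMatrix(
        values, np.ones(m.shape, dtype=bool), list(m.feature_ids), list(m.sample_ids)
    )


def svd_impute(
    m: OmicsMatrix,
    k: int,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> OmicsMatrix:
    """Impute missing cells from the rank-k SVD reconstruction.

    The matrix is feature-centered (observed-row means subtracted), missing
    cells start at 0, and the rank-k reconstruction refills them repeatedly
    until the imputed values change by less than ``tol`` (max-abs) or
    ``max_iter`` sweeps elapse.  Observed cells are never altered.
    """
    mm, nn = m.shape
    if not 1 <= k <= min(mm, nn):
        raise ValueError(f"k must be in [1, {min(mm, nn)}], got {k}")
    counts_r = m.mask.sum(axis=1)
    counts_c = m.mask.sum(axis=0)
    if (counts_r == 0).any():
        bad = int(np.argmin(counts_r))
        raise ValueError(f"feature {m.feature_ids[bad]!r} has no observed values")
    if (counts_c == 0).any():
        bad = int(np.argmin(counts_c))
        raise ValueError(f"sample {m.sample_ids[bad]!r} has no observed values")

    row_means = m.observed_values().sum(axis=1) / counts_r
    # missing cells start at the row mean, i.e. 0 in centered space
    est = np.where(m.mask, m.values, row_means[:, None])
    missing = ~m.mask
    converged = not missing.any()
    for _ in range(max_iter):
        if converged:
            break
        # re-centering on the current completed estimate keeps an exactly
        # low-rank truth a fixed point of the sweep
        rm = est.mean(axis=1)
        xc = est - rm[:, None]
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        recon = (u[:, :k] * s[:k]) @ vt[:k] + rm[:, None]
        delta = np.abs(recon[missing] - est[missing]).max()
        est[missing] = recon[missing]
        if delta < tol:
            converged = True
    if not converged:
        warnings.warn(
            f"svd_impute did not converge within {max_iter} iterations "
            f"(last change {delta:.3g}); returning last iterate"
        )
    values = np.where(m.mask, m.values, est)
    return OmicsMatrix(
        values, np.ones(m.shape, dtype=bool), list(m.feature_ids), list(m.sample_ids)
    )
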