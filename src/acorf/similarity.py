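"""Pairwise similarity of intensity profiles across samples.

The grouping algorithm consumes any externally produced similarity matrix;
this module is a convenience for the two most common choices, Pearson and
Spearman correlation of per-feature intensity profiles.  Missing intensities
are handled by pairwise-complete deletion; a pair sharing fewer than
``MIN_SHARED_SAMPLES`` observed samples gets a missing similarity, which no
threshold can select.
"""

from __future__ import annotations

import logging

import numpy as np

from .tables import IntensityMatrix, SimilarityMatrix

__all__ = ["compute_similarity", "SIMILARITY_METHODS", "MIN_SHARED_SAMPLES"]

logger = logging.getLogger(__name__)

SIMILARITY_METHODS = ("pearson", "spearman")

#: minimum pairwise-complete observations for a defined coefficient
MIN_SHARED_SAMPLES = 3


def compute_similarity(matrix: IntensityMatrix, method: str) -> SimilarityMatrix:
    """Correlate every pair of feature intensity profiles.

    Parameters
    ----------
    matrix
        Features x samples intensities; needs at least 3 samples.
    method
        ``"pearson"`` or ``"spearman"`` — no silent default.

    Returns
    -------
    SimilarityMatrix
        Symmetric, diagonal 1 for features with variance; zero-variance
        features get missing similarities everywhere (with a warning).
    """
    if method not in SIMILARITY_METHODS:
        raise ValueError(f"unknown similarity method {method!r}; choose from {SIMILARITY_METHODS}")
    if matrix.n_samples < MIN_SHARED_SAMPLES:
        raise ValueError(
            f"need at least {MIN_SHARED_SAMPLES} samples to compute similarity, "
            f"got {matrix.n_samples}"
        )
    profiles = matrix.values.T  # samples x features, as pandas corr expects
    corr = profiles.corr(method=method, min_periods=MIN_SHARED_SAMPLES)

    flat = matrix.values.std(axis=1, skipna=True, ddof=0)
    degenerate = flat[(flat == 0) | flat.isna()].index.tolist()
    if degenerate:
        logger.warning(
            "%d feature(s) with zero variance; their similarities are set to missing: %s",
            len(degenerate),
            degenerate[:10],
        )
        corr.loc[degenerate, :] = np.nan
        corr.loc[:, degenerate] = np.nan

    ok = [f for f in corr.index if f not in set(degenerate)]
    for f in ok:
        corr.at[f, f] = 1.0
    corr.index = corr.index.astype(str)
    corr.columns = corr.columns.astype(str)
    return SimilarityMatrix(corr)
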