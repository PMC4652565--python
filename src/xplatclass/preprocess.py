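"""Fold-change computation and the variability/redundancy pre-filter.

The pipeline's continuous representation is the per-sample log2 fold change
against a platform-matched normal reference:

    FC[f, s] = log2( T[f, s] / median_j N[f, j] )

where T is tumor expression and N the normal reference pool of the same
platform.  The pre-filter ranks features by the coefficient of variation
CV = sigma / mu (sample standard deviation over mean, computed on the
positive expression scale), drops redundant features by a greedy Pearson
scan in CV order, and keeps the top-k most variable survivors.
"""

from __future__ import annotations

import logging
from typing import List, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, ConfigError, DomainError, SizeError

logger = logging.getLogger(__name__)

#: duplicates at or beyond this |r| are always dropped by the redundancy filter
_DUPLICATE_TOL = 1e-10


def fold_change(tumor: pd.DataFrame, normals: pd.DataFrame) -> pd.DataFrame:
    """log2 fold change of each tumor sample against the normal median.

    Both matrices must be strictly positive and share feature ids.  Computed
    as ``log2(T) - log2(median(N))`` which is exact and robust to the very
    wide dynamic ranges a nonlinear platform scale can produce.
    """
    if list(tumor.index) != list(normals.index):
        if set(tumor.index) == set(normals.index):
            normals = normals.reindex(tumor.index)
        else:
            only_t = len(set(tumor.index) - set(normals.index))
            raise AlignmentError(
                f"tumor and normal matrices disagree on feature ids "
                f"({only_t} tumor-only features)"
            )
    t = tumor.to_numpy(dtype=float)
    n = normals.to_numpy(dtype=float)
    if (t <= 0).any():
        r, c = np.argwhere(t <= 0)[0]
        raise DomainError(
            f"nonpositive tumor value at feature {tumor.index[r]!r}, "
            f"sample {tumor.columns[c]!r}; fold change requires positive data"
        )
    if (n <= 0).any():
        r, c = np.argwhere(n <= 0)[0]
        raise DomainError(
            f"nonpositive normal value at feature {normals.index[r]!r}, "
            f"sample {normals.columns[c]!r}; fold change requires positive data"
        )
    log_med = np.log2(np.median(n, axis=1))
    fc = np.log2(t) - log_med[:, None]
    return pd.DataFrame(fc, index=tumor.index, columns=tumor.columns)


def cv_scores(matrix: pd.DataFrame) -> pd.Series:
    """Coefficient of variation sigma/mu per feature (sample SD, n-1)."""
    values = matrix.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise DomainError("CV requires at least two samples")
    mu = values.mean(axis=1)
    bad = np.flatnonzero(mu <= 0)
    if bad.size:
        raise DomainError(
            f"feature {matrix.index[bad[0]]!r} has nonpositive mean; "
            "CV is defined only for positive-mean features"
        )
    sigma = values.std(axis=1, ddof=1)
    return pd.Series(sigma / mu, index=matrix.index, name="cv")


def _cv_order(matrix: pd.DataFrame) -> List[str]:
    cv = cv_scores(matrix)
    return sorted(cv.index, key=lambda fid: (-cv[fid], fid))


def correlation_redundancy_filter(
    matrix: pd.DataFrame, ranking: Sequence[str], cutoff: float
) -> List[str]:
    """Greedy Pearson redundancy filter in ranking order.

    A feature is kept iff its absolute correlation with every already-kept
    feature is <= cutoff; exact linear duplicates are always dropped.
    Zero-variance features have undefined correlation and are dropped with a
    warning.  Output depends only on the ranking order and the correlation
    matrix, so it is invariant to sample permutations.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ConfigError("cutoff must lie in (0, 1]")
    unknown = [f for f in ranking if f not in matrix.index]
    if unknown:
        raise AlignmentError(f"ranking names unknown features: {unknown[:5]}")
    sub = matrix.loc[list(ranking)].to_numpy(dtype=float)
    n = sub.shape[1]
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1)
    zero_var = sd == 0
    z = (sub - mu) / np.where(zero_var, 1.0, sd)[:, None]
    kept: List[int] = []
    kept_ids: List[str] = []
    for i, fid in enumerate(ranking):
        if zero_var[i]:
            logger.warning(
                "feature %r has zero variance; correlation undefined, dropped", fid
            )
            continue
        if kept:
            r = np.abs(z[kept] @ z[i] / (n - 1))
            if (r > cutoff).any() or (r >= 1.0 - _DUPLICATE_TOL).any():
                continue
        kept.append(i)
        kept_ids.append(fid)
    return kept_ids


def select_top_variable(matrix: pd.DataFrame, k: int) -> List[str]:
    """The k features with the largest CV; ties broken by feature id."""
    if k > matrix.shape[0]:
        raise SizeError(
            f"requested top {k} features but only {matrix.shape[0]} available"
        )
    return _cv_order(matrix)[:k]


def prefilter_features(
    matrix: pd.DataFrame, top_k: int, cutoff: float = 0.8
) -> List[str]:
    """Redundancy filter in CV order, then the top-k surviving features.

    The CV ranking is computed first so the higher-CV member of every
    correlated pair survives the greedy scan; ``top_k`` is clipped to the
    number of survivors.
    """
    ranking = _cv_order(matrix)
    kept = correlation_redundancy_filter(matrix, ranking, cutoff)
    return kept[: min(top_k, len(kept))]
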