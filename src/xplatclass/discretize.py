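"""Unsupervised per-feature discretization of continuous expression matrices.

Three local (per-feature) discretizers map continuous values to integer bins
1..k:

* **equal width** — k intervals of equal value range.  Invariant under
  positive affine transforms of a feature, but not under general monotone
  maps (an outlier or a convex rescaling moves the cut points).
* **equal frequency** — bins containing (near-)equal numbers of sorted
  observations.  Depends only on within-dataset ranks, so it is *exactly*
  invariant under any strictly increasing per-feature transform.  This rank
  dependence is what lets a model trained on one expression platform read
  data from another: bins are refit independently on every dataset, and two
  platforms observing the same samples through different monotone scales
  produce identical bin matrices when technical noise is absent.
* **1-D k-means** — Lloyd iterations with deterministic quantile-midpoint
  initialization, clusters relabeled 1..k by ascending centroid.  Invariant
  under positive affine transforms (centroids transform equivariantly).

Tie policy for equal frequency: values get ordinal (stable) ranks; all tied
values receive the bin of their smallest tied rank.  Degenerate constant
features collapse to bin 1 for every method, with a logged warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ConfigError, SizeError

logger = logging.getLogger(__name__)

METHODS = ("equal_width", "equal_freq", "kmeans")


@dataclass
class BinningModel:
    """Per-feature discretization rule, retained for audit.

    ``boundaries[fid]`` holds the k-1 ascending cut points (equal_width /
    equal_freq) or the k ascending centroids (kmeans); empty for a feature
    that collapsed to a single bin.
    """

    method: str
    k: int
    boundaries: Dict[str, np.ndarray]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "k": int(self.k),
            "boundaries": {f: list(map(float, b)) for f, b in self.boundaries.items()},
        }


def dougherty_max_bins(n_distinct: int) -> int:
    """Heuristic maximum bin number ``k = max(1, floor(2 ln l))`` for an
    attribute with ``l`` distinct values."""
    if n_distinct < 1:
        raise ConfigError("n_distinct must be >= 1")
    return max(1, int(math.floor(2.0 * math.log(n_distinct))))


# ---------------------------------------------------------------------------
# per-feature fitters


def equal_width_bins(values, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Equal-width binning of one feature; returns (bins in 1..k, cut points).

    Cut points sit at ``min + j*(max-min)/k``; a value maps to bin
    ``floor((v-min)/width)+1`` clamped so the maximum lands in bin k.  A
    constant vector collapses to bin 1.
    """
    if k < 2:
        raise ConfigError("equal-width binning requires k >= 2")
    v = np.asarray(values, dtype=float)
    vmin, vmax = v.min(), v.max()
    if vmax == vmin:
        return np.ones(v.shape, dtype=int), np.empty(0)
    width = (vmax - vmin) / k
    bins = np.floor((v - vmin) / width).astype(int) + 1
    np.clip(bins, 1, k, out=bins)
    cuts = vmin + width * np.arange(1, k)
    return bins, cuts


def equal_freq_bins(values, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Equal-frequency binning of one feature.

    The value with 1-based ordinal rank r goes to bin ``ceil(r*k/n)``; tied
    values all receive the bin of their smallest tied rank (rank method
    "min"), which keeps the assignment deterministic and platform-consistent
    whenever the tie structure matches.
    """
    if k < 2:
        raise ConfigError("equal-frequency binning requires k >= 2")
    v = np.asarray(values, dtype=float)
    n = v.size
    if k > n:
        raise SizeError(f"equal-frequency binning with k={k} needs >= {k} values")
    ranks = rankdata(v, method="min").astype(np.int64)
    bins = ((ranks * k + n - 1) // n).astype(int)
    order = np.sort(v)
    cut_idx = (np.arange(1, k) * n) // k  # largest ordinal rank in bin <= j
    cuts = order[np.clip(cut_idx - 1, 0, n - 1)]
    return bins, cuts


def kmeans_1d(values, k: int, seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """1-D k-means with deterministic quantile-midpoint initialization.

    Centroids start at the midpoints of the k equal-frequency quantile
    intervals; Lloyd iterations run until no assignment changes (or 200
    iterations).  Final clusters are relabeled 1..k by ascending centroid.
    ``seed`` is accepted for interface symmetry; the fit is deterministic.
    """
    if k < 2:
        raise ConfigError("k-means discretization requires k >= 2")
    v = np.asarray(values, dtype=float)
    distinct = np.unique(v)
    if k > distinct.size:
        raise SizeError(
            f"k-means with k={k} needs >= {k} distinct values "
            f"(got {distinct.size})"
        )
    q = (2.0 * np.arange(k) + 1.0) / (2.0 * k)
    centroids = np.quantile(v, q)
    if np.unique(centroids).size < k:
        centroids = np.quantile(distinct, q)
    assign = np.argmin(np.abs(v[:, None] - centroids[None, :]), axis=1)
    for _ in range(200):
        for j in range(k):
            members = v[assign == j]
            if members.size:
                centroids[j] = members.mean()
        new_assign = np.argmin(np.abs(v[:, None] - centroids[None, :]), axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    order = np.argsort(centroids, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    bins = relabel[assign] + 1
    return bins, centroids[order]


# ---------------------------------------------------------------------------
# matrix-level driver


def discretize_matrix(
    matrix: pd.DataFrame, method: str, k: int, seed: int = 0
) -> Tuple[pd.DataFrame, BinningModel]:
    """Fit and transform every feature (row) independently.

    Returns the integer bin matrix (cells in 1..k) and the fitted
    :class:`BinningModel`.  Boundaries are refit on every dataset they are
    applied to; applying one platform's boundaries to another platform's
    values would reintroduce the scale problem discretization removes.
    """
    if method not in METHODS:
        raise ConfigError(f"unknown discretization method {method!r}")
    if k < 2:
        raise ConfigError("discretization requires k >= 2")
    values = matrix.to_numpy(dtype=float)
    nf, n = values.shape
    boundaries: Dict[str, np.ndarray] = {}

    if method == "equal_freq":
        if k > n:
            raise SizeError(f"equal-frequency binning with k={k} needs >= {k} samples")
        ranks = rankdata(values, method="min", axis=1).astype(np.int64)
        bins = ((ranks * k + n - 1) // n).astype(int)
        order = np.sort(values, axis=1)
        cut_idx = np.clip((np.arange(1, k) * n) // k - 1, 0, n - 1)
        for i, fid in enumerate(matrix.index):
            boundaries[fid] = order[i, cut_idx]
    elif method == "equal_width":
        vmin = values.min(axis=1, keepdims=True)
        vmax = values.max(axis=1, keepdims=True)
        constant = (vmax == vmin).ravel()
        width = np.where(vmax > vmin, (vmax - vmin) / k, 1.0)
        bins = np.floor((values - vmin) / width).astype(int) + 1
        np.clip(bins, 1, k, out=bins)
        bins[constant, :] = 1
        if constant.any():
            logger.warning(
                "%d constant feature(s) collapsed to bin 1", int(constant.sum())
            )
        for i, fid in enumerate(matrix.index):
            if constant[i]:
                boundaries[fid] = np.empty(0)
            else:
                boundaries[fid] = vmin[i, 0] + width[i, 0] * np.arange(1, k)
    else:  # kmeans
        bins = np.empty_like(values, dtype=int)
        n_constant = 0
        for i, fid in enumerate(matrix.index):
            row = values[i]
            distinct = np.unique(row).size
            if distinct == 1:
                bins[i, :] = 1
                boundaries[fid] = np.empty(0)
                n_constant += 1
                continue
            kk = min(k, distinct)
            row_bins, centroids = kmeans_1d(row, kk, seed=seed)
            bins[i] = row_bins
            boundaries[fid] = centroids
        if n_constant:
            logger.warning("%d constant feature(s) collapsed to bin 1", n_constant)

    binned = pd.DataFrame(bins, index=matrix.index, columns=matrix.columns)
    return binned, BinningModel(method=method, k=k, boundaries=boundaries)
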