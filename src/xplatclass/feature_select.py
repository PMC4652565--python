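"""Feature ranking and selection.

Three selectors, all operating on a features x samples matrix:

* :func:`rank_by_cv` — filter method; descending coefficient of variation.
* :func:`svm_rfe` — recursive feature elimination with a linear one-vs-one
  SVM; the per-feature criterion is the sum of squared weights w_i^2 over
  all C(C-1)/2 binary classifiers, and a fraction of the lowest-criterion
  survivors is removed per iteration (chunked elimination; step_fraction
  small enough recovers one-at-a-time).
* :func:`rf_backward_elimination` — random-forest backward elimination that
  repeatedly discards the least-important fraction of features (importances
  from the initial forest, not recomputed) and picks the smallest visited
  set whose out-of-bag error is within one standard error of the minimum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .exceptions import ConfigError, LabelError
from .preprocess import cv_scores

logger = logging.getLogger(__name__)


@dataclass
class FeatureRanking:
    """Ordered feature list, best first, with per-feature criterion values.

    For ``svm_rfe`` the score of a feature is its w^2 criterion at the
    iteration it was eliminated (survivors of the final iteration keep their
    final criterion), so scores are comparable within an elimination round
    but not monotone across rounds.
    """

    feature_ids: List[str]
    scores: np.ndarray
    method: str

    def top(self, n: int) -> List[str]:
        return self.feature_ids[: min(n, len(self.feature_ids))]


@dataclass
class RFSelectionTrace:
    """Backward-elimination trace: visited sizes with OOB error estimates."""

    sizes: List[int]
    oob_errors: List[float]
    oob_ses: List[float]
    chosen_size: int
    chosen_features: List[str]


def rank_by_cv(matrix: pd.DataFrame) -> FeatureRanking:
    """Rank features by descending CV; ties broken by feature id."""
    cv = cv_scores(matrix)
    order = sorted(cv.index, key=lambda fid: (-cv[fid], fid))
    return FeatureRanking(
        feature_ids=list(order),
        scores=cv.loc[order].to_numpy(),
        method="cv",
    )


def svm_weight_criterion(X: pd.DataFrame, y: Sequence[str], C: float = 1.0) -> pd.Series:
    """Per-feature sum of squared one-vs-one linear SVM weights.

    Features are standardized (zero mean, unit variance over samples) before
    fitting, so the criterion is comparable across features.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise LabelError("SVM criterion requires at least two classes")
    A = X.to_numpy(dtype=float)
    mu = A.mean(axis=1, keepdims=True)
    sd = A.std(axis=1)
    z = (A - mu) / np.where(sd == 0, 1.0, sd)[:, None]
    clf = SVC(kernel="linear", C=C)
    clf.fit(z.T, y)
    crit = (clf.coef_**2).sum(axis=0)
    return pd.Series(crit, index=X.index)


def svm_rfe(
    X: pd.DataFrame,
    y: Sequence[str],
    step_fraction: float = 0.1,
    C: float = 1.0,
) -> FeatureRanking:
    """Multiclass SVM recursive feature elimination.

    Per iteration, linear one-vs-one SVMs are trained on the surviving
    features and ``ceil(step_fraction * survivors)`` features (at least one)
    with the lowest w^2 criterion are eliminated; the ranking is the reverse
    elimination order.  Deterministic up to criterion ties, which are broken
    by feature id.
    """
    if not 0.0 < step_fraction <= 1.0:
        raise ConfigError("step_fraction must lie in (0, 1]")
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise LabelError("SVM-RFE requires at least two classes")
    ids = list(X.index)
    surviving = list(ids)
    eliminated: List[Tuple[str, float]] = []  # worst first
    sub = X
    while surviving:
        crit = svm_weight_criterion(sub.loc[surviving], y, C=C)
        order = sorted(surviving, key=lambda fid: (crit[fid], fid))
        n_drop = max(1, math.ceil(step_fraction * len(surviving)))
        if n_drop >= len(surviving):
            eliminated.extend((fid, float(crit[fid])) for fid in order)
            break
        drop = set(order[:n_drop])
        eliminated.extend((fid, float(crit[fid])) for fid in order[:n_drop])
        surviving = [fid for fid in surviving if fid not in drop]
    ranked = list(reversed(eliminated))
    return FeatureRanking(
        feature_ids=[fid for fid, _ in ranked],
        scores=np.array([s for _, s in ranked]),
        method="svm_rfe",
    )


def rank_by_rf_importance(
    X: pd.DataFrame, y: Sequence[str], n_trees: int = 200, seed: int = 0
) -> FeatureRanking:
    """Rank features by random-forest impurity importance (descending)."""
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X.to_numpy(dtype=float).T, np.asarray(y))
    imp = pd.Series(rf.feature_importances_, index=X.index)
    order = sorted(imp.index, key=lambda fid: (-imp[fid], fid))
    return FeatureRanking(
        feature_ids=list(order), scores=imp.loc[order].to_numpy(), method="rf"
    )


def rf_backward_elimination(
    X: pd.DataFrame,
    y: Sequence[str],
    drop_fraction: float = 0.2,
    n_trees: int = 500,
    seed: int = 0,
) -> Tuple[List[str], RFSelectionTrace]:
    """Random-forest backward elimination with the OOB one-standard-error rule.

    A forest on all features provides the importance ordering; at each step
    the ``drop_fraction`` least-important features (by the *initial*
    importances) are discarded and the forest refit, recording the OOB error
    and its binomial standard error.  The chosen set is the smallest visited
    set whose OOB error is within one standard error of the minimum — the
    procedure is designed to return a very small feature set while retaining
    accuracy.
    """
    if not 0.0 < drop_fraction < 1.0:
        raise ConfigError("drop_fraction must lie in (0, 1)")
    if n_trees < 50:
        logger.warning(
            "n_trees=%d is small; OOB error estimates will be unstable", n_trees
        )
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise LabelError("RF elimination requires at least two classes")
    n_samples = X.shape[1]
    Xt = X.to_numpy(dtype=float).T

    def fit_oob(col_idx: np.ndarray) -> Tuple[float, float, RandomForestClassifier]:
        rf = RandomForestClassifier(
            n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
        )
        rf.fit(Xt[:, col_idx], y)
        err = 1.0 - rf.oob_score_
        se = math.sqrt(err * (1.0 - err) / n_samples)
        return err, se, rf

    ids = np.asarray(list(X.index))
    all_idx = np.arange(len(ids))
    err0, se0, rf0 = fit_oob(all_idx)
    imp = rf0.feature_importances_
    order = sorted(range(len(ids)), key=lambda i: (-imp[i], ids[i]))
    current = list(order)

    sizes: List[int] = [len(current)]
    errors: List[float] = [err0]
    ses: List[float] = [se0]
    visited: List[List[int]] = [list(current)]
    while len(current) > 2:
        n_drop = max(1, int(math.floor(drop_fraction * len(current))))
        new_size = max(2, len(current) - n_drop)
        current = current[:new_size]
        err, se, _ = fit_oob(np.asarray(current))
        sizes.append(len(current))
        errors.append(err)
        ses.append(se)
        visited.append(list(current))

    i_min = int(np.argmin(errors))
    threshold = errors[i_min] + ses[i_min]
    candidates = [i for i in range(len(sizes)) if errors[i] <= threshold]
    i_chosen = min(candidates, key=lambda i: sizes[i])
    chosen = [str(ids[j]) for j in visited[i_chosen]]
    trace = RFSelectionTrace(
        sizes=sizes,
        oob_errors=errors,
        oob_ses=ses,
        chosen_size=sizes[i_chosen],
        chosen_features=chosen,
    )
    return chosen, trace
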