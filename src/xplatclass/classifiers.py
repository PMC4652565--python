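"""The four multi-class classifiers: linear OvO SVM, random forest, naive
Bayes, and PAM (nearest shrunken centroid).

SVM, RF and NB are backed by scikit-learn behind this module's interface.
PAM is implemented here from its defining equations.  For feature i and
class k with n_k of n training samples:

    d_ik  = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),   m_k = sqrt(1/n_k - 1/n)
    d'_ik = sign(d_ik) * max(|d_ik| - Delta, 0)                (soft threshold)
    xbar'_ik = xbar_i + m_k * (s_i + s0) * d'_ik           (shrunken centroid)

where xbar_i is the overall centroid, xbar_ik the class centroid, s_i the
pooled within-class standard deviation and s0 the median of the s_i (a fudge
constant guarding against near-zero denominators).  A sample x is assigned to
the class minimizing the discriminant

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2  -  2 log prior_k,

ties going to the first class in label order.  The shrinkage threshold Delta
is chosen by internal stratified cross-validation over a grid from 0 to
max|d_ik|, ties resolved toward the larger Delta (fewer surviving features).

Discretized inputs are fed to SVM/RF as ordinal integers (bins carry a
natural expression order); NB is categorical with additive smoothing on bins
and Gaussian on continuous fold-change data.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import CategoricalNB, GaussianNB
from sklearn.svm import SVC

from .data_io import SUBTYPES
from .exceptions import ConfigError, ContractError, LabelError

logger = logging.getLogger(__name__)

METHODS = ("svm", "rf", "nb", "pam")

REPR_FC = "fc"


def representation_tag(method: str, k: Optional[int] = None) -> str:
    """Canonical representation tag, e.g. ``"fc"`` or ``"equal_freq:k=10"``."""
    if method == REPR_FC:
        return REPR_FC
    return f"{method}:k={k}"


def is_discrete_representation(tag: str) -> bool:
    return tag != REPR_FC


def _repr_bins(tag: str) -> Optional[int]:
    m = re.search(r"k=(\d+)", tag)
    return int(m.group(1)) if m else None


def class_order(y: Sequence[str]) -> List[str]:
    """Deterministic class order: canonical subtype order first, then any
    other labels sorted lexicographically."""
    present = set(y)
    ordered = [c for c in SUBTYPES if c in present]
    ordered += sorted(present - set(SUBTYPES))
    return ordered


@dataclass
class TrainedClassifier:
    method: str
    classes: Tuple[str, ...]
    feature_ids: Tuple[str, ...]
    representation: str
    impl: object
    params: dict


# ---------------------------------------------------------------------------
# PAM


@dataclass
class PAMModel:
    feature_ids: Tuple[str, ...]
    classes: Tuple[str, ...]
    priors: np.ndarray  # (K,)
    overall: np.ndarray  # (f,)
    centroids: np.ndarray  # (f, K) unshrunken class centroids
    s: np.ndarray  # (f,) pooled within-class SD
    s0: float
    mk: np.ndarray  # (K,)
    delta: float
    dprime: np.ndarray  # (f, K) shrunken standardized differences
    cv_errors: Optional[np.ndarray] = None  # per Delta grid value, for audit
    delta_grid: Optional[np.ndarray] = None

    @property
    def shrunken_centroids(self) -> np.ndarray:
        return self.overall[:, None] + (self.s + self.s0)[:, None] * (
            self.mk[None, :] * self.dprime
        )

    def n_active_features(self) -> int:
        """Features with any nonzero shrunken difference."""
        return int((np.abs(self.dprime) > 0).any(axis=1).sum())


def _pam_statistics(Xv: np.ndarray, y: np.ndarray, classes: Sequence[str]):
    """Centroids, pooled SDs and standardized differences for PAM."""
    n = y.size
    K = len(classes)
    nk = np.array([(y == c).sum() for c in classes], dtype=float)
    priors = nk / n
    overall = Xv.mean(axis=1)
    centroids = np.column_stack([Xv[:, y == c].mean(axis=1) for c in classes])
    ss = np.zeros(Xv.shape[0])
    for j, c in enumerate(classes):
        diff = Xv[:, y == c] - centroids[:, j : j + 1]
        ss += (diff**2).sum(axis=1)
    dof = max(n - K, 1)
    s = np.sqrt(ss / dof)
    # snap numerically-zero pooled SDs (pure float jitter on noiseless
    # features) to exact zero so degenerate data behaves consistently
    # between full fits and CV refits
    tol = 1e-10 * max(float(np.abs(Xv).max()), 1.0)
    s[s <= tol] = 0.0
    s0 = float(np.median(s))
    if s0 == 0.0:
        # degenerate (near-)noiseless data: the median fudge constant
        # vanishes and the standardization becomes 0/0; fall back to the
        # smallest positive pooled SD, or 1 if every feature is noiseless
        positive = s[s > 0]
        s0 = float(positive.min()) if positive.size else 1.0
    mk = np.sqrt(1.0 / nk - 1.0 / n)
    denom = (s + s0)[:, None] * mk[None, :]
    safe = np.where(denom == 0, 1.0, denom)
    d = (centroids - overall[:, None]) / safe
    d[np.broadcast_to(denom == 0, d.shape)] = 0.0
    return priors, overall, centroids, s, s0, mk, d


def _soft_threshold(d: np.ndarray, delta: float) -> np.ndarray:
    return np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)


def _pam_discriminant(
    Xv: np.ndarray,
    overall: np.ndarray,
    s: np.ndarray,
    s0: float,
    mk: np.ndarray,
    dprime: np.ndarray,
    priors: np.ndarray,
) -> np.ndarray:
    """Discriminant scores, shape (n_samples, K); lower is closer."""
    denom = s + s0
    safe = np.where(denom == 0, 1.0, denom)
    shrunk = overall[:, None] + denom[:, None] * (mk[None, :] * dprime)
    K = len(priors)
    scores = np.empty((Xv.shape[1], K))
    for j in range(K):
        resid = (Xv - shrunk[:, j : j + 1]) / safe[:, None]
        scores[:, j] = (resid**2).sum(axis=0) - 2.0 * np.log(priors[j])
    return scores


def pam_fit(
    X: pd.DataFrame,
    y: Sequence[str],
    n_thresholds: int = 30,
    cv_folds: int = 5,
    seed: int = 0,
    delta: Optional[float] = None,
) -> PAMModel:
    """Fit a nearest-shrunken-centroid model.

    If ``delta`` is not given it is selected on a grid of ``n_thresholds``
    values in [0, max|d_ik|] by internal stratified cross-validation,
    minimizing the misclassification count with ties resolved toward the
    larger threshold (fewer surviving features).
    """
    y = np.asarray(y)
    classes = tuple(class_order(y))
    if len(classes) < 2:
        raise LabelError("PAM requires at least two classes")
    Xv = X.to_numpy(dtype=float)
    priors, overall, centroids, s, s0, mk, d = _pam_statistics(Xv, y, classes)
    dmax = float(np.abs(d).max()) if d.size else 0.0
    grid = np.linspace(0.0, dmax, max(2, n_thresholds))
    cv_errors = None
    if delta is None:
        min_class = min(int((y == c).sum()) for c in classes)
        folds = max(2, min(cv_folds, min_class))
        if min_class < 2:
            delta = 0.0
        else:
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            errors = np.zeros(grid.size)
            for tr, va in skf.split(Xv.T, y):
                stats = _pam_statistics(Xv[:, tr], y[tr], classes)
                f_priors, f_overall, _f_cent, f_s, f_s0, f_mk, f_d = stats
                for g, dlt in enumerate(grid):
                    dp = _soft_threshold(f_d, dlt)
                    sc = _pam_discriminant(
                        Xv[:, va], f_overall, f_s, f_s0, f_mk, dp, f_priors
                    )
                    pred = np.argmin(sc, axis=1)
                    errors[g] += (np.asarray(classes)[pred] != y[va]).sum()
            best = errors.min()
            # ties -> larger Delta (fewer genes)
            delta = float(grid[np.flatnonzero(errors == best).max()])
            cv_errors = errors
    dprime = _soft_threshold(d, float(delta))
    return PAMModel(
        feature_ids=tuple(X.index),
        classes=classes,
        priors=priors,
        overall=overall,
        centroids=centroids,
        s=s,
        s0=s0,
        mk=mk,
        delta=float(delta),
        dprime=dprime,
        cv_errors=cv_errors,
        delta_grid=grid,
    )


def pam_predict(model: PAMModel, X: pd.DataFrame) -> np.ndarray:
    """Assign each sample (column) to the nearest shrunken centroid."""
    if set(X.index) != set(model.feature_ids):
        raise ContractError("feature ids do not match the fitted PAM model")
    Xv = X.reindex(list(model.feature_ids)).to_numpy(dtype=float)
    scores = _pam_discriminant(
        Xv, model.overall, model.s, model.s0, model.mk, model.dprime, model.priors
    )
    pred = np.argmin(scores, axis=1)  # ties -> first class in label order
    return np.asarray(model.classes)[pred]


# ---------------------------------------------------------------------------
# unified train / predict


def nb_fit_discrete(
    X: pd.DataFrame,
    y: Sequence[str],
    alpha: float = 1.0,
    representation: str = "discrete",
) -> TrainedClassifier:
    """Categorical naive Bayes on integer bin matrices with additive
    smoothing ``alpha`` per (feature, class, bin)."""
    Xv = X.to_numpy(dtype=float)
    if not np.array_equal(Xv, np.round(Xv)) or (Xv < 1).any():
        raise ContractError(
            "categorical NB requires integer bins >= 1; got continuous values"
        )
    k = _repr_bins(representation) or int(Xv.max())
    impl = CategoricalNB(alpha=alpha, min_categories=k + 1)
    impl.fit(Xv.T.astype(int), np.asarray(y))
    return TrainedClassifier(
        method="nb",
        classes=tuple(class_order(y)),
        feature_ids=tuple(X.index),
        representation=representation,
        impl=impl,
        params={"alpha": alpha},
    )


def train(
    X: pd.DataFrame,
    y: Sequence[str],
    method: str,
    params: Optional[dict] = None,
    seed: int = 0,
    representation: str = REPR_FC,
) -> TrainedClassifier:
    """Train one of the four classifiers on a features x samples matrix."""
    if method not in METHODS:
        raise ConfigError(f"unknown classifier {method!r}")
    params = dict(params or {})
    y = np.asarray(y)
    classes = class_order(y)
    if len(classes) < 2:
        raise LabelError("training requires at least two classes")
    counts = {c: int((y == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise LabelError(f"class(es) {small} have fewer than 2 training samples")

    if method == "nb" and is_discrete_representation(representation):
        model = nb_fit_discrete(
            X, y, alpha=params.get("alpha", 1.0), representation=representation
        )
        return model

    Xt = X.to_numpy(dtype=float).T
    if method == "svm":
        impl = SVC(kernel="linear", C=params.get("C", 1.0))
        impl.fit(Xt, y)
    elif method == "rf":
        impl = RandomForestClassifier(
            n_estimators=params.get("n_trees", 500), random_state=seed, n_jobs=1
        )
        impl.fit(Xt, y)
    elif method == "nb":
        impl = GaussianNB()
        impl.fit(Xt, y)
    else:  # pam
        impl = pam_fit(
            X,
            y,
            n_thresholds=params.get("n_thresholds", 30),
            cv_folds=params.get("cv_folds", 5),
            seed=seed,
            delta=params.get("delta"),
        )
    return TrainedClassifier(
        method=method,
        classes=tuple(classes),
        feature_ids=tuple(X.index),
        representation=representation,
        impl=impl,
        params=params,
    )


def _check_input(model: TrainedClassifier, X: pd.DataFrame, representation) -> pd.DataFrame:
    if representation is not None and representation != model.representation:
        raise ContractError(
            f"model trained on representation {model.representation!r} "
            f"applied to {representation!r} data"
        )
    if set(X.index) != set(model.feature_ids):
        raise ContractError("feature list does not match the training feature list")
    X = X.reindex(list(model.feature_ids))
    if is_discrete_representation(model.representation):
        Xv = X.to_numpy(dtype=float)
        if not np.array_equal(Xv, np.round(Xv)):
            raise ContractError(
                f"model trained on {model.representation!r} bins applied to "
                "continuous values"
            )
    return X


def predict(
    model: TrainedClassifier, X: pd.DataFrame, representation: Optional[str] = None
) -> np.ndarray:
    """Predict one label from the training label set per sample (column)."""
    X = _check_input(model, X, representation)
    if model.method == "pam":
        return pam_predict(model.impl, X)
    if model.method == "nb" and isinstance(model.impl, CategoricalNB):
        Xt = X.to_numpy(dtype=float).T.astype(int)
    else:
        Xt = X.to_numpy(dtype=float).T
    return np.asarray(model.impl.predict(Xt))


def predict_proba(model: TrainedClassifier, X: pd.DataFrame) -> pd.DataFrame:
    """Class posterior probabilities (NB only); columns in impl class order."""
    X = _check_input(model, X, None)
    if model.method != "nb":
        raise ContractError("posterior probabilities are exposed for NB only")
    if isinstance(model.impl, CategoricalNB):
        Xt = X.to_numpy(dtype=float).T.astype(int)
    else:
        Xt = X.to_numpy(dtype=float).T
    proba = model.impl.predict_proba(Xt)
    return pd.DataFrame(proba, index=X.columns, columns=list(model.impl.classes_))
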