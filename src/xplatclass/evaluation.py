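"""Metrics and the two experiment drivers.

``run_same_platform`` trains and tests on stratified splits of one platform;
``run_cross_platform`` trains on platform A and tests on matched platform-B
samples.  Both sweep representation x selector x classifier x feature count
and report test accuracy per cell.

One policy everywhere: log2 fold change is computed per platform against that
platform's own normal reference, and discretization boundaries are refit
independently on every dataset (training and testing alike) — it is this
refit that lets rank-based bins carry a model across expression scales.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .classifiers import predict, representation_tag, train
from .data_io import SUBTYPES, RunConfig
from .discretize import discretize_matrix
from .exceptions import AlignmentError, ConfigError, SizeError, SplitError
from .feature_select import rank_by_cv, rank_by_rf_importance, svm_rfe
from .preprocess import fold_change, prefilter_features
from .report import CellResult, EvalReport

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics


def accuracy(y_true: Sequence[str], y_pred: Sequence[str]) -> float:
    """Overall accuracy: correct predictions over total, as a percent to one
    decimal (69 correct of 76 prints as 90.8)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise SizeError(
            f"length mismatch: {y_true.shape[0]} true vs {y_pred.shape[0]} predicted"
        )
    return round(100.0 * float((y_true == y_pred).sum()) / y_true.size, 1)


def _classes_for(y_true, y_pred) -> List[str]:
    present = set(np.asarray(y_true)) | set(np.asarray(y_pred))
    ordered = [c for c in SUBTYPES if c in present]
    ordered += sorted(present - set(SUBTYPES))
    return ordered


def confusion(
    y_true: Sequence[str], y_pred: Sequence[str], classes: Optional[List[str]] = None
) -> pd.DataFrame:
    """Confusion matrix, rows = true class, columns = predicted class."""
    if classes is None:
        classes = _classes_for(y_true, y_pred)
    cm = _sk_confusion(np.asarray(y_true), np.asarray(y_pred), labels=classes)
    return pd.DataFrame(cm, index=classes, columns=classes)


def per_class_sn_sp(
    y_true: Sequence[str], y_pred: Sequence[str], classes: Optional[List[str]] = None
) -> pd.DataFrame:
    """One-vs-rest sensitivity tp/(tp+fn) and specificity tn/(tn+fp).

    A class absent from ``y_true`` has undefined sensitivity, reported as NaN
    rather than zero.
    """
    cm = confusion(y_true, y_pred, classes)
    total = int(cm.to_numpy().sum())
    rows = []
    for cls in cm.index:
        tp = int(cm.loc[cls, cls])
        fn = int(cm.loc[cls].sum()) - tp
        fp = int(cm[cls].sum()) - tp
        tn = total - tp - fn - fp
        sn = tp / (tp + fn) if (tp + fn) > 0 else np.nan
        sp = tn / (tn + fp) if (tn + fp) > 0 else np.nan
        rows.append({"class": cls, "Sn": sn, "Sp": sp})
    return pd.DataFrame(rows).set_index("class")


def stratified_split(
    labels: pd.Series, train_fraction: float, seed: int
) -> Tuple[List[str], List[str]]:
    """Per-class proportional split; training counts rounded up (ceiling).

    Disjoint and exhaustive; deterministic per seed.  A class with fewer than
    two samples cannot be split.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ConfigError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    present = [c for c in SUBTYPES if c in set(labels)]
    present += sorted(set(labels) - set(SUBTYPES))
    train_ids: List[str] = []
    test_ids: List[str] = []
    for cls in present:
        ids = np.asarray(labels.index[labels == cls])
        if ids.size < 2:
            raise SplitError(f"class {cls!r} has fewer than 2 samples")
        n_train = int(np.ceil(train_fraction * ids.size))
        perm = rng.permutation(ids.size)
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    return train_ids, test_ids


# ---------------------------------------------------------------------------
# benchmark core


def _clip_grid(grid: Sequence[int], n_available: int) -> List[int]:
    ns = sorted({n for n in grid if n <= n_available})
    if any(n > n_available for n in grid):
        logger.warning(
            "feature grid clipped to the %d available features", n_available
        )
        if n_available not in ns:
            ns.append(n_available)
    return sorted(ns)


def _build_representation(
    fc_train: pd.DataFrame, fc_test: pd.DataFrame, rep: str, k: int, seed: int
) -> Tuple[pd.DataFrame, pd.DataFrame, str]:
    if rep == "fc":
        return fc_train, fc_test, representation_tag("fc")
    tr, _ = discretize_matrix(fc_train, rep, k, seed=seed)
    te, _ = discretize_matrix(fc_test, rep, k, seed=seed)
    return tr, te, representation_tag(rep, k)


def _classifier_params(config: RunConfig, clf: str) -> dict:
    if clf == "svm":
        return {"C": config.svm_c}
    if clf == "rf":
        return {"n_trees": config.n_trees}
    if clf == "nb":
        return {"alpha": config.nb_alpha}
    return {
        "n_thresholds": config.pam_n_thresholds,
        "cv_folds": config.pam_cv_folds,
    }


def _benchmark(
    train_raw: pd.DataFrame,
    fc_train: pd.DataFrame,
    fc_test: pd.DataFrame,
    y_train: pd.Series,
    y_test: pd.Series,
    config: RunConfig,
) -> EvalReport:
    """Sweep representation x selector x classifier x feature count.

    ``train_raw`` is the training tumor matrix on the expression scale; the
    CV-based pre-filter and the CV selector operate on it (CV = sigma/mu
    requires positive data), while SVM-RFE and RF importances rank on the
    representation the classifier will consume.
    """
    config.validate()
    nf = fc_train.shape[0]
    if config.prefilter_top_k is not None:
        feats = prefilter_features(
            train_raw, min(config.prefilter_top_k, nf), config.pearson_cutoff
        )
    else:
        feats = list(fc_train.index)
    fc_tr = fc_train.loc[feats]
    fc_te = fc_test.loc[feats]
    raw_tr = train_raw.loc[feats]

    report = EvalReport()
    for rep in config.representations:
        tr_rep, te_rep, tag = _build_representation(
            fc_tr, fc_te, rep, config.n_bins, config.seed + 1
        )
        for sel in config.selectors:
            if sel == "cv":
                ranking = rank_by_cv(raw_tr)
            elif sel == "svm_rfe":
                ranking = svm_rfe(
                    tr_rep, y_train, step_fraction=config.svm_rfe_step, C=config.svm_c
                )
            else:  # rf
                ranking = rank_by_rf_importance(
                    tr_rep, y_train, n_trees=config.n_trees, seed=config.seed + 2
                )
            ns = _clip_grid(config.feature_grid, len(feats))
            for clf in config.classifiers:
                for n in ns:
                    sub = ranking.top(n)
                    model = train(
                        tr_rep.loc[sub],
                        y_train,
                        clf,
                        params=_classifier_params(config, clf),
                        seed=config.seed + 3,
                        representation=tag,
                    )
                    pred = predict(model, te_rep.loc[sub])
                    acc = accuracy(y_test.to_numpy(), pred)
                    snsp = None
                    if config.snsp_top_n is not None and n == config.snsp_top_n:
                        table = per_class_sn_sp(y_test.to_numpy(), pred)
                        snsp = {
                            cls: {
                                "Sn": None if np.isnan(row["Sn"]) else round(row["Sn"], 3),
                                "Sp": None if np.isnan(row["Sp"]) else round(row["Sp"], 3),
                            }
                            for cls, row in table.iterrows()
                        }
                    report.cells.append(
                        CellResult(
                            classifier=clf,
                            selector=sel,
                            representation=tag,
                            n_features=n,
                            accuracy=acc,
                            snsp=snsp,
                        )
                    )
    return report


# ---------------------------------------------------------------------------
# experiment drivers


def run_same_platform(
    tumor: pd.DataFrame,
    normals: pd.DataFrame,
    labels: pd.Series,
    config: RunConfig,
) -> EvalReport:
    """Stratified train/test split on one platform, then the benchmark sweep.

    Discretization boundaries are refit on the test split too, keeping the
    one refit-per-dataset policy used everywhere.
    """
    labels = labels.reindex(tumor.columns)
    if labels.isna().any():
        raise AlignmentError("labels do not cover every tumor sample")
    train_ids, test_ids = stratified_split(labels, config.train_fraction, config.seed)
    fc = fold_change(tumor, normals)
    return _benchmark(
        tumor[train_ids],
        fc[train_ids],
        fc[test_ids],
        labels[train_ids],
        labels[test_ids],
        config,
    )


def run_cross_platform(
    tumor_a: pd.DataFrame,
    normals_a: pd.DataFrame,
    tumor_b: pd.DataFrame,
    normals_b: pd.DataFrame,
    labels: pd.Series,
    config: RunConfig,
    train_ids: Optional[Sequence[str]] = None,
    test_ids: Optional[Sequence[str]] = None,
) -> EvalReport:
    """Train on platform A, test on platform B.

    FC is computed per platform against its own normals; the representation
    is fitted independently per platform; selectors and classifiers see only
    platform A.  By default all platform-A samples train and all platform-B
    samples test; explicit id lists restrict either side.
    """
    if list(tumor_a.index) != list(tumor_b.index):
        if set(tumor_a.index) != set(tumor_b.index):
            raise AlignmentError("platforms disagree on feature ids")
        tumor_b = tumor_b.reindex(tumor_a.index)
    train_ids = list(train_ids) if train_ids is not None else list(tumor_a.columns)
    test_ids = list(test_ids) if test_ids is not None else list(tumor_b.columns)
    y_train = labels.reindex(train_ids)
    y_test = labels.reindex(test_ids)
    if y_train.isna().any() or y_test.isna().any():
        raise AlignmentError("labels do not cover every train/test sample")
    fc_a = fold_change(tumor_a[train_ids], normals_a)
    fc_b = fold_change(tumor_b[test_ids], normals_b)
    return _benchmark(tumor_a[train_ids], fc_a, fc_b, y_train, y_test, config)
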