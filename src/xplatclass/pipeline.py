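"""Top-level orchestration: preprocess -> discretize -> select -> train ->
evaluate, with reproducibility scaffolding (config capture, input digests,
fanned-out seeds, per-stage timing) and a fast self-check of the package's
core invariants.

The single global seed is fanned out to per-stage seeds by fixed offsets
(split: +0, discretization: +1, selection: +2, classification: +3) so each
stage is reproducible in isolation without seed collisions.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .classifiers import pam_fit, pam_predict
from .data_io import (
    RunConfig,
    read_expression_matrix,
    read_labels,
    write_report,
)
from .discretize import discretize_matrix, dougherty_max_bins, equal_freq_bins
from .evaluation import accuracy, per_class_sn_sp, run_cross_platform, run_same_platform
from .exceptions import XplatError
from .report import EvalReport

logger = logging.getLogger(__name__)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    config: RunConfig, inputs: Dict[str, str], outdir
) -> EvalReport:
    """Execute the full pipeline from files on disk and write all artifacts.

    ``inputs`` maps: ``train_tumor``, ``train_normals``, ``labels`` and,
    for a cross-platform run, ``test_tumor`` + ``test_normals`` plus an
    optional ``split`` — a JSON file with ``train_ids``/``test_ids`` lists
    restricting which platform-A samples train and which platform-B samples
    test (without it, all A samples train and all B samples test).  Writes
    ``report.json``, ``grid.tsv`` and ``manifest.json`` to *outdir*; the
    report is a pure function of (inputs, config, seed), so a rerun from the
    same manifest reproduces it byte for byte.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: List[dict] = []

    def timed(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                stages.append(
                    {"stage": name, "seconds": round(time.perf_counter() - self.t0, 3)}
                )

        return _T()

    cross = "test_tumor" in inputs
    try:
        with timed("read"):
            tumor_a = read_expression_matrix(inputs["train_tumor"])
            normals_a = read_expression_matrix(inputs["train_normals"])
            if cross:
                tumor_b = read_expression_matrix(inputs["test_tumor"])
                normals_b = read_expression_matrix(inputs["test_normals"])
                all_samples = list(tumor_a.columns) + [
                    s for s in tumor_b.columns if s not in set(tumor_a.columns)
                ]
            else:
                all_samples = list(tumor_a.columns)
            labels = read_labels(inputs["labels"], all_samples)
        train_ids = test_ids = None
        if cross and "split" in inputs:
            split = json.loads(Path(inputs["split"]).read_text())
            train_ids = split.get("train_ids")
            test_ids = split.get("test_ids")
        with timed("benchmark"):
            if cross:
                report = run_cross_platform(
                    tumor_a, normals_a, tumor_b, normals_b, labels, config,
                    train_ids=train_ids, test_ids=test_ids,
                )
            else:
                report = run_same_platform(tumor_a, normals_a, labels, config)
    except XplatError as exc:
        digest = {k: sha256_file(v) for k, v in inputs.items() if Path(v).exists()}
        raise type(exc)(
            f"pipeline stage failed: {exc} (input digests: {digest})"
        ) from exc

    with timed("write"):
        write_report(report, outdir / "report.json", outdir / "grid.tsv")
    manifest = {
        "version": __version__,
        "mode": "cross_platform" if cross else "same_platform",
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {k: sha256_file(v) for k, v in inputs.items()},
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# self-check


def _check_equal_freq_balance(rng) -> Optional[str]:
    v = rng.normal(size=40)  # distinct with probability 1
    bins, _ = equal_freq_bins(v, 8)
    occ = np.bincount(bins, minlength=9)[1:]
    if occ.max() - occ.min() > 1:
        return f"bin occupancies {occ.tolist()} differ by more than 1"
    return None


def _check_monotone_invariance(rng) -> Optional[str]:
    m = pd.DataFrame(rng.normal(size=(15, 30)) + 5.0)
    g = pd.DataFrame(np.exp(m.to_numpy() / 2.0) + m.to_numpy() ** 3)
    b1, _ = discretize_matrix(m, "equal_freq", 5)
    b2, _ = discretize_matrix(g, "equal_freq", 5)
    if not b1.equals(b2):
        return "equal-frequency bins changed under a strictly monotone transform"
    return None


def _check_equal_width_affine(rng) -> Optional[str]:
    m = pd.DataFrame(rng.normal(size=(10, 25)))
    b1, _ = discretize_matrix(m, "equal_width", 6)
    b2, _ = discretize_matrix(2.5 * m + 7.0, "equal_width", 6)
    if not b1.equals(b2):
        return "equal-width bins changed under a positive affine transform"
    return None


def _check_pam_delta0(rng) -> Optional[str]:
    X = pd.DataFrame(rng.normal(size=(8, 30)), index=[f"f{i}" for i in range(8)])
    y = np.array(["PN", "N", "CL"]).repeat(10)
    X.iloc[0, :10] += 2.0
    X.iloc[1, 10:20] += 2.0
    model = pam_fit(X, y, delta=0.0)
    pred = pam_predict(model, X)
    # brute-force standardized nearest centroid
    Xv = X.to_numpy()
    classes = model.classes
    cent = {c: Xv[:, y == c].mean(axis=1) for c in classes}
    denom = model.s + model.s0
    for j in range(Xv.shape[1]):
        scores = [
            (((Xv[:, j] - cent[c]) / denom) ** 2).sum() - 2 * np.log(model.priors[i])
            for i, c in enumerate(classes)
        ]
        if classes[int(np.argmin(scores))] != pred[j]:
            return f"PAM(delta=0) disagrees with nearest-centroid at sample {j}"
    return None


def _check_metrics(rng) -> Optional[str]:
    y = rng.choice(["PN", "N", "CL", "M"], size=200)
    p = rng.choice(["PN", "N", "CL", "M"], size=200)
    acc = accuracy(y, p)
    direct = round(100.0 * (y == p).mean(), 1)
    if acc != direct:
        return f"accuracy {acc} != direct count {direct}"
    table = per_class_sn_sp(y, p)
    for cls in table.index:
        tp = int(((y == cls) & (p == cls)).sum())
        fn = int(((y == cls) & (p != cls)).sum())
        tn = int(((y != cls) & (p != cls)).sum())
        fp = int(((y != cls) & (p == cls)).sum())
        if abs(table.loc[cls, "Sn"] - tp / (tp + fn)) > 1e-12:
            return f"Sn({cls}) disagrees with the one-vs-rest count"
        if abs(table.loc[cls, "Sp"] - tn / (tn + fp)) > 1e-12:
            return f"Sp({cls}) disagrees with the one-vs-rest count"
    return None


def _check_dougherty(rng) -> Optional[str]:
    if dougherty_max_bins(342) != 11:
        return "dougherty_max_bins(342) != 11"
    return None


def selfcheck() -> Tuple[bool, List[str]]:
    """Run the fast invariant suite; returns (all_passed, summary lines).

    Deterministic: the same fresh install produces the identical summary.
    """
    checks = [
        ("equal-frequency bin balance", _check_equal_freq_balance),
        ("equal-frequency monotone invariance", _check_monotone_invariance),
        ("equal-width affine invariance", _check_equal_width_affine),
        ("PAM delta=0 nearest-centroid agreement", _check_pam_delta0),
        ("accuracy / Sn-Sp counting oracle", _check_metrics),
        ("bin-number heuristic", _check_dougherty),
    ]
    lines: List[str] = []
    ok = True
    for name, fn in checks:
        rng = np.random.default_rng(0)
        try:
            detail = fn(rng)
        except Exception as exc:  # a failed check must not abort the sweep
            detail = f"raised {type(exc).__name__}: {exc}"
        if detail is None:
            lines.append(f"ok   - {name}")
        else:
            ok = False
            lines.append(f"FAIL - {name}: {detail}")
    lines.append(f"{'all checks passed' if ok else 'failures detected'}")
    return ok, lines
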