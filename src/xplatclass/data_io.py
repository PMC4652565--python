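"""Reading and writing of expression matrices, label tables, configs and reports.

File dialects owned here:

* expression matrix — TSV, first row sample ids, first column feature ids,
  features in rows (expression matrices have far more features than samples);
* labels — two-column TSV with header ``sample_id<TAB>subtype``;
* run config — YAML or JSON;
* benchmark report — JSON (full) plus a TSV grid (see :mod:`xplatclass.report`).

Missing values are rejected, never imputed: the pipeline assumes complete
matrices.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    ConfigError,
    CoverageError,
    FormatError,
    LabelError,
    ParseError,
)

#: The closed four-class subtype set: proneural, neural, classical, mesenchymal.
SUBTYPES: Tuple[str, ...] = ("PN", "N", "CL", "M")

#: Feature-count grid swept by the benchmark drivers.
DEFAULT_FEATURE_GRID: Tuple[int, ...] = tuple(range(10, 101, 10)) + tuple(
    range(150, 1001, 50)
)


def _find_bad_cell(path: Path) -> None:
    """Re-read *path* as text and raise :class:`ParseError` naming the first
    cell that is not a finite number."""
    raw = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    for r, fid in enumerate(raw.index):
        for c, sid in enumerate(raw.columns):
            cell = raw.iat[r, c]
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at feature {fid!r} "
                    f"(row {r + 2}), sample {sid!r} (column {c + 2})"
                ) from None
            if not np.isfinite(v):
                raise ParseError(
                    f"{path}: non-finite cell {cell!r} at feature {fid!r} "
                    f"(row {r + 2}), sample {sid!r} (column {c + 2})"
                )
    raise ParseError(f"{path}: matrix contains unparseable cells")


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a features x samples expression matrix from TSV.

    Returns a float DataFrame with feature ids as index and sample ids as
    columns, both preserved in file order.  NaN/inf cells and duplicate
    identifiers are rejected.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: expected at least one sample column")
    sample_ids = header[1:]
    sidx = pd.Index(sample_ids)
    if sidx.duplicated().any():
        dups = sorted(set(sidx[sidx.duplicated()]))
        raise FormatError(f"{path}: duplicate sample ids {dups}")
    df = pd.read_csv(path, sep="\t", header=0, index_col=0)
    df.index = df.index.astype(str)
    df.columns = sample_ids
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise FormatError(f"{path}: duplicate feature ids {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        _find_bad_cell(path)
        raise  # unreachable
    if not np.isfinite(values).all():
        _find_bad_cell(path)
    return pd.DataFrame(values, index=df.index, columns=df.columns)


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a features x samples matrix as TSV (>= 10 significant digits)."""
    matrix.to_csv(path, sep="\t", index_label="feature_id", float_format="%.10g")


def read_labels(path, samples: Sequence[str]) -> pd.Series:
    """Read a two-column label TSV and align it to *samples*.

    Every requested sample must be present exactly once and carry a subtype
    from the closed set ``{PN, N, CL, M}``.  Extra rows are ignored.
    """
    path = Path(path)
    tab = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if tab.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (sample_id, subtype)")
    sid_col, sub_col = tab.columns[0], tab.columns[1]
    if tab[sid_col].duplicated().any():
        dups = sorted(set(tab[sid_col][tab[sid_col].duplicated()]))
        raise FormatError(f"{path}: duplicate sample ids {dups}")
    bad = sorted(set(tab[sub_col]) - set(SUBTYPES))
    if bad:
        raise LabelError(
            f"{path}: unknown subtype token(s) {bad}; expected one of {SUBTYPES}"
        )
    mapping = dict(zip(tab[sid_col], tab[sub_col]))
    missing = [s for s in samples if s not in mapping]
    if missing:
        raise CoverageError(
            f"{path}: labels missing for {len(missing)} sample(s): "
            f"{missing[:10]}"
        )
    return pd.Series([mapping[s] for s in samples], index=list(samples), name="subtype")


def write_labels(labels: pd.Series, path) -> None:
    out = pd.DataFrame({"sample_id": labels.index, "subtype": labels.to_numpy()})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Settings for one benchmark run.

    ``representations`` may contain ``"fc"`` (continuous log2 fold change) and
    the discretizers ``"equal_width"``, ``"equal_freq"``, ``"kmeans"`` (fitted
    per feature with ``n_bins`` bins, refit independently on every dataset).
    """

    representations: Tuple[str, ...] = ("fc", "equal_width", "equal_freq", "kmeans")
    n_bins: int = 10
    selectors: Tuple[str, ...] = ("cv", "svm_rfe", "rf")
    classifiers: Tuple[str, ...] = ("svm", "rf", "nb", "pam")
    feature_grid: Tuple[int, ...] = DEFAULT_FEATURE_GRID
    train_fraction: float = 0.75
    seed: int = 0
    prefilter_top_k: Optional[int] = 2000
    pearson_cutoff: float = 0.8
    svm_rfe_step: float = 0.1
    rf_drop_fraction: float = 0.2
    n_trees: int = 200
    svm_c: float = 1.0
    nb_alpha: float = 1.0
    pam_n_thresholds: int = 30
    pam_cv_folds: int = 5
    snsp_top_n: Optional[int] = 100

    _VALID_REPRESENTATIONS = ("fc", "equal_width", "equal_freq", "kmeans")
    _VALID_SELECTORS = ("cv", "svm_rfe", "rf")
    _VALID_CLASSIFIERS = ("svm", "rf", "nb", "pam")

    def validate(self) -> "RunConfig":
        for r in self.representations:
            if r not in self._VALID_REPRESENTATIONS:
                raise ConfigError(f"unknown representation {r!r}")
        for s in self.selectors:
            if s not in self._VALID_SELECTORS:
                raise ConfigError(f"unknown selector {s!r}")
        for c in self.classifiers:
            if c not in self._VALID_CLASSIFIERS:
                raise ConfigError(f"unknown classifier {c!r}")
        uses_bins = any(r != "fc" for r in self.representations)
        if uses_bins and self.n_bins < 2:
            raise ConfigError("n_bins must be >= 2 when a discretizer is enabled")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigError("train_fraction must lie in (0, 1)")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an explicit integer")
        if not 0.0 < self.pearson_cutoff <= 1.0:
            raise ConfigError("pearson_cutoff must lie in (0, 1]")
        if not self.feature_grid or any(n < 1 for n in self.feature_grid):
            raise ConfigError("feature_grid must contain positive counts")
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        """Build a config from a flat or nested mapping.

        Nested keys ``discretization: {method, k}``, ``selection: {method}``,
        ``classifier: {method}`` and ``grid`` are accepted alongside the flat
        field names.
        """
        d = dict(d)
        kwargs = {}
        disc = d.pop("discretization", None)
        if disc is not None:
            method = disc.get("method", "none")
            kwargs["representations"] = (
                ("fc",) if method in ("none", "fc") else (str(method),)
            )
            if "k" in disc:
                kwargs["n_bins"] = int(disc["k"])
        sel = d.pop("selection", None)
        if sel is not None:
            kwargs["selectors"] = (str(sel.get("method", "cv")),)
            kwargs.update(sel.get("params", {}) or {})
        clf = d.pop("classifier", None)
        if clf is not None:
            kwargs["classifiers"] = (str(clf.get("method", "svm")),)
            kwargs.update(clf.get("params", {}) or {})
        if "grid" in d:
            kwargs["feature_grid"] = tuple(int(n) for n in d.pop("grid"))
        valid = {f.name for f in dataclasses.fields(cls)}
        for key, value in d.items():
            if key not in valid:
                raise ConfigError(f"unknown config key {key!r}")
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        cfg = cls(**kwargs)
        return cfg.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d


def read_run_config(path) -> RunConfig:
    """Read a :class:`RunConfig` from YAML or JSON (by file extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def write_report(report, json_path, tsv_path=None) -> None:
    """Write an :class:`~xplatclass.report.EvalReport` as JSON plus TSV grid."""
    json_path = Path(json_path)
    if tsv_path is None:
        tsv_path = json_path.with_suffix(".tsv")
    report.to_json(json_path)
    report.to_grid_tsv(tsv_path)
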