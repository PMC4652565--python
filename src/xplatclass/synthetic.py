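"""Synthetic matched two-platform tumor + normal datasets with known subtype
structure.

The generator emulates the study design this package targets: four tumor
subtypes with class-specific differential expression on a subset of features,
a cohort of matched samples whose shared latent log2 expression is observed
through two platform-specific strictly monotone transforms with independent
technical noise, and a pool of platform-matched normal reference samples.

Generative model (all on the latent log2 scale):

    L[f, s] = baseline_f + effect_size * 1{f informative for class(s)}
              + Normal(0, sigma_bio)
    O_p[f, s] = 2 ** ( T_p(L[f, s]) + Normal(0, sigma_platform) )

Normals are drawn with no class effect; their latent draws are shared between
the platforms (the same reference individuals observed on each platform), so
that when both transforms are the identity and platform noise is zero the two
platforms coincide exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .data_io import SUBTYPES, write_expression_matrix, write_labels
from .exceptions import ConfigError, DomainError


# ---------------------------------------------------------------------------
# Monotone platform transforms


@dataclass(frozen=True)
class TransformSpec:
    """A strictly increasing map applied elementwise to latent log2 values.

    Kinds: ``identity``; ``affine`` (a*x + b, a > 0); ``power`` (x**gamma,
    gamma > 0, domain x >= 0); ``log_shift`` (ln(x + c), domain x > -c);
    ``piecewise`` (monotone linear interpolation through knots, linearly
    extrapolated with the end-segment slopes); ``compose`` (parts applied in
    listed order).
    """

    kind: str
    params: tuple = ()

    def validate(self) -> "TransformSpec":
        if self.kind == "identity":
            pass
        elif self.kind == "affine":
            a, _b = self.params
            if not a > 0:
                raise ConfigError("affine transform requires slope a > 0")
        elif self.kind == "power":
            (gamma,) = self.params
            if not gamma > 0:
                raise ConfigError("power transform requires gamma > 0")
        elif self.kind == "log_shift":
            (_c,) = self.params
        elif self.kind == "piecewise":
            knots = np.asarray(self.params, dtype=float)
            if knots.ndim != 2 or knots.shape[0] < 2 or knots.shape[1] != 2:
                raise ConfigError("piecewise transform needs >= 2 (x, y) knots")
            if not (np.diff(knots[:, 0]) > 0).all() or not (
                np.diff(knots[:, 1]) > 0
            ).all():
                raise ConfigError(
                    "piecewise knots must be strictly increasing in x and y"
                )
        elif self.kind == "compose":
            if not self.params:
                raise ConfigError("compose transform needs at least one part")
            for part in self.params:
                part.validate()
        else:
            raise ConfigError(f"unknown transform kind {self.kind!r}")
        return self

    # convenient constructors -------------------------------------------------
    @staticmethod
    def identity() -> "TransformSpec":
        return TransformSpec("identity")

    @staticmethod
    def affine(a: float, b: float) -> "TransformSpec":
        return TransformSpec("affine", (float(a), float(b))).validate()

    @staticmethod
    def power(gamma: float) -> "TransformSpec":
        return TransformSpec("power", (float(gamma),)).validate()

    @staticmethod
    def log_shift(c: float) -> "TransformSpec":
        return TransformSpec("log_shift", (float(c),)).validate()

    @staticmethod
    def piecewise(knots: Sequence[Tuple[float, float]]) -> "TransformSpec":
        return TransformSpec(
            "piecewise", tuple((float(x), float(y)) for x, y in knots)
        ).validate()

    @staticmethod
    def compose(*parts: "TransformSpec") -> "TransformSpec":
        return TransformSpec("compose", tuple(parts)).validate()

    def to_dict(self) -> dict:
        if self.kind == "compose":
            return {"kind": "compose", "parts": [p.to_dict() for p in self.params]}
        return {"kind": self.kind, "params": list(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "TransformSpec":
        kind = d["kind"]
        if kind == "compose":
            return cls(
                "compose", tuple(cls.from_dict(p) for p in d["parts"])
            ).validate()
        params = d.get("params", [])
        if kind == "piecewise":
            params = tuple(tuple(float(v) for v in knot) for knot in params)
        else:
            params = tuple(float(v) for v in params)
        return cls(kind, params).validate()


def apply_transform(values, spec: TransformSpec) -> np.ndarray:
    """Apply a monotone transform elementwise; preserves order statistics."""
    spec.validate()
    v = np.asarray(values, dtype=float)
    if spec.kind == "identity":
        return v.copy()
    if spec.kind == "affine":
        a, b = spec.params
        return a * v + b
    if spec.kind == "power":
        (gamma,) = spec.params
        if (v < 0).any():
            raise DomainError("power transform requires values >= 0")
        return v**gamma
    if spec.kind == "log_shift":
        (c,) = spec.params
        if (v + c <= 0).any():
            raise DomainError(f"log_shift({c}) requires values > {-c}")
        return np.log(v + c)
    if spec.kind == "piecewise":
        knots = np.asarray(spec.params, dtype=float)
        kx, ky = knots[:, 0], knots[:, 1]
        out = np.interp(v, kx, ky)
        lo_slope = (ky[1] - ky[0]) / (kx[1] - kx[0])
        hi_slope = (ky[-1] - ky[-2]) / (kx[-1] - kx[-2])
        below, above = v < kx[0], v > kx[-1]
        out = np.where(below, ky[0] + (v - kx[0]) * lo_slope, out)
        out = np.where(above, ky[-1] + (v - kx[-1]) * hi_slope, out)
        return out
    if spec.kind == "compose":
        for part in spec.params:
            v = apply_transform(v, part)
        return np.asarray(v)
    raise ConfigError(f"unknown transform kind {spec.kind!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Simulation configuration and output


@dataclass(frozen=True)
class SimulationConfig:
    n_features: int = 500
    n_informative_per_class: int = 10
    n_tumor_per_class: int = 50  # training cohort, platform A
    n_test_per_class: int = 19  # matched cohort observed on both platforms
    n_normals: int = 8  # per platform
    effect_size: float = 1.5  # latent log2 shift on informative features
    sigma_bio: float = 0.5  # biological noise SD (latent log2 units)
    sigma_platform: float = 0.3  # technical noise SD, per platform
    transform_a: TransformSpec = field(
        default_factory=lambda: TransformSpec.affine(1.0, 0.0)
    )
    transform_b: TransformSpec = field(
        default_factory=lambda: TransformSpec.compose(
            TransformSpec.power(1.8), TransformSpec.affine(3.0, 10.0)
        )
    )
    baseline_range: Tuple[float, float] = (4.0, 12.0)
    overlapping_signatures: bool = False
    seed: int = 42

    def validate(self) -> "SimulationConfig":
        if self.n_informative_per_class * len(SUBTYPES) > self.n_features:
            raise ConfigError(
                "n_informative_per_class x 4 must not exceed n_features"
            )
        if min(self.sigma_bio, self.sigma_platform) < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.n_tumor_per_class < 1 or self.n_test_per_class < 1:
            raise ConfigError("per-class sample counts must be >= 1")
        if self.n_normals < 1:
            raise ConfigError("n_normals must be >= 1")
        if not self.baseline_range[1] > self.baseline_range[0]:
            raise ConfigError("baseline_range must be an increasing interval")
        self.transform_a.validate()
        self.transform_b.validate()
        return self


@dataclass
class PairedDataset:
    """Matched samples observed on two platforms, plus normals and truth.

    ``tumor_a`` and ``tumor_b`` share feature and sample identifiers; the
    designated ``train_ids``/``test_ids`` partition mirrors the train-on-A,
    test-on-B design.
    """

    tumor_a: pd.DataFrame
    tumor_b: pd.DataFrame
    normals_a: pd.DataFrame
    normals_b: pd.DataFrame
    labels: pd.Series
    truth: Dict[str, List[str]]
    train_ids: List[str]
    test_ids: List[str]

    @property
    def informative_features(self) -> List[str]:
        out: List[str] = []
        for cls in SUBTYPES:
            out.extend(self.truth.get(cls, []))
        return sorted(set(out))


def default_scenario() -> SimulationConfig:
    """The documented acceptance scenario (a reduced-scale four-subtype,
    two-platform design): 500 features, 10 informative per class, 50 training
    tumors per class on platform A, 19 matched test tumors per class, 8
    normals per platform, effect size 1.5, sigma_bio 0.5, sigma_platform 0.3,
    platform A identity-scale and platform B a nonlinear power-law map."""
    return SimulationConfig().validate()


def generate_paired_dataset(config: SimulationConfig) -> PairedDataset:
    """Generate a :class:`PairedDataset`; a pure function of ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    nf = config.n_features
    m = config.n_informative_per_class
    feature_ids = [f"iso{i:05d}" for i in range(nf)]

    baselines = rng.uniform(*config.baseline_range, nf)

    # class-specific informative feature sets
    truth: Dict[str, List[str]] = {}
    informative_idx: Dict[str, np.ndarray] = {}
    if config.overlapping_signatures:
        for cls in SUBTYPES:
            idx = rng.choice(nf, size=m, replace=False)
            informative_idx[cls] = np.sort(idx)
    else:
        pool = rng.permutation(nf)[: len(SUBTYPES) * m]
        for j, cls in enumerate(SUBTYPES):
            informative_idx[cls] = np.sort(pool[j * m : (j + 1) * m])
    for cls in SUBTYPES:
        truth[cls] = [feature_ids[i] for i in informative_idx[cls]]

    # sample bookkeeping: training block then matched test block, class-major
    train_ids: List[str] = []
    test_ids: List[str] = []
    label_values: List[str] = []
    for cls in SUBTYPES:
        train_ids.extend(
            f"{cls}-tr{j:03d}" for j in range(config.n_tumor_per_class)
        )
    for cls in SUBTYPES:
        test_ids.extend(f"{cls}-te{j:03d}" for j in range(config.n_test_per_class))
    sample_ids = train_ids + test_ids
    for sid in sample_ids:
        label_values.append(sid.split("-")[0])
    labels = pd.Series(label_values, index=sample_ids, name="subtype")

    # latent tumor log2 expression, shared by both platforms (matched samples)
    ns = len(sample_ids)
    latent = baselines[:, None] + rng.normal(0.0, config.sigma_bio, size=(nf, ns))
    for cls in SUBTYPES:
        cols = np.flatnonzero(labels.to_numpy() == cls)
        rows = informative_idx[cls]
        latent[np.ix_(rows, cols)] += config.effect_size

    # latent normal reference log2 expression: the same reference individuals
    # are observed on each platform
    latent_norm = baselines[:, None] + rng.normal(
        0.0, config.sigma_bio, size=(nf, config.n_normals)
    )

    def observe(lat: np.ndarray, spec: TransformSpec) -> np.ndarray:
        t = apply_transform(lat, spec)
        t = t + rng.normal(0.0, config.sigma_platform, size=t.shape)
        return 2.0**t

    tumor_a = observe(latent, config.transform_a)
    tumor_b = observe(latent, config.transform_b)
    normals_a = observe(latent_norm, config.transform_a)
    normals_b = observe(latent_norm, config.transform_b)

    normal_ids_a = [f"NA{j:02d}" for j in range(config.n_normals)]
    normal_ids_b = [f"NB{j:02d}" for j in range(config.n_normals)]
    return PairedDataset(
        tumor_a=pd.DataFrame(tumor_a, index=feature_ids, columns=sample_ids),
        tumor_b=pd.DataFrame(tumor_b, index=feature_ids, columns=sample_ids),
        normals_a=pd.DataFrame(normals_a, index=feature_ids, columns=normal_ids_a),
        normals_b=pd.DataFrame(normals_b, index=feature_ids, columns=normal_ids_b),
        labels=labels,
        truth=truth,
        train_ids=train_ids,
        test_ids=test_ids,
    )


def write_dataset(dataset: PairedDataset, outdir) -> None:
    """Write tumor/normal matrices, labels and the truth record to *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(dataset.tumor_a, outdir / "tumor_A.tsv")
    write_expression_matrix(dataset.tumor_b, outdir / "tumor_B.tsv")
    write_expression_matrix(dataset.normals_a, outdir / "normals_A.tsv")
    write_expression_matrix(dataset.normals_b, outdir / "normals_B.tsv")
    write_labels(dataset.labels, outdir / "labels.tsv")
    (outdir / "truth.json").write_text(
        json.dumps(
            {
                "informative": dataset.truth,
                "train_ids": dataset.train_ids,
                "test_ids": dataset.test_ids,
            },
            indent=2,
            sort_keys=True,
        )
    )


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain mapping (YAML/JSON)."""
    d = dict(d)
    for key in ("transform_a", "transform_b"):
        if key in d and isinstance(d[key], dict):
            d[key] = TransformSpec.from_dict(d[key])
    if "baseline_range" in d:
        d["baseline_range"] = tuple(float(v) for v in d["baseline_range"])
    try:
        cfg = SimulationConfig(**d)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None
    return cfg.validate()
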