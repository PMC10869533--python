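"""Core data containers, I/O and run configuration.

The central object is :class:`FeatureTable`: an ``n_samples x n_features``
real matrix with a binary outcome vector (1 = event, e.g. nodal metastasis
present; 0 = absent), unique feature names and unique sample identifiers.
Everything downstream — preselection, LASSO, the genetic search and the
evaluation stack — consumes this container.

Feature tables are exchanged as comma-delimited UTF-8 text with a header
row; the label column is named explicitly.  Run configuration is a flat
``key=value`` text file that round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("galambda")

__all__ = [
    "FeatureTable",
    "SplitSpec",
    "RunConfig",
    "read_feature_table",
    "write_feature_table",
    "split_train_test",
]


@dataclass(frozen=True)
class FeatureTable:
    """A labeled feature matrix: samples in rows, features in columns."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    labels: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = values.shape
        if labels.shape != (n,):
            raise ValueError("labels length must equal the number of rows")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal the number of rows")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must equal the number of columns")
        if len(set(self.feature_names)) != p:
            raise ValueError("duplicate feature names")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if not np.isfinite(values).all():
            raise ValueError("missing or non-finite values in feature matrix")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("non-binary label: labels must be 0/1")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_rows(self, indices: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(
            self.values[idx],
            self.feature_names,
            self.labels[idx],
            tuple(self.sample_ids[i] for i in idx),
        )

    def subset_columns(self, indices: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(
            self.values[:, idx],
            tuple(self.feature_names[i] for i in idx),
            self.labels,
            self.sample_ids,
        )


@dataclass(frozen=True)
class SplitSpec:
    """A train/test partition of sample indices.

    ``|train| = round_half_up(n * ratio_train)`` so that 181 samples at a
    6:4 ratio give a 109-sample training set.
    """

    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    ratio: tuple[float, float]
    seed: int

    def __post_init__(self) -> None:
        train = set(self.train_indices)
        test = set(self.test_indices)
        if train & test:
            raise ValueError("train and test indices overlap")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_train_test(
    table: FeatureTable,
    ratio: tuple[float, float] = (0.6, 0.4),
    seed: int = 0,
    stratified: bool = True,
) -> SplitSpec:
    """Randomly partition samples into train/test at the given ratio.

    The training-set size is the round-half-up of ``n * ratio_train``.
    With ``stratified=True`` the per-class train fractions differ from the
    global fraction by at most one sample per class.
    """
    r = np.asarray(ratio, dtype=float)
    if (r <= 0).any():
        raise ValueError("ratio components must be positive")
    frac_train = r[0] / r.sum()
    n = table.n_samples
    n_train = _round_half_up(n * frac_train)
    rng = np.random.default_rng(seed)

    if not stratified:
        perm = rng.permutation(n)
        train = np.sort(perm[:n_train])
        test = np.sort(perm[n_train:])
    else:
        train_parts: list[np.ndarray] = []
        for cls in (0, 1):
            members = np.flatnonzero(table.labels == cls)
            if len(members) < 2:
                raise ValueError(
                    f"class {cls} has fewer than 2 samples; cannot stratify"
                )
            perm = rng.permutation(members)
            k = _round_half_up(len(members) * frac_train)
            train_parts.append(perm[:k])
        train = np.sort(np.concatenate(train_parts))
        # Per-class rounding can put the total off by one relative to the
        # global round-half-up target; rebalance by moving single samples
        # of the majority class.
        while len(train) != n_train:
            in_train = np.zeros(n, dtype=bool)
            in_train[train] = True
            if len(train) > n_train:
                cls_counts = np.bincount(table.labels[train], minlength=2)
                cls = int(np.argmax(cls_counts))
                pool = np.flatnonzero(in_train & (table.labels == cls))
                drop = pool[rng.integers(len(pool))]
                train = np.setdiff1d(train, [drop])
            else:
                cls_counts = np.bincount(table.labels[~in_train], minlength=2)
                cls = int(np.argmax(cls_counts))
                pool = np.flatnonzero(~in_train & (table.labels == cls))
                add = pool[rng.integers(len(pool))]
                train = np.sort(np.append(train, add))
        test = np.setdiff1d(np.arange(n), train)

    return SplitSpec(
        tuple(int(i) for i in train),
        tuple(int(i) for i in test),
        (float(r[0] / r.sum()), float(r[1] / r.sum())),
        int(seed),
    )


def read_feature_table(
    path: str | Path,
    label_column: str = "label",
    allow_median_impute: bool = False,
) -> FeatureTable:
    """Load a delimited feature table with a binary label column.

    The first column is used as the sample identifier if it is named
    ``sample_id``; otherwise row numbers are used.  Missing values are
    rejected unless ``allow_median_impute`` is set, in which case they are
    replaced by the per-feature median (logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found")
    if "sample_id" in df.columns:
        sample_ids = tuple(str(s) for s in df.pop("sample_id"))
    else:
        sample_ids = tuple(f"s{i}" for i in range(len(df)))
    labels = df.pop(label_column).to_numpy()
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("non-binary label")
    names = tuple(str(c) for c in df.columns)
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        if not allow_median_impute:
            raise ValueError("missing values present; imputation not enabled")
        med = np.nanmedian(values, axis=0)
        nan_rows, nan_cols = np.nonzero(np.isnan(values))
        values[nan_rows, nan_cols] = med[nan_cols]
        logger.warning("imputed %d missing values with feature medians", len(nan_rows))
    return FeatureTable(values, names, labels.astype(int), sample_ids)


def write_feature_table(
    table: FeatureTable, path: str | Path, label_column: str = "label"
) -> None:
    """Write a feature table as CSV (full float precision)."""
    df = pd.DataFrame(table.values, columns=list(table.feature_names))
    df.insert(0, "sample_id", list(table.sample_ids))
    df[label_column] = table.labels
    df.to_csv(path, index=False, float_format="%.17g")


# --------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with study defaults.

    One global ``seed`` fans out to per-stage child seeds by fixed offsets
    so each stage is independently reproducible.
    """

    # preselection
    alpha: float = 0.05
    rho: float = 0.8
    alpha_grid: tuple[float, ...] = (0.01, 0.025, 0.05, 0.075, 0.10)
    rho_grid: tuple[float, ...] = (0.70, 0.75, 0.80, 0.85, 0.90)
    # lasso
    nlambdas: int = 100
    lambda_min_ratio: float = 1e-3
    cv_folds: int = 5
    df_cap_fraction: float = 0.1  # cap on nonzeros: floor(n_train/10); 0.2 -> n/5
    # genetic algorithm
    population_size: int = 50
    generations: int = 100
    stagnation_window: int = 25
    mutation_rate: float | None = None  # None -> 1/nvars per locus
    init_p_lo: float = 0.2
    init_p_hi: float = 0.8
    excellent_nums: tuple[int, ...] = (3, 2, 1)
    excellent_mse_quantiles: tuple[float, ...] = (0.2, 0.4, 0.6)
    # evaluation
    bootstrap_samples: int = 100
    ci_level: float = 0.95
    pooled_cv: bool = True
    # split
    split_ratio: tuple[float, float] = (0.6, 0.4)
    stratified_split: bool = True
    # global
    seed: int = 0

    # per-stage child seeds (fixed offsets from the global seed)
    _STAGE_OFFSETS = {
        "split": 11,
        "preselection": 23,
        "lasso": 37,
        "ga": 53,
        "evaluation": 71,
        "synthetic": 97,
    }

    def stage_seed(self, stage: str) -> int:
        if stage not in self._STAGE_OFFSETS:
            raise KeyError(f"unknown stage {stage!r}")
        return (int(self.seed) + self._STAGE_OFFSETS[stage]) % (2**31 - 1)

    def df_max(self, n_train: int) -> int:
        return max(1, int(np.floor(n_train * self.df_cap_fraction)))

    # -- flat key=value (de)serialization -------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(repr(x) for x in v)
            lines.append(f"{f.name}={v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            raw[key.strip()] = val.strip()
        kwargs: dict[str, object] = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            s = raw[f.name]
            if f.type.startswith("tuple"):
                items = [x for x in s.split(",") if x]
                elem = float if "float" in f.type or "int" not in f.type else int
                kwargs[f.name] = tuple(elem(x) for x in items)
            elif f.type.startswith("int"):
                kwargs[f.name] = int(s)
            elif f.type.startswith("bool"):
                kwargs[f.name] = s in ("True", "true", "1")
            elif f.type.startswith("float | None"):
                kwargs[f.name] = None if s == "None" else float(s)
            else:
                kwargs[f.name] = float(s)
        return cls(**kwargs)  # type: ignore[arg-type]

    def validate(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.rho <= 1):
            raise ValueError("alpha in (0,1), rho in (0,1] required")
        if self.nlambdas < 2 or not (0 < self.lambda_min_ratio < 1):
            raise ValueError("invalid lambda grid parameters")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.population_size < 4 or self.population_size % 2:
            raise ValueError("population_size must be even and >= 4")
        if not (0 <= self.init_p_lo <= self.init_p_hi <= 1):
            raise ValueError("invalid initialization probability range")
        if len(self.excellent_nums) != len(self.excellent_mse_quantiles):
            raise ValueError("excellent-gene schedule lengths must match")
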