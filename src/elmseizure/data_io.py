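"""Reading, relabelling, rescaling and splitting of chunked EEG tables.

The canonical input is the UCI "Epileptic Seizure Recognition" CSV dialect:
one row per 1-second EEG chunk, feature columns ``X1..X178`` holding raw ADC
amplitudes, and a label column ``y`` in {1..5} where 1 is ictal (seizure) and
2--5 are non-seizure conditions (pre-ictal, inter-ictal, healthy eyes closed,
healthy eyes open).  An optional unnamed leading id column (subject/chunk
codes such as ``X21.V1.791``) is auto-detected.

Everything downstream of the reader works on plain numpy arrays wrapped in
two light dataclasses, :class:`LabeledDataset` (5-class) and
:class:`BinaryDataset` (seizure vs non-seizure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DatasetFormatError",
    "DatasetParseError",
    "LabeledDataset",
    "BinaryDataset",
    "SplitSpec",
    "Split",
    "Rescaler",
    "read_dataset",
    "write_dataset",
    "relabel_binary",
    "fit_rescaler",
    "apply_rescaler",
    "split",
    "balance_training",
]

FIVE_CLASSES = (1, 2, 3, 4, 5)
SEIZURE_CLASS = 1


class DatasetFormatError(ValueError):
    """The file does not have the expected tabular layout."""


class DatasetParseError(ValueError):
    """A cell could not be parsed as a number."""


def _as_2d_float(features) -> np.ndarray:
    X = np.asarray(features)
    if X.ndim != 2:
        raise DatasetFormatError(f"features must be 2-D, got shape {X.shape}")
    return X


@dataclass(frozen=True)
class LabeledDataset:
    """An n x m table of EEG chunk amplitudes with 5-class labels."""

    features: np.ndarray
    labels: np.ndarray
    row_ids: tuple[str, ...] | None = None
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self):
        X = _as_2d_float(self.features)
        y = np.asarray(self.labels)
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)
        if y.ndim != 1 or len(y) != len(X):
            raise DatasetFormatError("labels must be 1-D with one entry per row")
        if len(y) and not np.isin(y, FIVE_CLASSES).all():
            bad = sorted(set(np.unique(y)) - set(FIVE_CLASSES))
            raise ValueError(f"labels outside {{1..5}}: {bad}")
        if not np.isfinite(np.asarray(X, dtype=float)).all():
            raise DatasetParseError("features contain missing/non-finite values")
        if self.row_ids is not None and len(self.row_ids) != len(X):
            raise DatasetFormatError("row_ids length mismatch")
        if self.feature_names is not None and len(self.feature_names) != X.shape[1]:
            raise DatasetFormatError("feature_names length mismatch")

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def take(self, idx: np.ndarray) -> "LabeledDataset":
        ids = None if self.row_ids is None else tuple(self.row_ids[i] for i in idx)
        return replace(self, features=self.features[idx], labels=self.labels[idx], row_ids=ids)


@dataclass(frozen=True)
class BinaryDataset:
    """Same feature table with labels collapsed to {0 = no seizure, 1 = seizure}."""

    features: np.ndarray
    labels: np.ndarray
    row_ids: tuple[str, ...] | None = None
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self):
        X = _as_2d_float(self.features)
        y = np.asarray(self.labels)
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)
        if y.ndim != 1 or len(y) != len(X):
            raise DatasetFormatError("labels must be 1-D with one entry per row")
        if len(y) and not np.isin(y, (0, 1)).all():
            raise ValueError("binary labels must be 0 or 1")

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def prevalence(self) -> float:
        return float(np.mean(self.labels == 1))

    def take(self, idx: np.ndarray) -> "BinaryDataset":
        ids = None if self.row_ids is None else tuple(self.row_ids[i] for i in idx)
        return replace(self, features=self.features[idx], labels=self.labels[idx], row_ids=ids)


def read_dataset(path, label_col: str = "y") -> LabeledDataset:
    """Read a UCI-dialect CSV into a :class:`LabeledDataset`.

    The header must contain ``label_col``; every other column is a feature,
    kept in header order.  An unnamed leading column is treated as row ids.

    Raises
    ------
    DatasetFormatError
        missing label column or ragged rows.
    DatasetParseError
        non-numeric or blank cells (the message carries the row index).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.ParserError as e:
        raise DatasetFormatError(f"inconsistent column count in {path}: {e}") from e
    if df.columns.size == 0:
        raise DatasetFormatError(f"{path} has no header")

    row_ids = None
    first = str(df.columns[0])
    if first.startswith("Unnamed") or first == "":
        row_ids = tuple(df.iloc[:, 0].astype(str))
        df = df.drop(columns=[df.columns[0]])

    if label_col not in df.columns:
        raise DatasetFormatError(f"label column {label_col!r} not found in {path}")

    feat_cols = [c for c in df.columns if c != label_col]
    feats = df[feat_cols].apply(pd.to_numeric, errors="coerce")
    bad = feats.isna().any(axis=1)
    if bad.any():
        r = int(np.flatnonzero(bad.to_numpy())[0])
        raise DatasetParseError(f"non-numeric or blank feature cell at data row {r}")
    labels = pd.to_numeric(df[label_col], errors="coerce")
    if labels.isna().any():
        r = int(np.flatnonzero(labels.isna().to_numpy())[0])
        raise DatasetParseError(f"non-numeric or blank label at data row {r}")

    X = feats.to_numpy()
    y = labels.to_numpy()
    if np.issubdtype(y.dtype, np.floating) and np.allclose(y, np.round(y)):
        y = y.astype(int)
    return LabeledDataset(X, y, row_ids=row_ids, feature_names=tuple(feat_cols))


def write_dataset(ds: LabeledDataset | BinaryDataset, path, label_col: str = "y") -> None:
    """Write a dataset back to the same CSV dialect (id column if present)."""
    names = ds.feature_names or tuple(f"X{i + 1}" for i in range(ds.n_features))
    df = pd.DataFrame(ds.features, columns=list(names))
    # keep integer-valued tables integer so the round-trip is textual too
    if np.allclose(ds.features, np.round(ds.features)):
        df = df.astype(np.int64)
    df[label_col] = np.asarray(ds.labels)
    if ds.row_ids is not None:
        df.insert(0, "", list(ds.row_ids))
    df.to_csv(path, index=False)


def relabel_binary(ds: LabeledDataset) -> BinaryDataset:
    """Collapse the 5-class labels to seizure (class 1 -> 1) vs rest (-> 0).

    Feeding an already-binary dataset is rejected: label 0 is outside {1..5}.
    """
    y = np.asarray(ds.labels)
    if not np.isin(y, FIVE_CLASSES).all():
        bad = sorted(set(np.unique(y)) - set(FIVE_CLASSES))
        raise ValueError(f"labels outside {{1..5}} (already binarized?): {bad}")
    return BinaryDataset(
        ds.features,
        (y == SEIZURE_CLASS).astype(int),
        row_ids=ds.row_ids,
        feature_names=ds.feature_names,
    )


@dataclass(frozen=True)
class Rescaler:
    """Per-column affine map (x - center) / scale fitted on training data only.

    Uses the population variance convention (divide by n), so a two-point
    column [1, 3] maps exactly to [-1, +1].  Zero-variance columns are either
    dropped (default) or raise, recorded in ``dropped``.
    """

    center: np.ndarray
    scale: np.ndarray
    kept: np.ndarray           # bool mask over original columns
    dropped: tuple[int, ...] = ()

    def to_text(self) -> str:
        lines = [f"n_columns\t{self.kept.size}",
                 "dropped\t" + ",".join(map(str, self.dropped))]
        for j, (c, s) in enumerate(zip(self.center, self.scale)):
            lines.append(f"col\t{j}\t{float(c)!r}\t{float(s)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "Rescaler":
        lines = [l for l in text.splitlines() if l.strip()]
        n_cols = int(lines[0].split("\t")[1])
        drop_field = lines[1].split("\t")
        dropped = tuple(int(x) for x in drop_field[1].split(",")) if len(drop_field) > 1 and drop_field[1] else ()
        center, scale = [], []
        for l in lines[2:]:
            _, _, c, s = l.split("\t")
            center.append(float(c))
            scale.append(float(s))
        kept = np.ones(n_cols, dtype=bool)
        kept[list(dropped)] = False
        return cls(np.array(center), np.array(scale), kept, dropped)


def fit_rescaler(train_features: np.ndarray, zero_variance: str = "drop") -> Rescaler:
    """Fit per-column center/scale (unit population variance) on training rows.

    Parameters
    ----------
    zero_variance : {"drop", "error"}
        Policy for constant columns.
    """
    X = _as_2d_float(np.asarray(train_features, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows to fit a rescaler")
    center = X.mean(axis=0)
    scale = X.std(axis=0)  # population sd, ddof=0
    zero = scale == 0.0
    if zero.any():
        if zero_variance == "error":
            raise ValueError(f"zero-variance columns: {np.flatnonzero(zero).tolist()}")
        if zero_variance != "drop":
            raise ValueError(f"unknown zero_variance policy {zero_variance!r}")
        warnings.warn(
            f"dropping {int(zero.sum())} zero-variance column(s): "
            f"{np.flatnonzero(zero).tolist()}",
            UserWarning,
            stacklevel=2,
        )
    kept = ~zero
    return Rescaler(center[kept], scale[kept], kept, tuple(np.flatnonzero(zero).tolist()))


def apply_rescaler(r: Rescaler, features: np.ndarray) -> np.ndarray:
    """Apply fitted center/scale unchanged to any partition (drops same columns)."""
    X = _as_2d_float(np.asarray(features, dtype=float))
    if X.shape[1] != r.kept.size:
        raise DatasetFormatError(
            f"rescaler fitted on {r.kept.size} columns, got {X.shape[1]}"
        )
    return (X[:, r.kept] - r.center) / r.scale


@dataclass(frozen=True)
class SplitSpec:
    """Train/holdout split protocol.

    ``halve_holdout`` divides the holdout 50/50 into validation and test,
    matching the protocol in which an 11,500-row table at 80/20 yields
    9200 training, 1150 validation and 1150 test rows.
    """

    train_frac: float
    halve_holdout: bool = False
    stratified: bool = True
    seed: int = 0


@dataclass(frozen=True)
class Split:
    train: LabeledDataset | BinaryDataset
    test: LabeledDataset | BinaryDataset
    validation: LabeledDataset | BinaryDataset | None = None
    train_idx: np.ndarray | None = None
    validation_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None


def _largest_remainder(ideal: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment: floor + distribute remainder by largest fraction."""
    base = np.floor(ideal).astype(int)
    short = total - int(base.sum())
    if short > 0:
        frac = ideal - base
        order = np.lexsort((np.arange(len(ideal)), -frac))
        base[order[:short]] += 1
    elif short < 0:  # numerical edge: trim from smallest fractions
        frac = ideal - base
        order = np.lexsort((np.arange(len(ideal)), frac))
        for j in order:
            if short == 0:
                break
            if base[j] > 0:
                base[j] -= 1
                short += 1
    return base


def split(ds: BinaryDataset | LabeledDataset, spec: SplitSpec) -> Split:
    """Partition rows into train / (validation) / test per the protocol.

    Train receives round(train_frac * n) rows.  With ``stratified`` (default)
    each partition's class prevalence matches the full table within rounding.
    Deterministic under a fixed seed.
    """
    n = ds.n_rows
    if n < 10:
        raise ValueError(f"need at least 10 rows to split, got {n}")
    if not (0.0 < spec.train_frac < 1.0):
        raise ValueError(f"train_frac must be in (0,1), got {spec.train_frac}")
    n_train = int(round(spec.train_frac * n))
    n_hold = n - n_train
    if n_train == 0 or n_hold == 0:
        raise ValueError("a partition received 0 rows")
    if spec.halve_holdout:
        n_val = n_hold // 2
        n_test = n_hold - n_val
        if n_val == 0:
            raise ValueError("validation partition received 0 rows")
    else:
        n_val, n_test = 0, n_hold

    rng = np.random.default_rng(spec.seed)
    y = np.asarray(ds.labels)

    if spec.stratified:
        classes = np.unique(y)
        n_c = np.array([(y == c).sum() for c in classes], dtype=float)
        # allocate test first so its prevalence is proportional within 1 row
        test_c = _largest_remainder(n_c * n_test / n, n_test)
        rem_c = n_c - test_c
        val_c = _largest_remainder(rem_c * (n_val / max(n - n_test, 1)), n_val)
        train_c = (n_c - test_c - val_c).astype(int)
        if (train_c < 0).any():
            raise ValueError("stratified allocation failed (class too small)")
        tr_parts, va_parts, te_parts = [], [], []
        for c, ntr, nva, nte in zip(classes, train_c, val_c, test_c):
            idx = rng.permutation(np.flatnonzero(y == c))
            te_parts.append(idx[:nte])
            va_parts.append(idx[nte:nte + nva])
            tr_parts.append(idx[nte + nva:])
        train_idx = np.sort(np.concatenate(tr_parts))
        val_idx = np.sort(np.concatenate(va_parts)) if n_val else np.array([], dtype=int)
        test_idx = np.sort(np.concatenate(te_parts))
    else:
        perm = rng.permutation(n)
        test_idx = np.sort(perm[:n_test])
        val_idx = np.sort(perm[n_test:n_test + n_val])
        train_idx = np.sort(perm[n_test + n_val:])

    return Split(
        train=ds.take(train_idx),
        validation=ds.take(val_idx) if n_val else None,
        test=ds.take(test_idx),
        train_idx=train_idx,
        validation_idx=val_idx if n_val else None,
        test_idx=test_idx,
    )


def balance_training(ds: BinaryDataset, seed: int = 0) -> BinaryDataset:
    """Duplicate minority-class rows until the two classes are 50/50.

    Optional mode mimicking a reported training prevalence of 0.5; not part
    of the default protocol.
    """
    y = np.asarray(ds.labels)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to balance")
    if n_pos == n_neg:
        return ds
    minority = 1 if n_pos < n_neg else 0
    need = abs(n_neg - n_pos)
    pool = np.flatnonzero(y == minority)
    rng = np.random.default_rng(seed)
    extra = np.concatenate([np.tile(pool, need // len(pool)),
                            rng.choice(pool, need % len(pool), replace=False)])
    idx = np.concatenate([np.arange(len(y)), extra]).astype(int)
    return ds.take(idx)
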