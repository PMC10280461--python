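"""Reading, encoding, splitting, and augmenting clinical feature tables.

The tables handled here are patient-per-row CSV files mixing binary symptom
indicators (0/1), integer-coded categoricals (country, location, ...), and
genuinely numeric columns (age, day counts), with a binary outcome column.
Loading refuses missing cells rather than imputing: no imputation rule is part
of the method, and silently inventing one would change the classification
problem being solved.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DatasetError",
    "TabularDataset",
    "FoldAssignment",
    "AugmentationResult",
    "load_table",
    "write_table",
    "integer_encode",
    "make_folds",
    "augment_dataset",
]


class DatasetError(ValueError):
    """Raised for malformed tables: missing cells, bad labels, absent columns."""


@dataclass
class TabularDataset:
    """A numeric feature matrix with a binary outcome label per row.

    Parameters
    ----------
    values
        Array of shape ``(n_rows, n_features)``; all cells finite.
    labels
        Integer array of length ``n_rows`` holding only 0 and 1
        (1 = positive outcome, e.g. death).
    feature_names
        Unique column identifiers, one per feature, order preserved.
    label_name
        Name of the outcome column (used when writing back to CSV).
    encodings
        For text columns that were integer-encoded on load, the
        ``{column: {string: code}}`` mappings, kept for reporting and so that
        augmentation can recognise coded categoricals.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    label_name: str = "label"
    encodings: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise DatasetError("values must be a 2-D matrix")
        if self.labels.shape != (self.values.shape[0],):
            raise DatasetError("labels length must equal number of rows")
        if not np.isin(self.labels, (0, 1)).all():
            raise DatasetError("labels must contain only 0 and 1")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DatasetError(
                f"non-finite value at row {bad[0]}, column "
                f"{self.feature_names[bad[1]]!r}"
            )
        if len(self.feature_names) != self.values.shape[1]:
            raise DatasetError("one feature name per column required")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DatasetError("feature names must be unique")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def binary_columns(self) -> np.ndarray:
        """Boolean flag per column: True where every value is 0 or 1."""
        return np.array(
            [np.isin(self.values[:, j], (0.0, 1.0)).all() for j in range(self.n_features)]
        )

    def column_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise DatasetError(f"no column named {name!r}") from None

    def fingerprint(self) -> str:
        """Content hash of values+labels, for run manifests."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.values).tobytes())
        h.update(np.ascontiguousarray(self.labels).tobytes())
        h.update("\x00".join(self.feature_names).encode())
        return h.hexdigest()


@dataclass
class FoldAssignment:
    """A partition of rows into near-equal cross-validation folds."""

    fold_index: np.ndarray  # value in 0..folds-1 per row
    folds: int

    def __post_init__(self) -> None:
        self.fold_index = np.asarray(self.fold_index, dtype=int)

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (train_rows, validation_rows) for one held-out fold."""
        val = self.fold_index == fold
        return np.flatnonzero(~val), np.flatnonzero(val)


def integer_encode(raw_column: list[str]) -> tuple[list[int], dict[str, int]]:
    """Map distinct strings to consecutive integers in first-appearance order.

    Returns the encoded column and the ``{string: code}`` mapping so reports
    can translate back.
    """
    if len(raw_column) == 0:
        raise DatasetError("cannot encode an empty column")
    mapping: dict[str, int] = {}
    codes = []
    for v in raw_column:
        if v not in mapping:
            mapping[v] = len(mapping)
        codes.append(mapping[v])
    return codes, mapping


def load_table(path, label_column: str, delimiter: str = ",") -> TabularDataset:
    """Load a delimited table, integer-encoding text columns.

    The label column is removed from the feature matrix; feature column order
    and row order follow the file. Missing cells are an error naming the first
    offending row and column.
    """
    try:
        df = pd.read_csv(path, sep=delimiter)
    except FileNotFoundError:
        raise DatasetError(f"no such file: {path}") from None
    if label_column not in df.columns:
        raise DatasetError(f"label column {label_column!r} not found in {path}")
    na = df.isna()
    if na.to_numpy().any():
        row = int(na.any(axis=1).idxmax())
        col = na.columns[na.loc[row].to_numpy().argmax()]
        raise DatasetError(f"missing value at row {row}, column {col!r}")

    encodings: dict[str, dict[str, int]] = {}
    columns = {}
    for col in df.columns:
        series = df[col]
        if series.dtype == object:
            codes, mapping = integer_encode([str(v) for v in series])
            columns[col] = np.asarray(codes, dtype=float)
            encodings[col] = mapping
        else:
            columns[col] = series.to_numpy(dtype=float)

    labels = columns.pop(label_column)
    if not np.isin(labels, (0.0, 1.0)).all():
        bad = labels[~np.isin(labels, (0.0, 1.0))][0]
        raise DatasetError(
            f"label column {label_column!r} must be binary; saw value {bad!r}"
        )
    names = [c for c in df.columns if c != label_column]
    return TabularDataset(
        values=np.column_stack([columns[c] for c in names]) if names else np.empty((len(df), 0)),
        labels=labels.astype(int),
        feature_names=names,
        label_name=label_column,
        encodings={k: v for k, v in encodings.items() if k != label_column},
    )


def write_table(ds: TabularDataset, path, delimiter: str = ",") -> None:
    """Write the dataset back to CSV, label column last, header included."""
    df = pd.DataFrame(ds.values, columns=ds.feature_names)
    df[ds.label_name] = ds.labels
    df.to_csv(path, sep=delimiter, index=False)


def make_folds(n_rows: int, folds: int = 5, seed: int = 0) -> FoldAssignment:
    """Randomly partition rows into `folds` near-equal folds.

    Deterministic for a fixed seed; fold sizes differ by at most one.
    """
    if folds < 2:
        raise DatasetError("need at least 2 folds")
    if folds > n_rows:
        raise DatasetError(f"cannot split {n_rows} rows into {folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    fold_index = np.empty(n_rows, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        fold_index[chunk] = f
    return FoldAssignment(fold_index=fold_index, folds=folds)


@dataclass
class AugmentationResult:
    """An augmented dataset plus the provenance of every appended row."""

    dataset: TabularDataset
    source_rows: np.ndarray  # original row index each appended row was copied from
    rules: list[str]  # "age" or "jitter", per appended row


def augment_dataset(
    ds: TabularDataset,
    fraction: float,
    age_column: str | None = None,
    age_shrink: float = 0.05,
    numeric_jitter: float = 0.01,
    seed: int = 0,
) -> AugmentationResult:
    """Append lightly perturbed copies of uniformly chosen rows.

    Each appended row is a copy of a random source row in which, by a fair
    coin, EITHER the age value is reduced by exactly ``age_shrink`` (5% by
    default) OR every non-binary numeric feature is perturbed by a relative
    amount drawn uniformly within ``±numeric_jitter`` (1% by default).
    Binary indicator columns and integer-coded categoricals are never touched,
    labels are copied unchanged, and the original rows are preserved
    bit-exactly. When no age column is named, every appended row takes the
    jitter rule.
    """
    if not 0 < fraction <= 1:
        raise DatasetError("fraction must be in (0, 1]")
    if age_column is not None:
        age_idx = ds.column_index(age_column)
    else:
        age_idx = None

    n_new = round(fraction * ds.n_rows)
    rng = np.random.default_rng(seed)
    sources = rng.integers(0, ds.n_rows, size=n_new)

    binary = ds.binary_columns()
    jitterable = [
        j
        for j in range(ds.n_features)
        if not binary[j] and ds.feature_names[j] not in ds.encodings
    ]

    new_rows = np.empty((n_new, ds.n_features))
    rules: list[str] = []
    for i, src in enumerate(sources):
        row = ds.values[src].copy()
        use_age = age_idx is not None and rng.random() < 0.5
        if use_age:
            row[age_idx] *= 1.0 - age_shrink
            rules.append("age")
        else:
            for j in jitterable:
                row[j] *= 1.0 + rng.uniform(-numeric_jitter, numeric_jitter)
            rules.append("jitter")
        new_rows[i] = row

    out = TabularDataset(
        values=np.vstack([ds.values, new_rows]),
        labels=np.concatenate([ds.labels, ds.labels[sources]]),
        feature_names=list(ds.feature_names),
        label_name=ds.label_name,
        encodings=dict(ds.encodings),
    )
    return AugmentationResult(dataset=out, source_rows=sources, rules=rules)
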