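"""Core data containers and plain-text readers/writers.

Two input dialects are supported:

* separate files — a whitespace-separated numeric matrix (one sample per
  line) plus aligned one-value-per-line label / fold / band files;
* a single TSV with a header row, where the reserved column names
  ``label``, ``fold``, ``band`` and ``category`` are split off and every
  remaining column is a feature.

Labels are permissive: any value > 0 is positive, everything else negative,
so 1/2 codings parse without preprocessing.  Sample indices are 0-based
internally and 1-based in user-facing error messages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataFormatError

RESERVED_TSV_COLUMNS = ("label", "fold", "band", "category")


@dataclass(frozen=True)
class HyperParams:
    """The six learning hyper-parameters of the hyper-ensemble.

    Attributes
    ----------
    n_parts : int
        Number of disjoint parts into which the negatives are partitioned;
        one random forest is trained per part.
    fp : int
        SMOTE oversampling factor: synthetic positives generated per
        original positive (0 disables oversampling).
    ratio : int
        Undersampling ratio: negatives retained per effective positive
        (original + synthetic) in each part's training set.
    k : int
        Number of nearest positive neighbours used by SMOTE.
    n_trees : int
        Trees per random forest.
    m_try : int
        Features sampled at each decision-tree split node.
    """

    n_parts: int = 100
    fp: int = 2
    ratio: int = 3
    k: int = 5
    n_trees: int = 10
    m_try: int = 5

    def __post_init__(self) -> None:
        for name, minimum in (
            ("n_parts", 1),
            ("fp", 0),
            ("ratio", 1),
            ("k", 1),
            ("n_trees", 1),
            ("m_try", 1),
        ):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < minimum:
                raise ConfigurationError(
                    f"hyper-parameter {name!r} must be an integer >= {minimum}, got {value!r}"
                )
            object.__setattr__(self, name, int(value))

    def validate_for(self, n_features: int) -> None:
        """Check feasibility against a dataset's feature count."""
        if self.m_try > n_features:
            raise ConfigurationError(
                f"m_try={self.m_try} exceeds the number of features ({n_features})"
            )

    def as_dict(self) -> dict:
        return {
            "n_parts": self.n_parts,
            "fp": self.fp,
            "ratio": self.ratio,
            "k": self.k,
            "n_trees": self.n_trees,
            "m_try": self.m_try,
        }


@dataclass
class Dataset:
    """A feature matrix with binary labels and optional annotations.

    ``labels`` uses 1 for the minority/positive class and 0 for the
    majority/negative class.  ``band_ids`` carries a cytogenetic-band (or
    other locality-group) identifier per sample; ``category_ids`` a
    regulatory-region category per sample.
    """

    features: np.ndarray
    labels: np.ndarray
    band_ids: Optional[np.ndarray] = None
    category_ids: Optional[np.ndarray] = None
    fold_ids: Optional[np.ndarray] = None
    sample_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise DataFormatError("features must be a 2-D matrix (n_samples x n_features)")
        if self.features.shape[1] < 1:
            raise DataFormatError("features must have at least one column")
        if not np.isfinite(self.features).all():
            bad = np.argwhere(~np.isfinite(self.features))[0]
            raise DataFormatError(
                f"features contain a non-finite value at sample {bad[0] + 1}, column {bad[1] + 1}"
            )
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or len(self.labels) != self.n_samples:
            raise DataFormatError(
                f"labels: length mismatch — {len(np.atleast_1d(self.labels))} labels for "
                f"{self.n_samples} samples"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise DataFormatError("labels must contain only {0, 1}")
        self.labels = self.labels.astype(np.int8)
        for name in ("band_ids", "category_ids", "fold_ids", "sample_ids"):
            vec = getattr(self, name)
            if vec is None:
                continue
            vec = np.asarray(vec)
            if vec.ndim != 1 or len(vec) != self.n_samples:
                raise DataFormatError(
                    f"{name}: length mismatch — {len(np.atleast_1d(vec))} values for "
                    f"{self.n_samples} samples"
                )
            setattr(self, name, vec)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def positive_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 1)

    @property
    def negative_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 0)

    @property
    def n_positives(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negatives(self) -> int:
        return int((self.labels == 0).sum())

    def subset(self, indices: Sequence[int]) -> "Dataset":
        """Row-subset every aligned vector; indices keep their order."""
        idx = np.asarray(indices)
        return Dataset(
            features=self.features[idx],
            labels=self.labels[idx],
            band_ids=None if self.band_ids is None else self.band_ids[idx],
            category_ids=None if self.category_ids is None else self.category_ids[idx],
            fold_ids=None if self.fold_ids is None else self.fold_ids[idx],
            sample_ids=None if self.sample_ids is None else self.sample_ids[idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented

        def _veq(a, b):
            if a is None or b is None:
                return a is None and b is None
            return len(a) == len(b) and bool((np.asarray(a) == np.asarray(b)).all())

        return (
            self.features.shape == other.features.shape
            and bool(np.array_equal(self.features, other.features))
            and _veq(self.labels, other.labels)
            and _veq(self.band_ids, other.band_ids)
            and _veq(self.category_ids, other.category_ids)
            and _veq(self.fold_ids, other.fold_ids)
            and _veq(self.sample_ids, other.sample_ids)
        )


def _coerce_labels(raw: np.ndarray) -> np.ndarray:
    """Map raw numeric labels to {0,1}: any value > 0 is positive."""
    return (np.asarray(raw, dtype=float) > 0).astype(np.int8)


def _read_column_file(path: Path, what: str, numeric: bool) -> np.ndarray:
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            if numeric:
                try:
                    values.append(float(token))
                except ValueError as exc:
                    raise DataFormatError(
                        f"{what} file {path}: non-numeric value {token!r} at line {lineno}"
                    ) from exc
            else:
                values.append(token)
    return np.asarray(values)


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a whitespace-separated numeric matrix, one sample per line."""
    path = Path(path)
    rows: list[list[float]] = []
    width: Optional[int] = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            row = []
            for col, token in enumerate(tokens, start=1):
                try:
                    row.append(float(token))
                except ValueError as exc:
                    raise DataFormatError(
                        f"matrix file {path}: non-numeric cell {token!r} at row {lineno}, "
                        f"column {col}"
                    ) from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise DataFormatError(
                    f"matrix file {path}: row {lineno} has {len(row)} columns, expected {width}"
                )
            rows.append(row)
    if not rows:
        raise DataFormatError(f"matrix file {path} is empty")
    return np.asarray(rows, dtype=float)


def read_dataset(
    matrix_path: str | Path,
    labels_path: str | Path,
    band_path: str | Path | None = None,
    fold_path: str | Path | None = None,
    category_path: str | Path | None = None,
) -> Dataset:
    """Assemble a :class:`Dataset` from the separate-files dialect.

    Raises
    ------
    DataFormatError
        On a row-count mismatch between the matrix and any aligned file
        (the message names both counts) or on any non-numeric cell.
    """
    features = read_matrix(matrix_path)
    n = features.shape[0]
    raw_labels = _read_column_file(Path(labels_path), "labels", numeric=True)
    if len(raw_labels) != n:
        raise DataFormatError(
            f"length mismatch: labels file has {len(raw_labels)} values but the matrix has "
            f"{n} rows"
        )
    extras: dict[str, Optional[np.ndarray]] = {"band_ids": None, "fold_ids": None, "category_ids": None}
    for key, path, numeric in (
        ("band_ids", band_path, False),
        ("fold_ids", fold_path, True),
        ("category_ids", category_path, False),
    ):
        if path is None:
            continue
        vec = _read_column_file(Path(path), key, numeric=numeric)
        if len(vec) != n:
            raise DataFormatError(
                f"length mismatch: {key} file has {len(vec)} values but the matrix has {n} rows"
            )
        extras[key] = vec.astype(int) if numeric else vec
    return Dataset(features=features, labels=_coerce_labels(raw_labels), **extras)


def read_dataset_tsv(path: str | Path) -> Dataset:
    """Read the single-TSV dialect (header row; reserved column names)."""
    frame = pd.read_csv(path, sep="\t")
    if "label" not in frame.columns:
        raise DataFormatError(f"TSV file {path} lacks the required 'label' column")
    reserved = [c for c in RESERVED_TSV_COLUMNS if c in frame.columns]
    feature_cols = [c for c in frame.columns if c not in reserved]
    if not feature_cols:
        raise DataFormatError(f"TSV file {path} has no feature columns")
    features = frame[feature_cols].to_numpy(dtype=float)
    return Dataset(
        features=features,
        labels=_coerce_labels(frame["label"].to_numpy()),
        band_ids=frame["band"].to_numpy() if "band" in reserved else None,
        category_ids=frame["category"].to_numpy() if "category" in reserved else None,
        fold_ids=frame["fold"].to_numpy(dtype=int) if "fold" in reserved else None,
    )


def write_dataset(
    dataset: Dataset,
    matrix_path: str | Path,
    labels_path: str | Path,
    band_path: str | Path | None = None,
    category_path: str | Path | None = None,
) -> None:
    """Write the separate-files dialect; round-trips with :func:`read_dataset`."""
    np.savetxt(matrix_path, dataset.features, fmt="%.17g")
    np.savetxt(labels_path, dataset.labels, fmt="%d")
    if band_path is not None:
        if dataset.band_ids is None:
            raise ConfigurationError("band_path given but the dataset has no band_ids")
        Path(band_path).write_text("".join(f"{b}\n" for b in dataset.band_ids))
    if category_path is not None:
        if dataset.category_ids is None:
            raise ConfigurationError("category_path given but the dataset has no category_ids")
        Path(category_path).write_text("".join(f"{c}\n" for c in dataset.category_ids))


def write_scores(
    scores: Sequence[float],
    path: str | Path,
    sample_ids: Optional[Sequence[str]] = None,
) -> None:
    """Write scores one per line with 6-digit fixed precision.

    With ``sample_ids`` given, each line is ``<id>\t<score>``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size and (not np.isfinite(scores).all() or scores.min() < 0 or scores.max() > 1):
        raise DataFormatError("scores must be finite and within [0, 1]")
    if sample_ids is not None and len(sample_ids) != len(scores):
        raise DataFormatError(
            f"length mismatch: {len(sample_ids)} sample ids for {len(scores)} scores"
        )
    with open(path, "w") as fh:
        for i, s in enumerate(scores):
            if sample_ids is not None:
                fh.write(f"{sample_ids[i]}\t{s:.6f}\n")
            else:
                fh.write(f"{s:.6f}\n")


def read_scores(path: str | Path) -> np.ndarray:
    """Read a score file written by :func:`write_scores` (either layout)."""
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                values.append(float(tokens[-1]))
            except ValueError as exc:
                raise DataFormatError(
                    f"score file {path}: non-numeric value at line {lineno}"
                ) from exc
    return np.asarray(values, dtype=float)
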