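"""Loading, preprocessing and writing of expression-matrix datasets.

The in-memory container is :class:`Dataset`: a dense ``N x M`` float matrix
(samples in rows), a binary label vector coded ``{-1, +1}``, and feature /
sample identifiers.  Input files are delimited text (comma for ``.csv``,
tab otherwise) with one header row and one row per sample; gene-in-rows
files are handled by ``transpose=True``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class Dataset:
    """A two-class sample-by-feature expression dataset.

    Attributes
    ----------
    values:
        ``(N, M)`` float array, samples in rows.  Never contains NaN.
    labels:
        ``(N,)`` int array with values in ``{-1, +1}``; both classes present.
    feature_names:
        ``M`` unique strings.
    sample_ids:
        ``N`` strings.
    label_mapping:
        Raw label value -> code, recorded at load time (None for datasets
        built programmatically with labels already coded).
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    label_mapping: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (samples x features)")
        n, m = self.values.shape
        if n < 4 or m < 2:
            raise ValueError(f"need N >= 4 samples and M >= 2 features, got {n}x{m}")
        if self.labels.shape != (n,):
            raise ValueError("labels length must match number of samples")
        if not set(np.unique(self.labels)) == {-1, 1}:
            raise ValueError("labels must contain both classes, coded -1/+1")
        if np.isnan(self.values).any():
            raise ValueError("values contain missing entries; enable mean imputation")
        if len(self.feature_names) != m:
            raise ValueError("feature_names length must match number of features")
        if len(set(self.feature_names)) != m:
            raise ValueError("feature_names must be unique")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match number of samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "Dataset":
        """Row-subset copy (used by CV splitters)."""
        idx = np.asarray(idx)
        return Dataset(
            values=self.values[idx].copy(),
            labels=self.labels[idx].copy(),
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in idx],
            label_mapping=self.label_mapping,
        )


def _mean_impute(values: np.ndarray) -> np.ndarray:
    """Replace NaN cells by the per-feature mean over non-missing entries."""
    out = values.copy()
    col_mean = np.nanmean(out, axis=0)
    nan_r, nan_c = np.where(np.isnan(out))
    out[nan_r, nan_c] = col_mean[nan_c]
    return out


def load_dataset(
    path: str | Path,
    label_column: str,
    *,
    transpose: bool = False,
    impute_mean: bool = False,
    has_ids: bool = True,
) -> Dataset:
    """Read a delimited text file into a :class:`Dataset`.

    The two raw label values are mapped to ``-1``/``+1`` in sorted order
    (the lexicographically/numerically smaller value becomes ``-1``); the
    mapping is stored on ``Dataset.label_mapping`` and written to the run
    log by the CLI.

    Parameters
    ----------
    path:
        CSV (``.csv``) or TSV (any other extension) file with a header row.
    label_column:
        Name of the column holding the two class labels.
    transpose:
        The file stores genes in rows; transpose after reading.  The label
        column is then a *row* of the original file.
    impute_mean:
        Replace missing feature cells by the per-feature mean.  Off by
        default; loading fails on missing values when off.
    has_ids:
        First column holds sample identifiers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0 if has_ids else None)
    if transpose:
        df = df.T
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path.name}")

    raw_labels = df[label_column]
    classes = sorted(raw_labels.unique(), key=str)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 distinct labels, found {len(classes)}")
    mapping = {classes[0]: -1, classes[1]: 1}
    labels = raw_labels.map(mapping).to_numpy()

    feats = df.drop(columns=[label_column])
    values = feats.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    bad = np.isnan(values)
    if bad.any():
        if not impute_mean:
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"non-numeric or missing cell at sample {feats.index[r]!r}, "
                f"feature {feats.columns[c]!r}; pass impute_mean=True to mean-impute"
            )
        values = _mean_impute(values)

    return Dataset(
        values=values,
        labels=labels,
        feature_names=[str(c) for c in feats.columns],
        sample_ids=[str(i) for i in feats.index],
        label_mapping={str(k): v for k, v in mapping.items()},
    )


# ---------------------------------------------------------------------------
# min-max rescaling (parameters learned on a training partition only)
# ---------------------------------------------------------------------------

def fit_min_max(train_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature minima and ranges of the training matrix.

    Constant features get range 0 and are mapped to 0 on application.
    """
    mins = train_values.min(axis=0)
    ranges = train_values.max(axis=0) - mins
    return mins, ranges


def apply_min_max(values: np.ndarray, mins: np.ndarray, ranges: np.ndarray) -> np.ndarray:
    out = np.zeros_like(values, dtype=np.float64)
    nz = ranges != 0
    out[:, nz] = (values[:, nz] - mins[nz]) / ranges[nz]
    # constant training features map to 0 regardless of the applied value
    return out


def rescale_min_max(train: Dataset, apply_to: Dataset) -> Dataset:
    """Min-max rescale ``apply_to`` with parameters learned on ``train``.

    Each feature is mapped by ``(x - min_train) / (max_train - min_train)``;
    values outside the training range extrapolate (no clipping).  Features
    constant on the training data map to 0.
    """
    if train.feature_names != apply_to.feature_names:
        raise ValueError("train and apply_to must share feature_names")
    mins, ranges = fit_min_max(train.values)
    return Dataset(
        values=apply_min_max(apply_to.values, mins, ranges),
        labels=apply_to.labels.copy(),
        feature_names=list(apply_to.feature_names),
        sample_ids=list(apply_to.sample_ids),
        label_mapping=apply_to.label_mapping,
    )


# ---------------------------------------------------------------------------
# result output
# ---------------------------------------------------------------------------

def write_subset_tsv(path: str | Path, members: Sequence[int],
                     feature_names: Sequence[str],
                     weights: Sequence[float] | None = None) -> None:
    """Write the selected subset as rank / index / name / final weight TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("rank\tfeature_index\tfeature_name\tfinal_weight\n")
        for rank, f in enumerate(members, start=1):
            w = "" if weights is None else f"{weights[f]:.12g}"
            fh.write(f"{rank}\t{f}\t{feature_names[f]}\t{w}\n")


def read_subset_tsv(path: str | Path) -> list[int]:
    """Reload the feature indices from a subset TSV (round-trip helper)."""
    df = pd.read_csv(path, sep="\t")
    return [int(i) for i in df["feature_index"]]


def write_run_log(path: str | Path, record: dict) -> None:
    Path(path).write_text(json.dumps(record, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
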