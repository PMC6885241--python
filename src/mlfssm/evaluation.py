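"""Subset accuracy estimation and the outer cross-validation protocol.

Two nested levels of cross-validation are used, and they must not be
confused:

* the **inner** CV is the accuracy oracle ``accu(ft)`` that scores every
  candidate subset during the search — a stratified k-fold (default 5)
  restricted to the training partition, returning the pooled accuracy
  (total correct predictions / N);
* the **outer** CV (default 20 repeats of stratified 5-fold) estimates the
  generalization accuracy of the complete select-then-classify pipeline.
  Feature selection, and any rescaling, are fit strictly inside each outer
  training partition; the held-out fold only ever meets the final model.

The classifier is a support vector machine with an RBF kernel and C = 1;
the kernel width gamma defaults to the reciprocal of the number of active
(unique) features so that runs are deterministic given a seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import sklearn
from sklearn.svm import SVC

from .datasets import Dataset, apply_min_max, fit_min_max
from .engine import FeatureSubset, RunConfig, RunResult, run_mlfssm

logger = logging.getLogger(__name__)


@dataclass
class ClassifierSpec:
    """SVM settings used for every subset evaluation and final model."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | None = None  # None -> 1 / (number of active features)

    def make(self, n_active_features: int) -> SVC:
        gamma = self.gamma if self.gamma is not None else 1.0 / n_active_features
        return SVC(kernel=self.kernel, C=self.C, gamma=gamma)


def stratified_fold_indices(
    labels: np.ndarray, folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Random stratified partition of sample indices into ``folds`` folds.

    Within each class the samples are shuffled and dealt round into folds,
    so every fold holds both classes whenever ``folds`` <= the smaller
    class count.
    """
    out: list[list[int]] = [[] for _ in range(folds)]
    idx = np.arange(len(labels))
    for cls in np.unique(labels):
        cls_idx = idx[labels == cls]
        cls_idx = rng.permutation(cls_idx)
        for j, chunk in enumerate(np.array_split(cls_idx, folds)):
            out[j].extend(chunk.tolist())
    return [np.asarray(sorted(f), dtype=np.int64) for f in out]


def _feasible_folds(labels: np.ndarray, requested: int) -> int:
    counts = np.bincount((labels == 1).astype(int), minlength=2)
    smallest = int(counts.min())
    if smallest < 2:
        raise ValueError("need at least 2 samples per class for stratified CV")
    feasible = min(requested, smallest)
    if feasible < requested:
        logger.warning(
            "reducing CV folds from %d to %d (smallest class has %d samples)",
            requested, feasible, smallest,
        )
    return feasible


def evaluate_subset(
    train: Dataset,
    subset: FeatureSubset | Sequence[int] | np.ndarray,
    spec: ClassifierSpec,
    folds: int,
    rng: np.random.Generator,
) -> float:
    """Inner-CV pooled accuracy of an SVM restricted to the subset's features.

    Duplicate members are collapsed before the classifier sees the columns,
    so the estimate is invariant to repeated indices.  Fold assignment is
    drawn fresh from ``rng`` on every call, preventing one lucky partition
    from biasing a whole layer of subsets identically.
    """
    members = getattr(subset, "members", subset)
    cols = np.unique(np.asarray(members, dtype=np.int64))
    if cols.size == 0:
        raise ValueError("subset has no members")
    if cols.min() < 0 or cols.max() >= train.n_features:
        raise ValueError("subset members out of range")
    x = train.values[:, cols]
    y = train.labels
    k = _feasible_folds(y, folds)
    fold_idx = stratified_fold_indices(y, k, rng)
    n = len(y)
    correct = 0
    mask = np.empty(n, dtype=bool)
    # inputs were validated once at Dataset construction; skipping sklearn's
    # per-call revalidation roughly halves the cost of the ~10^4 evaluations
    # a search performs
    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        for test_idx in fold_idx:
            mask[:] = True
            mask[test_idx] = False
            clf = spec.make(cols.size)
            clf.fit(x[mask], y[mask])
            correct += int((clf.predict(x[test_idx]) == y[test_idx]).sum())
    return correct / n


def make_subset_evaluator(
    spec: ClassifierSpec | None = None, folds: int = 5
) -> Callable[[Dataset, np.ndarray, np.random.Generator], float]:
    """Bind classifier settings and fold count into an ``accu`` oracle with
    the (dataset, members, rng) signature the search engine expects."""
    spec = spec or ClassifierSpec()

    def _evaluate(train: Dataset, members: np.ndarray, rng: np.random.Generator) -> float:
        return evaluate_subset(train, members, spec, folds, rng)

    return _evaluate


def evaluator_from_config(config: RunConfig) -> Callable:
    return make_subset_evaluator(
        ClassifierSpec(kernel=config.kernel, C=config.svm_c), config.inner_cv_folds
    )


# ---------------------------------------------------------------------------
# outer protocol
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    """Aggregate of the outer repeated stratified k-fold protocol."""

    repeats: int
    folds: int
    fold_accuracies: list[float] = field(default_factory=list)
    fold_correct: list[int] = field(default_factory=list)
    fold_sizes: list[int] = field(default_factory=list)
    selected_subsets: list[list[int]] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        """Arithmetic mean of the per-fold accuracies."""
        return float(np.mean(self.fold_accuracies))

    @property
    def pooled_accuracy(self) -> float:
        """Total correct predictions over total held-out samples."""
        return sum(self.fold_correct) / sum(self.fold_sizes)

    def to_dict(self) -> dict:
        return {
            "repeats": self.repeats,
            "folds": self.folds,
            "mean_accuracy": self.mean_accuracy,
            "pooled_accuracy": self.pooled_accuracy,
            "fold_accuracies": self.fold_accuracies,
            "selected_subsets": self.selected_subsets,
        }


def outer_cv(
    data: Dataset,
    selector: Callable[[Dataset, np.random.Generator], RunResult | Sequence[int]],
    *,
    repeats: int = 20,
    folds: int = 5,
    spec: ClassifierSpec | None = None,
    rescale: bool = False,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    train_audit: Callable[[Dataset], None] | None = None,
) -> CVReport:
    """Repeated stratified k-fold estimate of a select-then-classify pipeline.

    For every outer fold the ``selector`` sees only the training partition
    (as a :class:`Dataset`) plus a fold-local rng; its selected subset is
    refit on the full training partition and scored once on the held-out
    fold.  With ``rescale=True`` a min-max transform is learned on the
    training partition and applied to both sides.

    ``train_audit``, when given, is called with every training partition the
    selector receives — used by leakage audits to checksum the rows.
    """
    spec = spec or ClassifierSpec()
    if rng is None:
        from ._rng import substream

        rng = substream(seed, "outer_cv")
    k = _feasible_folds(data.labels, folds)
    report = CVReport(repeats=repeats, folds=k)

    for _rep in range(repeats):
        fold_idx = stratified_fold_indices(data.labels, k, rng)
        for test_idx in fold_idx:
            train_mask = np.ones(data.n_samples, dtype=bool)
            train_mask[test_idx] = False
            train_ds = data.take_samples(np.flatnonzero(train_mask))
            x_test, y_test = data.values[test_idx], data.labels[test_idx]
            if rescale:
                mins, ranges = fit_min_max(train_ds.values)
                train_ds = Dataset(
                    values=apply_min_max(train_ds.values, mins, ranges),
                    labels=train_ds.labels,
                    feature_names=list(train_ds.feature_names),
                    sample_ids=list(train_ds.sample_ids),
                )
                x_test = apply_min_max(x_test, mins, ranges)
            if train_audit is not None:
                train_audit(train_ds)

            fold_rng = np.random.default_rng(rng.integers(2**31))
            picked = selector(train_ds, fold_rng)
            members = picked.final_subset.members if isinstance(picked, RunResult) else picked
            cols = np.unique(np.asarray(members, dtype=np.int64))

            clf = spec.make(cols.size)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(train_ds.values[:, cols], train_ds.labels)
            correct = int((clf.predict(x_test[:, cols]) == y_test).sum())
            report.fold_correct.append(correct)
            report.fold_sizes.append(len(test_idx))
            report.fold_accuracies.append(correct / len(test_idx))
            report.selected_subsets.append([int(c) for c in cols])
    return report


def mlfssm_selector(config: RunConfig) -> Callable[[Dataset, np.random.Generator], RunResult]:
    """Wrap :func:`run_mlfssm` into the selector signature ``outer_cv`` uses,
    deriving per-fold sampling/evaluation streams from the fold rng."""
    evaluator = evaluator_from_config(config)

    def _select(train: Dataset, rng: np.random.Generator) -> RunResult:
        rng_s = np.random.default_rng(rng.integers(2**31))
        rng_e = np.random.default_rng(rng.integers(2**31))
        return run_mlfssm(train, config, evaluator, rng_sampling=rng_s, rng_evaluation=rng_e)

    return _select
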