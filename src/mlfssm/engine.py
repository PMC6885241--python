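"""Multilayer randomized-search wrapper feature subset selection (MLFSSM).

The selector works in *layers*.  On every layer it generates ``M`` candidate
feature subsets of fixed length ``ls`` (``M`` = number of features), scores
each with a classifier accuracy oracle, and revises a per-feature weight
vector: the weight of feature ``f`` becomes a decayed carry-over of its
previous weight plus the sum of the ``p``-th powers of the accuracies of the
layer's subsets that contain ``f``,

    w[1, f] = 1 / M
    w[l, f] = alpha * w[l-1, f] + sum_m accu(ft[l, m])**p * flag[m, f],  l >= 2

where ``flag[m, f]`` is 1 iff ``f`` is a member of subset ``m`` (membership,
not occurrence count).  Normalized weights give per-slot selection
probabilities for the next layer,

    pos[l, f] = w[l, f] / sum_j w[l, j].

Layer 1 is a balanced design: every subset holds ``ls`` distinct features and
every feature occurs exactly ``ls`` times across the pool.  Layers >= 2 draw
each of the ``ls`` slots independently from ``pos`` (duplicates allowed).
The run stops when the ``T`` best subsets of the current layer all reach
accuracy 1.0, or after ``L`` layers; the top subset of the last layer is
returned.

Raising accuracies to a large power ``p`` (default 32) makes the weight
increments extremely top-heavy: a subset at accuracy 0.95 contributes about
190 times the increment of one at 0.80, so weight mass flows to the members
of the few best subsets while the decay ``alpha`` (default 0.2) slowly
forgets old evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .datasets import Dataset

TerminationCause = Literal["perfect_top_T", "max_layers", "budget_exhausted"]

#: Accuracy oracle signature: (training data, member indices, rng) -> [0, 1].
SubsetEvaluator = Callable[[Dataset, np.ndarray, np.random.Generator], float]


@dataclass
class RunConfig:
    """Parameters of an MLFSSM run.

    alpha:
        Weight ratio in (0, 1): fraction of the previous layer's weight
        carried over.  Default 0.2.
    p:
        Power applied to subset accuracies before accumulation; larger
        values concentrate weight on the best subsets.  Default 32.
    ls:
        Subset length (slots per subset).  Default 21.
    top_t:
        The run stops early when the ``top_t`` best subsets of a layer all
        reach accuracy 1.0.  Default 20.
    max_layers:
        Hard layer cap ``L``.  Default 20.
    seed:
        Master seed; expanded into named substreams.
    inner_cv_folds:
        Folds of the stratified inner CV scoring each subset.  Default 5.
    svm_c, kernel:
        Classifier settings forwarded to the evaluation oracle.
    """

    alpha: float = 0.2
    p: int = 32
    ls: int = 21
    top_t: int = 20
    max_layers: int = 20
    seed: int = 0
    inner_cv_folds: int = 5
    svm_c: float = 1.0
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.p < 1 or int(self.p) != self.p:
            raise ValueError("p must be a positive integer")
        for name in ("ls", "top_t", "max_layers", "inner_cv_folds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    def validate_for(self, n_features: int) -> None:
        if self.ls > n_features:
            raise ValueError(f"ls={self.ls} exceeds feature count M={n_features}")
        if self.top_t > n_features:
            raise ValueError(f"top_t={self.top_t} exceeds subset count M={n_features}")


@dataclass
class FeatureSubset:
    """An ordered list of ``ls`` feature indices plus its estimated accuracy.

    Duplicate members may appear in subsets sampled on layers >= 2; the
    classifier sees each feature once, but the stored list keeps duplicates.
    ``accuracy`` is None before evaluation.
    """

    members: np.ndarray
    accuracy: float | None = None

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=np.int64)

    @property
    def unique_members(self) -> np.ndarray:
        return np.unique(self.members)


@dataclass
class LayerState:
    """One layer: its index, generating weights, and the M evaluated subsets."""

    layer_index: int
    weights: np.ndarray
    subsets: list[FeatureSubset]


@dataclass
class RunResult:
    final_subset: FeatureSubset
    termination: TerminationCause
    layers_run: int
    weight_history: list[np.ndarray] = field(default_factory=list)
    best_accuracy_history: list[float] = field(default_factory=list)
    final_weights: np.ndarray | None = None
    evaluations: int = 0


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def init_weights(n_features: int) -> np.ndarray:
    """Uniform layer-1 weights, every entry ``1 / M``."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return np.full(n_features, 1.0 / n_features)


def build_layer_one_subsets(
    n_features: int, ls: int, rng: np.random.Generator
) -> list[FeatureSubset]:
    """Balanced layer-1 pool: M subsets of ls distinct features each, with
    every feature occurring exactly ls times across the pool.

    Construction is a randomized cyclic design.  Draw ``ls`` distinct
    offsets ``o_1 < ... < o_ls`` from ``{0, ..., M-1}`` and a random
    relabelling permutation ``pi``; subset ``i`` is
    ``{ pi[(i + o_j) mod M] : j = 1..ls }``.  Offsets are distinct, so
    members within a subset are distinct; feature ``pi[v]`` occurs in
    exactly the ``ls`` subsets ``i = v - o_j mod M``, so every occurrence
    count is exactly ``ls``.  Cost O(M * ls) worst case (repair-based
    schemes stall when ``ls`` approaches ``M``).  Slot order within each
    subset is shuffled; order never affects evaluation.
    """
    if ls > n_features:
        raise ValueError(f"ls={ls} exceeds n_features={n_features}")
    m = n_features
    offsets = rng.choice(m, size=ls, replace=False)
    relabel = rng.permutation(m)
    base = (np.arange(m)[:, None] + offsets[None, :]) % m
    blocks = relabel[base]
    for i in range(m):
        rng.shuffle(blocks[i])
    return [FeatureSubset(members=blocks[i].copy()) for i in range(m)]


def selection_probabilities(weights: np.ndarray) -> np.ndarray:
    """Normalize nonnegative weights into per-slot selection probabilities."""
    weights = np.asarray(weights, dtype=np.float64)
    if (weights < 0).any():
        raise ValueError("weights must be nonnegative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("at least one weight must be positive")
    return weights / total


def sample_subsets(
    probs: np.ndarray, n_subsets: int, ls: int, rng: np.random.Generator
) -> list[FeatureSubset]:
    """Draw ``n_subsets`` subsets of ``ls`` independent slots each from
    ``probs`` (with replacement; duplicate members are kept)."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim != 1 or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("probs must be a valid probability vector")
    draws = rng.choice(len(probs), size=(n_subsets, ls), replace=True, p=probs)
    return [FeatureSubset(members=draws[i]) for i in range(n_subsets)]


def update_weights(
    prev_weights: np.ndarray,
    subsets: Sequence[FeatureSubset],
    alpha: float,
    p: int,
) -> np.ndarray:
    """One weight revision: decayed carry-over plus accuracy-power increments.

    ``w_new[f] = alpha * prev[f] + sum over subsets containing f of accu**p``;
    membership counts once even when a subset holds duplicate copies of ``f``.
    """
    prev_weights = np.asarray(prev_weights, dtype=np.float64)
    new = alpha * prev_weights
    for sub in subsets:
        if sub.accuracy is None:
            raise ValueError("all subsets must be evaluated before a weight update")
        if not 0.0 <= sub.accuracy <= 1.0:
            raise ValueError(f"accuracy {sub.accuracy} outside [0, 1]")
        new[sub.unique_members] += sub.accuracy ** p
    return new


def should_terminate(layer: LayerState, config: RunConfig) -> str:
    """Decide ``continue`` / ``perfect_top_T`` / ``max_layers`` for a layer.

    ``perfect_top_T`` fires when the T highest-accuracy subsets of the layer
    all sit at accuracy exactly 1.0 (inner-CV accuracy is a ratio of integer
    counts, so exact comparison is well defined).
    """
    accs = [s.accuracy for s in layer.subsets]
    if any(a is None for a in accs):
        raise ValueError("cannot decide termination with unevaluated subsets")
    if layer.layer_index >= config.max_layers:
        return "max_layers"
    top = sorted(accs, reverse=True)[: config.top_t]
    if len(top) >= config.top_t and top[-1] == 1.0:
        return "perfect_top_T"
    return "continue"


def best_subset(subsets: Sequence[FeatureSubset]) -> FeatureSubset:
    """Highest-accuracy subset; ties broken by lowest subset index."""
    best = subsets[0]
    for sub in subsets[1:]:
        if sub.accuracy > best.accuracy:
            best = sub
    return best


# ---------------------------------------------------------------------------
# the full loop
# ---------------------------------------------------------------------------

def run_mlfssm(
    train: Dataset,
    config: RunConfig,
    evaluator: SubsetEvaluator,
    *,
    rng_sampling: np.random.Generator | None = None,
    rng_evaluation: np.random.Generator | None = None,
    layer_callback: Callable[[LayerState], None] | None = None,
) -> RunResult:
    """Run the multilayer selector on a training dataset.

    ``evaluator`` maps (dataset, member indices, rng) to an accuracy in
    [0, 1]; the default oracle lives in :mod:`mlfssm.evaluation`.  All
    randomness flows from ``config.seed`` via named substreams unless
    explicit generators are passed (the outer-CV driver passes per-fold
    streams so folds stay independent).
    """
    from ._rng import substream  # local import avoids cycles at module load

    m = train.n_features
    config.validate_for(m)
    if rng_sampling is None:
        rng_sampling = substream(config.seed, "layer_sampling")
    if rng_evaluation is None:
        rng_evaluation = substream(config.seed, "subset_evaluation")

    weights = init_weights(m)
    weight_history: list[np.ndarray] = []
    best_history: list[float] = []
    evaluations = 0

    layer_index = 0
    subsets: list[FeatureSubset] = []
    while True:
        layer_index += 1
        if layer_index == 1:
            subsets = build_layer_one_subsets(m, config.ls, rng_sampling)
        else:
            probs = selection_probabilities(weights)
            subsets = sample_subsets(probs, m, config.ls, rng_sampling)

        for sub in subsets:
            sub.accuracy = evaluator(train, sub.members, rng_evaluation)
            evaluations += 1

        layer = LayerState(layer_index=layer_index, weights=weights.copy(), subsets=subsets)
        weight_history.append(weights.copy())
        best_history.append(max(s.accuracy for s in subsets))
        if layer_callback is not None:
            layer_callback(layer)

        decision = should_terminate(layer, config)
        weights = update_weights(weights, subsets, config.alpha, config.p)
        if decision != "continue":
            return RunResult(
                final_subset=best_subset(subsets),
                termination=decision,  # type: ignore[arg-type]
                layers_run=layer_index,
                weight_history=weight_history,
                best_accuracy_history=best_history,
                final_weights=weights,
                evaluations=evaluations,
            )
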