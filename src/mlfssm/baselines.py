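"""Las Vegas wrapper (LVW) and its weight-revising variant (imp-LVW).

LVW is the classical randomized wrapper: draw a subset uniformly at random
(size uniform on [1, ls_max], members without replacement), score it, and
keep the incumbent best — preferring higher accuracy and, at equal
accuracy, fewer features.  The stop rule is a fixed evaluation budget,
``max_evaluations`` (default M * 21, matching MLFSSM's default budget of
L=20 layers x M subsets to within one layer's worth of evaluations).

imp-LVW biases the sampling: per-feature weights start uniform at 1/M and
each sampled subset is drawn with probability proportional to the weights;
whenever a subset performs better than the previous subsets — strictly
above the running mean accuracy of everything evaluated so far — the
weight of each of its members is incremented by that accuracy, so the
weights are revised continuously throughout the run.  Unlike the
multilayer selector it reacts only to the single current subset, so it can
chase a local optimum, but the bias toward features seen in above-average
subsets still helps against unweighted LVW.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .datasets import Dataset
from .engine import FeatureSubset, RunResult, SubsetEvaluator


@dataclass
class LVWConfig:
    """Budget and sampling settings shared by LVW and imp-LVW.

    max_evaluations:
        Subset evaluations before stopping; None means M * 21 for the
        dataset at hand.
    ls_max:
        Largest subset size sampled (sizes are uniform on [1, ls_max]).
    """

    max_evaluations: int | None = None
    ls_max: int = 21
    seed: int = 0

    def budget_for(self, n_features: int) -> int:
        return self.max_evaluations if self.max_evaluations is not None else n_features * 21


def _better(acc: float, size: int, best_acc: float, best_size: int) -> bool:
    # higher accuracy wins; at equal accuracy fewer features win
    return acc > best_acc or (acc == best_acc and size < best_size)


def run_lvw(
    train: Dataset,
    config: LVWConfig,
    evaluator: SubsetEvaluator,
    *,
    rng: np.random.Generator | None = None,
    rng_evaluation: np.random.Generator | None = None,
) -> RunResult:
    """Uniform random subset search keeping the incumbent best."""
    if rng is None:
        rng = substream(config.seed, "baseline_draws")
    if rng_evaluation is None:
        rng_evaluation = substream(config.seed, "subset_evaluation")
    m = train.n_features
    ls_max = min(config.ls_max, m)
    budget = config.budget_for(m)

    best: FeatureSubset | None = None
    incumbent_history: list[float] = []
    for _ in range(budget):
        size = int(rng.integers(1, ls_max + 1))
        members = rng.choice(m, size=size, replace=False)
        acc = evaluator(train, members, rng_evaluation)
        if best is None or _better(acc, size, best.accuracy, len(best.members)):
            best = FeatureSubset(members=members, accuracy=acc)
        incumbent_history.append(best.accuracy)
    return RunResult(
        final_subset=best,
        termination="budget_exhausted",
        layers_run=budget,
        best_accuracy_history=incumbent_history,
        evaluations=budget,
    )


def run_imp_lvw(
    train: Dataset,
    config: LVWConfig,
    evaluator: SubsetEvaluator,
    *,
    rng: np.random.Generator | None = None,
    rng_evaluation: np.random.Generator | None = None,
) -> RunResult:
    """Weight-biased random subset search.

    Weights start at 1/M; members of any subset whose accuracy strictly
    exceeds the running mean accuracy of all previously evaluated subsets
    each gain that accuracy as a weight increment (the first subset, having
    no predecessors, always counts as improving), steering later draws
    toward features seen in above-average subsets.
    """
    if rng is None:
        rng = substream(config.seed, "baseline_draws")
    if rng_evaluation is None:
        rng_evaluation = substream(config.seed, "subset_evaluation")
    m = train.n_features
    ls_max = min(config.ls_max, m)
    budget = config.budget_for(m)

    weights = np.full(m, 1.0 / m)
    best: FeatureSubset | None = None
    incumbent_history: list[float] = []
    acc_sum = 0.0
    for n_seen in range(budget):
        size = int(rng.integers(1, ls_max + 1))
        probs = weights / weights.sum()
        members = rng.choice(m, size=size, replace=False, p=probs)
        acc = evaluator(train, members, rng_evaluation)
        if n_seen == 0 or acc > acc_sum / n_seen:
            weights[members] += acc
        acc_sum += acc
        if best is None or _better(acc, size, best.accuracy, len(best.members)):
            best = FeatureSubset(members=members, accuracy=acc)
        incumbent_history.append(best.accuracy)
    return RunResult(
        final_subset=best,
        termination="budget_exhausted",
        layers_run=budget,
        best_accuracy_history=incumbent_history,
        final_weights=weights,
        evaluations=budget,
    )
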