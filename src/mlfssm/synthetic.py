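"""Synthetic two-class expression benchmarks with planted signal.

Real microarray benchmarks in this problem regime are tiny-n, huge-M
(e.g. 60 samples x 2000-7129 genes) with a handful of informative genes.
The generator emulates that regime with three kinds of planted structure on
a Gaussian noise background:

* **linear-informative** features — a class-mean shift of ``effect_size``
  noise-SDs, detectable by any univariate filter;
* **XOR pairs** — two features whose individual class-conditional means are
  identical (marginally null) but whose *sign product* carries the label:
  interaction-only signal that no univariate filter can see and that
  motivates subset-level (wrapper) selection;
* **redundant** features — noisy copies of informative features,
  emulating co-regulated genes.

Everything else is label-independent Gaussian noise.  The ground-truth
index sets are returned alongside the matrix so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .datasets import Dataset


@dataclass
class GroundTruth:
    """Index bookkeeping for a planted dataset."""

    linear: list[int] = field(default_factory=list)
    xor_pairs: list[tuple[int, int]] = field(default_factory=list)
    redundant: list[int] = field(default_factory=list)
    noise: list[int] = field(default_factory=list)

    @property
    def informative(self) -> list[int]:
        """All directly signal-carrying features (linear + XOR members)."""
        return self.linear + [i for pair in self.xor_pairs for i in pair]


@dataclass
class PlantedSpec:
    """Recipe for one planted dataset.

    effect_size is the class-mean separation of a linear-informative
    feature in units of ``noise_sd``; XOR pair components sit at
    ``+-effect_size * noise_sd`` so that the sign-product rule stays
    readable through the noise (error rate ~ Phi(-effect_size) per
    component).  Defaults give the small benchmark: 100 samples x 200
    features, 5 linear-informative, one XOR pair, two redundant copies.
    """

    n_samples: int = 100
    n_features: int = 200
    n_linear_informative: int = 5
    n_xor_pairs: int = 1
    n_redundant: int = 2
    effect_size: float = 2.0
    noise_sd: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.n_linear_informative + 2 * self.n_xor_pairs + self.n_redundant
        if planted > self.n_features:
            raise ValueError(
                f"planted features ({planted}) exceed n_features ({self.n_features})"
            )
        if self.n_redundant > 0 and self.n_linear_informative + self.n_xor_pairs == 0:
            raise ValueError("redundant copies need at least one informative source")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        n_minor = min(
            round(self.n_samples * self.class_balance),
            self.n_samples - round(self.n_samples * self.class_balance),
        )
        if n_minor < 2:
            raise ValueError("each class needs at least 2 samples")


def make_planted_dataset(spec: PlantedSpec) -> tuple[Dataset, GroundTruth]:
    """Generate one dataset and its ground truth.

    Feature layout: linear-informative first, then XOR pairs, then
    redundant copies, then pure noise.  Labels are exactly balanced to
    ``class_balance`` and shuffled.
    """
    rng = substream(spec.seed, "synthesis")
    n, m = spec.n_samples, spec.n_features
    sd = spec.noise_sd

    n_pos = round(n * spec.class_balance)
    y = np.concatenate([np.ones(n_pos, dtype=np.int64), -np.ones(n - n_pos, dtype=np.int64)])
    rng.shuffle(y)

    x = np.empty((n, m))
    truth = GroundTruth()
    col = 0

    half_shift = 0.5 * spec.effect_size * sd
    for _ in range(spec.n_linear_informative):
        x[:, col] = y * half_shift + rng.normal(0.0, sd, size=n)
        truth.linear.append(col)
        col += 1

    xor_amp = spec.effect_size * sd
    for _ in range(spec.n_xor_pairs):
        s = rng.choice([-1, 1], size=n)  # latent sign, independent of the label
        x[:, col] = s * xor_amp + rng.normal(0.0, sd, size=n)
        x[:, col + 1] = s * y * xor_amp + rng.normal(0.0, sd, size=n)
        truth.xor_pairs.append((col, col + 1))
        col += 2

    sources = truth.informative
    for j in range(spec.n_redundant):
        src = sources[j % len(sources)]
        x[:, col] = x[:, src] + rng.normal(0.0, sd / 2.0, size=n)
        truth.redundant.append(col)
        col += 1

    n_noise = m - col
    x[:, col:] = rng.normal(0.0, sd, size=(n, n_noise))
    truth.noise = list(range(col, m))

    names = (
        [f"lin_{i:04d}" for i in range(spec.n_linear_informative)]
        + [f"xor{i:02d}_{ab}" for i in range(spec.n_xor_pairs) for ab in ("a", "b")]
        + [f"red_{i:04d}" for i in range(spec.n_redundant)]
        + [f"noise_{i:05d}" for i in range(n_noise)]
    )
    dataset = Dataset(
        values=x,
        labels=y,
        feature_names=names,
        sample_ids=[f"s{i:04d}" for i in range(n)],
    )
    return dataset, truth


#: Named presets used by the command line and the test harness.
PRESETS: dict[str, PlantedSpec] = {
    # small: the default recovery benchmark
    "small": PlantedSpec(),
    # xor-linear: mixed marginal + interaction-only signal in the N << M
    # regime, sized so wrapper searches at budget M*21 stay desk-scale
    "xor-linear": PlantedSpec(
        n_samples=60, n_features=100, n_linear_informative=3,
        n_xor_pairs=1, n_redundant=2,
    ),
    # cns-like: the scale of a 60-sample, 7129-gene expression benchmark
    "cns-like": PlantedSpec(
        n_samples=60, n_features=7129, n_linear_informative=10,
        n_xor_pairs=2, n_redundant=6,
    ),
}


def make_preset(name: str, seed: int = 0) -> tuple[Dataset, GroundTruth]:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}")
    base = PRESETS[name]
    spec = PlantedSpec(**{**base.__dict__, "seed": seed})
    return make_planted_dataset(spec)
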