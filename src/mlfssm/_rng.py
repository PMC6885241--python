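"""Named, reproducible random substreams.

Every stochastic component of a run (layer sampling, subset evaluation,
baseline draws, outer CV splits, data synthesis) pulls from its own
`numpy.random.Generator`, all derived from one master seed.  Streams are
assigned by *name* so that toggling one component on or off never shifts
the randomness seen by another.
"""

from __future__ import annotations

import numpy as np

# Fixed registry: the spawn index of a name never changes between releases,
# otherwise old seeds stop reproducing old runs.
_STREAM_NAMES = (
    "layer_sampling",
    "subset_evaluation",
    "outer_cv",
    "baseline_draws",
    "synthesis",
)


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of ``seed``.

    Parameters
    ----------
    seed:
        Master seed of the run (any non-negative integer).
    name:
        One of ``layer_sampling``, ``subset_evaluation``, ``outer_cv``,
        ``baseline_draws``, ``synthesis``.
    """
    try:
        idx = _STREAM_NAMES.index(name)
    except ValueError:
        raise KeyError(f"unknown RNG stream {name!r}; known: {_STREAM_NAMES}") from None
    children = np.random.SeedSequence(seed).spawn(len(_STREAM_NAMES))
    return np.random.default_rng(children[idx])


def substreams(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Spawn several named substreams of ``seed`` at once."""
    return {name: substream(seed, name) for name in names}
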