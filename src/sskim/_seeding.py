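"""Derivation of independent child random streams from a global seed.

Every stochastic operation keys its stream by the global integer seed plus
small integer tags identifying the operation and, where relevant, the
object drawn (e.g. neuron indices).  This makes draws reproducible and
mutually independent, and lets nested subsets (smaller populations under
the same seed) reuse exactly the same trajectories.
"""

from __future__ import annotations

import numpy as np


def _flatten(parts):
    for p in parts:
        if isinstance(p, (tuple, list)):
            yield from _flatten(p)
        else:
            yield int(p)


def child_seed(seed, *tags: int) -> np.random.SeedSequence:
    """SeedSequence keyed by ``seed`` (int or nested tuple of ints) + ``tags``."""
    entropy = tuple(_flatten((seed, *tags)))
    if any(e < 0 for e in entropy):
        raise ValueError("seed components must be non-negative integers")
    return np.random.SeedSequence(entropy)


def child_rng(seed, *tags: int) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *tags))
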