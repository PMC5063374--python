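"""Counter-based random substreams.

All randomness in the package flows from a single integer seed.  Each
operation (and, where relevant, each subject or replicate) draws from its
own substream identified by a small integer key, so that adding a stage to
a pipeline never perturbs the random numbers seen by another stage.
"""

from __future__ import annotations

import numpy as np

# substream keys, one per stochastic operation
OP_GROUND_TRUTH = 0
OP_SUBJECT = 1
OP_DEGRADE = 2
OP_PLANTED = 3
OP_DYNAMICS = 4
OP_BOOTSTRAP = 5
OP_PERMUTE = 6
OP_ATLAS = 7


def substream(seed: int, *key: int) -> np.random.Generator:
    """Return a Generator for the substream ``key`` of the root ``seed``."""
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


def kernel_seed(seed: int, *key: int) -> int:
    """A 31-bit integer seed for compiled kernels, derived from a substream."""
    return int(substream(seed, *key).integers(0, 2**31 - 1))
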