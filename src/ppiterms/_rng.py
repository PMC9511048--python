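"""Named, reproducible random streams.

Every stochastic sub-step of the pipeline draws from its own stream, derived
from the master seed and a string name. Adding a new step therefore never
perturbs the draws of existing steps, and per-dataset work is reproducible
regardless of execution order.
"""

from __future__ import annotations

import hashlib

import numpy as np


def stream_seed(master_seed: int, *names: object) -> int:
    """Derive a sub-seed (< 2**31) from a master seed and a path of names."""
    key = ":".join([str(int(master_seed))] + [str(n) for n in names])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stream(master_seed: int, *names: object) -> np.random.Generator:
    """A numpy Generator seeded for the named sub-step."""
    return np.random.default_rng(stream_seed(master_seed, *names))
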