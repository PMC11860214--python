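"""Named, seeded random streams.

Every stochastic component draws from its own stream derived from a master
seed plus a stable name, so adding a consumer never perturbs another
component's draws.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["spawn_rng", "as_rng"]


def _name_entropy(name: object) -> int:
    digest = hashlib.blake2s(str(name).encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "big")


def spawn_rng(master_seed: int, *names: object) -> np.random.Generator:
    """Return a Generator keyed by ``master_seed`` and a path of names."""
    entropy = [int(master_seed)] + [_name_entropy(n) for n in names]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def as_rng(seed_or_rng) -> np.random.Generator:
    """Accept either an integer seed or an existing Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
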