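"""Deterministic RNG substreams keyed by stable string hashes.

Every stochastic stage derives its generator from a single user seed plus a
stable key, so adding tables or stages never perturbs existing draws.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "as_rng"]


def substream(seed: int, *key: object) -> np.random.Generator:
    """Return a Generator derived from ``seed`` and a stable string key.

    The key parts are joined, hashed with SHA-256 and folded into the
    SeedSequence entropy, so the mapping is stable across platforms and
    Python hash randomization.
    """
    digest = hashlib.sha256("|".join(str(k) for k in key).encode()).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32)
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *(int(w) for w in words)])
    return np.random.default_rng(ss)


def as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    """Coerce an int seed or None into a Generator (None -> fresh entropy)."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
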