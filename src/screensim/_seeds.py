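"""Deterministic seed derivation.

All randomness in the package flows from a single integer master seed.
Sub-streams (per collection, condition, replication, algorithm) are derived by
hashing the master seed together with a tuple of string/number parts, so the
same logical run always receives the same seed regardless of execution order
or parallel schedule.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MOD = 2**31 - 1


def derive_seed(master_seed: int, *parts: object) -> int:
    """Map (master_seed, parts...) to a stable integer in [0, 2**31 - 1)."""
    key = ":".join([str(int(master_seed))] + [repr(p) for p in parts])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % _MOD


def rng_for(master_seed: int, *parts: object) -> np.random.Generator:
    """A numpy Generator seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master_seed, *parts))
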