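"""Deterministic seed fan-out.

One master seed drives every stochastic stage. Per-subject, per-stage seeds are
derived by hashing (master, subject_id, stage) so results do not depend on the
order in which subjects are processed.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def derive_seed(master: int, *keys: object) -> int:
    """Derive a child seed (< 2**31) from a master seed and string-able keys."""
    h = hashlib.blake2b(digest_size=8)
    h.update(str(int(master)).encode())
    for k in keys:
        h.update(b"\x1f")
        h.update(str(k).encode())
    return int.from_bytes(h.digest(), "little") % (2**31)


def derive_rng(master: int, *keys: object) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *keys))
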