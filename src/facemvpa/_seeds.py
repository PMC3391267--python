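"""Deterministic child-seed derivation.

One master seed governs a whole simulated cohort; every stochastic step draws
from its own child seed derived by stable hashing of (master, *tags), so that
adding or reordering unrelated stages never perturbs an existing stream.
"""
from __future__ import annotations

import hashlib

__all__ = ["child_seed"]

_MOD = 2**31  # keep derived seeds small enough for any RNG API


def child_seed(master: int, *tags: object) -> int:
    """Derive a reproducible 31-bit seed from a master seed and a tag path.

    Tags are stringified, so ``child_seed(7, "subject", 3, "run", 1)`` is
    stable across sessions and platforms (SHA-256, first 4 bytes).
    """
    key = "|".join([str(int(master)), *[str(t) for t in tags]])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % _MOD
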