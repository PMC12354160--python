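"""Deterministic child-seed derivation.

One master seed drives a whole cohort simulation; every participant/stage
combination gets its own independent stream derived by stable hashing, so
adding a participant or reordering stages never perturbs the others.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, *tokens: object) -> int:
    """Derive a child seed (< 2**31) from a master seed and identifying tokens.

    Uses SHA-256 of the repr of (master, *tokens); stable across runs and
    Python processes (unlike built-in ``hash``).
    """
    payload = repr((int(master),) + tuple(str(t) for t in tokens)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
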