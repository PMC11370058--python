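"""Deterministic seed fan-out.

A single master seed is hashed together with stage labels to give every
stochastic stage its own independent, reproducible stream, so any stage can
be rerun in isolation from the manifest without replaying the whole run.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master: int, *parts) -> int:
    """Derive a child seed (< 2^31) from a master seed and stage labels.

    Stable across runs and platforms: SHA-256 over the decimal/string
    rendering of the inputs, truncated to 31 bits.
    """
    token = "|".join(str(p) for p in (master, *parts))
    digest = hashlib.sha256(token.encode("ascii")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
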