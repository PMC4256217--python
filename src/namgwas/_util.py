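"""Seed bookkeeping shared by every stochastic stage.

Each stage draws from its own stream derived from the master seed and a
purpose string, so rerunning one stage never perturbs another.
"""

from __future__ import annotations

import hashlib

import numpy as np

_SEED_CAP = 2**31 - 1


def derive_seed(master: int, *purpose: str) -> int:
    """Stable child seed from a master seed and a purpose label."""
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for p in purpose:
        h.update(b"/")
        h.update(str(p).encode())
    return int.from_bytes(h.digest()[:4], "big") % _SEED_CAP


def rng_for(master: int, *purpose: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *purpose))
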