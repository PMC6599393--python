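"""Deterministic seed derivation.

A single global seed drives every stochastic stage. Per-stage / per-group /
per-restart seeds are derived by hashing the master seed together with string
tokens, so adding a stage never perturbs the seeds of existing ones.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MOD = 2**32


def derive_seed(master: int, *tokens) -> int:
    """Derive a 32-bit child seed from ``master`` and a token path."""
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for tok in tokens:
        h.update(b"/")
        h.update(str(tok).encode())
    return int.from_bytes(h.digest()[:4], "big") % _MOD


def derive_rng(master: int, *tokens) -> np.random.Generator:
    """Generator seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master, *tokens))
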