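"""Deterministic seed fan-out.

Every stochastic operation in the package takes an explicit integer seed.
Sub-seeds are derived from a master seed plus a string label through SHA-256,
so adding a new consumer never perturbs the streams of existing ones
(counter-based scheme). Derived seeds stay below 2**31.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MOD = 2**31


def derive_seed(master: int, label: str, index: int = 0) -> int:
    """Derive a reproducible sub-seed from ``master`` for the given label."""
    h = hashlib.sha256(f"{int(master)}:{label}:{int(index)}".encode()).digest()
    return int.from_bytes(h[:4], "big") % _MOD


def generator(master: int, label: str, index: int = 0) -> np.random.Generator:
    """A :class:`numpy.random.Generator` seeded from the derived sub-seed."""
    return np.random.default_rng(derive_seed(master, label, index))
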