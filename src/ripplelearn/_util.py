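"""Seed-derivation helpers shared across pipeline stages.

Every stage that needs randomness derives an independent integer seed from
the master seed plus string/int labels, so streams never collide and every
run is reproducible from one number.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31


def derive_seed(*parts: int | str) -> int:
    """Deterministically fold a master seed and labels into one int < 2^31."""
    entropy = [
        zlib.crc32(p.encode()) if isinstance(p, str) else int(p) % _MOD
        for p in parts
    ]
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] % _MOD)


def derive_rng(*parts: int | str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(*parts))
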