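"""Deterministic seed derivation.

Every random draw in the package flows from a single master seed through
named substreams, so that results are reproducible and independent of
execution order (e.g. restarts run serially or in parallel).
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31 - 1


def derive_seed(master: int, *tokens) -> int:
    """Derive a child seed < 2**31 from a master seed and a token path.

    The derivation is a pure function of ``(master, tokens)``: the same
    path always yields the same child seed, and distinct paths yield
    statistically independent streams (via ``numpy.random.SeedSequence``).
    """
    digest = zlib.crc32("/".join(str(t) for t in tokens).encode())
    ss = np.random.SeedSequence([int(master) & 0x7FFFFFFF, digest])
    return int(ss.generate_state(1)[0]) % _MOD


def rng_from(master: int, *tokens) -> np.random.Generator:
    """A ``numpy`` Generator seeded from a named substream of ``master``."""
    return np.random.default_rng(derive_seed(master, *tokens))
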