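"""Named substreams derived from a single master seed.

A simulation run draws randomness for several independent purposes (spawn
placement, target assignment, speed sampling, tie-breaking, fixtures).  Each
purpose gets its own ``numpy`` Generator derived from the master seed and a
string label, so individual components can be tested in isolation while a
run as a whole stays reproducible from one integer.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def child_seed(seed: int, *names: str | int) -> int:
    """Deterministically derive an integer seed < 2**31 from a master seed and labels."""
    h = zlib.crc32(str(int(seed)).encode())
    for name in names:
        h = zlib.crc32(str(name).encode(), h)
    return h % (2**31 - 1)


def substream(seed: int, *names: str | int) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``."""
    return np.random.default_rng(child_seed(seed, *names))
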