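"""Seeded random-number substreams.

Every stochastic operation in the package draws from its own substream,
derived from (global seed, operation name).  Stages can therefore be
regenerated independently and in any order without perturbing each other.
"""

from __future__ import annotations

import zlib

import numpy as np

_MASK = 0x7FFFFFFF  # keep derived entries in int31 range


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed on ``(seed, name)``.

    The operation name is folded to a 32-bit CRC so the stream is stable
    across platforms and Python hash randomization.
    """
    key = zlib.crc32(name.encode("utf-8")) & _MASK
    return np.random.default_rng(np.random.SeedSequence([int(seed) & _MASK, key]))
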