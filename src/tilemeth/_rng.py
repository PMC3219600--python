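"""Named substreams from a single integer seed.

Every stochastic operation in the package draws from ``substream(seed, name)``
so that each pipeline stage is independently reproducible: re-running one stage
with the same master seed yields bit-identical output regardless of what other
stages consumed.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the (seed, name) pair.

    The stream key mixes the master seed with a CRC32 of the stage name, so
    streams are stable across sessions and platforms.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, key])
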