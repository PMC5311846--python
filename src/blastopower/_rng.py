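"""Deterministic named sub-streams from a single master seed.

Every stochastic component draws from a generator obtained through
:func:`substream`, so a run is fully reproducible from one integer seed
and independent batches/genes never share generator state.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError("integer stream keys must be non-negative")
        return int(key)
    return zlib.crc32(key.encode("utf-8"))


def substream(seed: int, *keys: int | str) -> np.random.Generator:
    """Return a generator for the named sub-stream of ``seed``.

    ``substream(seed, "set1", effect, batch)`` is independent of any other
    key tuple under the same seed, and identical across runs and platforms.
    String keys are mapped to integers with CRC-32.
    """
    entropy = [int(seed)] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
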