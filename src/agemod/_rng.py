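"""Named random substreams so every stage draws from an isolated, reproducible stream."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by (seed, name).

    Streams for different names are statistically independent, and each is a
    pure function of the master seed, so stages (cohort draw, missingness,
    fold plans, permutations, subsampling) can be re-run in isolation.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
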