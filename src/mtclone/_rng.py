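"""Deterministic random-stream derivation.

A single user-facing seed fans out into named, statistically independent
substreams so that each pipeline stage is individually reproducible: rerunning
one stage with the same global seed draws exactly the same numbers no matter
what the other stages consumed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(seed: int, name: str) -> int:
    """Derive a stable 31-bit integer seed for the named substream."""
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    ss = np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))])
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of a global seed."""
    return np.random.default_rng(substream_seed(seed, name))
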