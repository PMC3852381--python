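"""Deterministic random-stream management.

A single integer seed drives the whole pipeline.  Each stage draws from
its own substream, derived from the global seed plus a stable hash of a
stage label, so rerunning one stage in isolation reproduces exactly the
numbers it saw inside a full run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return the deterministic generator for one named stage.

    The label is hashed with CRC-32 so the mapping is stable across
    Python processes (unlike the builtin ``hash``).
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
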