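"""Seed plumbing: one independent RNG stream per named consumer.

Every stochastic stage derives its generator from a (master seed, stream
name) pair, so adding a new generator or changing the number of draws in
one stage never perturbs another stage's stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream_rng", "stream_seed"]


def stream_seed(seed: int, stream: str) -> int:
    """Stable 31-bit sub-seed for *stream* derived from the master seed."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stream.encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent Generator for *stream* keyed by the master seed."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stream.encode())])
    return np.random.default_rng(ss)
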