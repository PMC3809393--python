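"""Seed fan-out.

A single run seed is expanded into independent per-stage streams keyed by
stable string labels, so adding a stage never shifts the stream another
stage consumes.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng"]


def child_seed_sequence(seed: int, *labels: object) -> np.random.SeedSequence:
    """Derive a SeedSequence from ``seed`` and a stable label path."""
    if seed < 0:
        raise ValueError("seed must be non-negative")
    words = [int(seed)] + [zlib.crc32(str(lab).encode("utf-8")) for lab in labels]
    return np.random.SeedSequence(words)


def child_rng(seed: int, *labels: object) -> np.random.Generator:
    """A PCG64 generator on the stream identified by ``(seed, *labels)``."""
    return np.random.default_rng(child_seed_sequence(seed, *labels))
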