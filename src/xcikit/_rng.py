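"""Seed management: one global seed, independent streams per stage."""

from __future__ import annotations

import zlib

import numpy as np

_STAGES = ("interactome", "allelotype", "atac", "shape", "decay")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a generator whose stream depends on (seed, stage) only.

    Streams for distinct stage names are statistically independent, so any
    stage can be regenerated without replaying the others.
    """
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValueError(f"seed must be a non-negative integer, got {seed!r}")
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
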