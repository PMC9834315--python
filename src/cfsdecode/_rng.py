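"""Named random sub-streams derived from one master seed.

Every stochastic stage (synthesis, fold splitting, label shuffles,
permutations...) draws from its own generator, derived deterministically
from the master seed and a stage name, so stages can be re-run in
isolation and whole pipelines are bit-reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def subseed(master_seed: int, name: str) -> int:
    """A deterministic 31-bit seed for the named sub-stream."""
    mix = np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode("utf8"))])
    return int(mix.generate_state(1)[0] % (2**31 - 1))


def substream(master_seed: int, name: str) -> np.random.Generator:
    """A Generator seeded from ``master_seed`` and a stage ``name``."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode("utf8"))])
    )
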