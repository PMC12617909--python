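"""Named random substreams fanned out from one user-facing seed.

Each consumer (negative sampling, fold assignment, parameter init, dropout,
data generation) draws from its own named stream so that, e.g., changing
the fold seed never perturbs initialisation.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(seed: int, name: str) -> int:
    """Deterministic per-stream seed derived from (seed, name); < 2**31."""
    return (int(seed) ^ zlib.crc32(name.encode("utf-8"))) % (2**31)


def substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), child_seed(seed, name)])
    )
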