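"""Deterministic, purpose-keyed random streams.

Each (seed, purpose) pair gets its own independent generator so that,
e.g., toggling injected deviation effects does not perturb the noise
realization of the base measurements.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream"]


def stream(seed: int, purpose: str) -> np.random.Generator:
    """Return an independent Generator keyed on (seed, purpose).

    The purpose string is hashed with CRC32 (stable across processes and
    Python versions, unlike builtin hash) and folded into the seed
    sequence entropy.
    """
    if not (0 <= int(seed) < 2**63):
        raise ValueError(f"seed must be a non-negative integer, got {seed!r}")
    key = zlib.crc32(purpose.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
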