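"""Deterministic fan-out of one user seed into per-stage seeds.

Every randomized stage of the workflow receives a child seed derived from
the single configured seed and a stable stage name, so a whole pipeline
run is reproducible from one integer while stages stay statistically
independent.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(seed: int, *path: str | int) -> int:
    """Derive a deterministic 31-bit child seed from ``seed`` and a path.

    Path components may be stage names (hashed with CRC32, stable across
    platforms and Python processes) or integers (e.g. repeat indices).
    """
    entropy = [int(seed) & 0xFFFFFFFF]
    for part in path:
        if isinstance(part, str):
            entropy.append(zlib.crc32(part.encode("utf-8")))
        else:
            entropy.append(int(part) & 0xFFFFFFFF)
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] % (2**31))


def child_rng(seed: int, *path: str | int) -> np.random.Generator:
    """A numpy Generator seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(seed, *path))
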