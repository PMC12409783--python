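"""Small shared helpers: seed fan-out and validation."""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(seed: int, *stage: object) -> int:
    """Derive a per-stage child seed from a master seed.

    A fixed counter scheme: the stage labels are hashed (CRC32, stable
    across runs and platforms) into the spawn key of a SeedSequence, so
    each pipeline stage can be re-run independently yet reproducibly.
    Result is always < 2**31.
    """
    key = tuple(zlib.crc32(str(s).encode()) for s in stage)
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=key)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def check_finite(name: str, arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains NaN or Inf values")
    return arr
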