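"""Shared helpers: seed derivation and small validation utilities."""

from __future__ import annotations

import numpy as np

_SPLITMIX_GAMMA = 0x9E3779B97F4A7C15
_MASK64 = (1 << 64) - 1


def derive_seed(root_seed: int, stage: str) -> int:
    """Derive a per-stage seed from one root seed, splitmix64-style.

    The stage name is hashed into the stream position so every pipeline
    stage gets an independent, reproducible seed below 2**31.
    """
    z = (int(root_seed) & _MASK64)
    for ch in stage.encode("utf-8"):
        z = (z + _SPLITMIX_GAMMA + ch) & _MASK64
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
        z = z ^ (z >> 31)
    return int(z % (2 ** 31))


def rng_for(root_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(root_seed, stage))


def check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(np.asarray(arr)))
        raise ValueError(f"{name} contains non-finite entries, first at index {bad[0].tolist()}")
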