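"""Deterministic seed derivation.

A splitmix64-style finalizer maps an (outer seed, stream index) pair to an
independent 64-bit sub-seed, so nested stochastic procedures (repeated CV,
bootstrap replicates, internal Monte-Carlo) never share streams with the
outer experiment seed.
"""

from __future__ import annotations

_M64 = (1 << 64) - 1
_GOLDEN = 0x9E3779B97F4A7C15


def derive_seed(seed: int, index: int) -> int:
    """Return a reproducible sub-seed for stream `index` under `seed`."""
    z = (int(seed) & _M64) ^ ((int(index) + 1) * _GOLDEN & _M64)
    z = (z + _GOLDEN) & _M64
    z ^= z >> 30
    z = (z * 0xBF58476D1CE4E5B9) & _M64
    z ^= z >> 27
    z = (z * 0x94D049BB133111EB) & _M64
    z ^= z >> 31
    return z
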