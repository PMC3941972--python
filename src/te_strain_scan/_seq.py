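"""Low-level DNA helpers shared across modules.

Sequences are plain upper-case strings at API boundaries; hot loops use
numpy uint8 code arrays (A=0, C=1, G=2, T=3, anything else=4).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code array (N and unknowns -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=length).astype(np.uint8))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability `rate`, uniformly among the
    3 alternative bases (Jukes-Cantor-compatible single pass, no indels)."""
    if not 0.0 <= rate <= 0.75:
        raise ValueError(f"substitution rate {rate} outside [0, 0.75]")
    codes = encode(seq).copy()
    hit = rng.random(len(codes)) < rate
    idx = np.nonzero(hit & (codes < 4))[0]
    if idx.size:
        # add 1..3 mod 4: always lands on a different base
        shift = rng.integers(1, 4, size=idx.size).astype(np.uint8)
        codes[idx] = (codes[idx] + shift) % 4
    return decode(codes)
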