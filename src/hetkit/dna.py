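"""Low-level DNA utilities: 2-bit encoding, complements, random sequence.

Sequences are handled in two forms throughout the package: python ``str``
(for I/O and alignment) and ``numpy`` ``uint8`` code arrays with A=0, C=1,
G=2, T=3 (for k-mer arithmetic and read simulation). Conversions are
vectorised; none of the generators ever emit ambiguity codes.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 code array (A=0,C=1,G=2,T=3)."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _CODE[raw]
    if codes.max(initial=0) > 3:
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to a DNA string."""
    return _DECODE[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return decode(random_codes(rng, n))


def mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Return a copy of ``seq`` with substitutions planted at ``rate``.

    Every substitution changes the base (drawn from the three alternatives),
    so the realised divergence equals the number of planted sites.
    """
    codes = encode(seq).copy()
    hits = np.flatnonzero(rng.random(len(codes)) < rate)
    if hits.size:
        shift = rng.integers(1, 4, size=hits.size, dtype=np.uint8)
        codes[hits] = (codes[hits] + shift) % 4
    return decode(codes)
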