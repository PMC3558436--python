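"""Low-level DNA helpers shared across the package."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# A,C,G,T -> 0..3; everything else (incl. N) -> 4
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(BASES):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

VALID_CHARS = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement; preserves case, N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return decode(rng.integers(0, 4, n, dtype=np.uint8))


def matches(a: np.ndarray, b: np.ndarray) -> int:
    """Number of matching columns between equal-length code arrays.

    An N (code 4) never matches anything, including another N.
    """
    return int(np.count_nonzero((a == b) & (a < 4) & (b < 4)))


def check_dna(seq: str) -> None:
    """Raise ValueError when *seq* contains characters outside {A,C,G,T,N}."""
    bad = set(seq.upper()) - VALID_CHARS
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)!r}")
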