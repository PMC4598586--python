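"""Low-level nucleotide codecs shared across the toolkit.

Sequences are held as Python strings at the API surface and as uint8 code
arrays (A=0, C=1, G=2, T=3, N=4) in numerical kernels.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4

_ENCODE_LUT = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_LUT[_b] = _i
    _ENCODE_LUT[_b + 32] = _i  # lowercase

_DECODE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = np.array([T, G, C, A, N], dtype=np.uint8)

_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _DECODE_LUT[arr].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr][::-1]


def convert_ct(arr: np.ndarray) -> np.ndarray:
    """Bisulfite C->T conversion of a code array (copy)."""
    out = arr.copy()
    out[out == C] = T
    return out


def convert_ga(arr: np.ndarray) -> np.ndarray:
    """G->A conversion (the complementary-strand bisulfite alphabet)."""
    out = arr.copy()
    out[out == G] = A
    return out


def random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Draw i.i.d. bases with the given GC fraction; returns uint8 codes."""
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def phred_to_array(qual: str) -> np.ndarray:
    """Phred+33 quality string -> integer array."""
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33


def array_to_phred(q: np.ndarray) -> str:
    return (np.clip(q, 0, 60).astype(np.uint8) + 33).tobytes().decode("ascii")
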