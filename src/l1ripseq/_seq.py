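"""Small sequence and coordinate utilities shared across modules.

Coordinate conventions, declared once and used everywhere:

* BED intervals are 0-based, half-open.
* GTF intervals are 1-based, inclusive.
* SAM positions are 1-based.

Nucleotides are handled either as Python strings or as uint8 code arrays
(A=0, C=1, G=2, T=3, N=4); the code-array form is what the vectorised
simulator and alignment emulator operate on.
"""

from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgtn"):
    _CODE[_b] = _i

_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G, N->N

STOP_CODONS = {"TAA", "TAG", "TGA"}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an upper-case string."""
    return BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def bed_to_gtf(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start0 + 1, end0


def gtf_to_bed(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start1 - 1, end1
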