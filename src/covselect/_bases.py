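"""Nucleotide alphabet helpers shared by the simulator and the decoder.

All sequences in this package are uppercase ACGT. Two byte-level encodings are
used internally: ASCII (uint8 values of 'A','C','G','T'), which is what FASTQ
files and the vectorised decoder operate on, and 2-bit codes 0..3, which the
simulator uses for substitution-error arithmetic.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
BASE_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)

# ASCII byte -> 2-bit code; 255 marks a non-ACGT byte.
CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASE_ASCII):
    CODE_OF[_b] = _i


def is_valid_seq(seq: str) -> bool:
    """True if *seq* is a (possibly empty) uppercase ACGT string."""
    return all(c in ALPHABET for c in seq)


def seq_to_ascii(seq: str) -> np.ndarray:
    """String -> 1-D uint8 array of ASCII bytes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def ascii_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def umi_int_to_seq(u: int, length: int) -> str:
    """Decode an integer in [0, 4**length) to its base-4 nucleotide string."""
    out = []
    for k in range(length - 1, -1, -1):
        out.append(ALPHABET[(u >> (2 * k)) & 3])
    return "".join(out)


def umi_ints_to_ascii(u: np.ndarray, length: int) -> np.ndarray:
    """Vectorised UMI integers -> (n, length) ASCII byte matrix."""
    shifts = 2 * np.arange(length - 1, -1, -1, dtype=np.int64)
    codes = (np.asarray(u, dtype=np.int64)[:, None] >> shifts) & 3
    return BASE_ASCII[codes]
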