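"""Low-level DNA sequence helpers.

Sequences are held internally as ``uint8`` code arrays (A=0, C=1, G=2, T=3,
N/other=4), which keeps per-site mutation and k-mer extraction vectorised.
The code order is alphabetical so that comparing packed k-mer integers is
equivalent to comparing k-mer strings lexicographically.
"""
from __future__ import annotations

import numpy as np

from .errors import InputError

A, C, G, T, N = 0, 1, 2, 3, 4

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string into a uint8 code array."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _ENCODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _DECODE[codes].tobytes().decode("ascii")


def complement(codes: np.ndarray) -> np.ndarray:
    out = (3 - codes.astype(np.int16)).astype(np.uint8)
    out[codes == N] = N
    return out


def revcomp(codes: np.ndarray) -> np.ndarray:
    return complement(codes)[::-1]


def write_fasta(genome: dict[str, np.ndarray | str], path, width: int = 80) -> None:
    """Write a genome dict to FASTA with fixed line width."""
    with open(path, "w") as fh:
        for name, seq in genome.items():
            if not isinstance(seq, str):
                seq = decode(seq)
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, np.ndarray]:
    """Read a FASTA file into a dict of code arrays."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True, build_index=True)
    genome = {name: encode(str(fa[name][:])) for name in fa.keys()}
    if not genome:
        raise InputError(f"empty FASTA: {path}")
    return genome


def rolling_canonical_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical k-mer codes for every valid window of a sequence.

    Returns ``(positions, canonical_codes)`` over windows free of ambiguous
    bases. The canonical form is the lexicographic minimum of the k-mer and
    its reverse complement, represented as a base-4 packed integer.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    if 2 * k > 63:
        raise InputError("k too large for 64-bit packing")
    L = len(codes)
    n = L - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    x = codes.astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    for i in range(k):
        window = x[i : i + n]
        bad |= window > 3
        fwd |= np.where(window > 3, 0, window) << np.uint64(2 * (k - 1 - i))
        rev |= np.where(window > 3, 0, (3 - window) & np.uint64(3)) << np.uint64(2 * i)
    canon = np.minimum(fwd, rev)
    keep = ~bad
    return np.nonzero(keep)[0].astype(np.int64), canon[keep]


def code_to_kmer(code: int, k: int) -> str:
    """Unpack a base-4 packed integer back into a k-mer string."""
    out = bytearray(k)
    for i in range(k - 1, -1, -1):
        out[i] = b"ACGT"[code & 3]
        code >>= 2
    return out.decode("ascii")


def kmer_to_code(kmer: str) -> int:
    code = 0
    for ch in kmer:
        code = (code << 2) | int(_ENCODE[ord(ch)])
    return code
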