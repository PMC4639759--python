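"""Two-bit sequence encoding and vectorized canonical k-mer extraction.

Sequences are held as uint8 code arrays (A=0, C=1, G=2, T=3; anything else
255).  A k-mer with k <= 31 packs into a uint64; the canonical form is the
lexicographic minimum of the k-mer and its reverse complement, which under
this encoding is simply the numeric minimum of the two packed values.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

MAX_K = 31  # 2*31 = 62 bits < 64


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code array (255 for non-ACGT)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`; only valid for codes in 0..3."""
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes[::-1]).astype(np.uint8)


def _check_k(k: int) -> None:
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > MAX_K:
        raise ValueError(f"k must be <= {MAX_K} for packed counting, got {k}")


def forward_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed forward-strand k-mers (no canonicalization); windows spanning
    non-ACGT codes are returned but carry arbitrary packing — callers that
    allow such symbols must mask them separately."""
    _check_k(k)
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    m = n - k + 1
    clean = np.where(codes > 3, 0, codes).astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd |= clean[j : j + m] << np.uint64(2 * (k - 1 - j))
    return fwd


def canonical_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed canonical k-mers of one sequence, skipping windows with non-ACGT.

    Returns a uint64 array with one entry per valid window, in sequence order.
    """
    _check_k(k)
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    m = n - k + 1
    bad = codes > 3
    clean = np.where(bad, 0, codes).astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        col = clean[j : j + m]
        fwd |= col << np.uint64(2 * (k - 1 - j))
        rev |= (np.uint64(3) - col) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    if bad.any():
        cs = np.concatenate(([0], np.cumsum(bad)))
        ok = (cs[k:] - cs[:-k]) == 0
        canon = canon[ok]
    return canon


def canonical_kmers_matrix(codes: np.ndarray, k: int, chunk: int = 65536) -> np.ndarray:
    """Packed canonical k-mers for a (n_reads, read_len) code matrix.

    All codes must be valid (0..3); rows are processed in chunks to bound
    the working-set size.  Returns one flat uint64 array.
    """
    _check_k(k)
    n, length = codes.shape
    if length < k:
        return np.empty(0, dtype=np.uint64)
    m = length - k + 1
    out = []
    for lo in range(0, n, chunk):
        block = codes[lo : lo + chunk].astype(np.uint64)
        rows = block.shape[0]
        fwd = np.zeros((rows, m), dtype=np.uint64)
        rev = np.zeros((rows, m), dtype=np.uint64)
        for j in range(k):
            col = block[:, j : j + m]
            fwd |= col << np.uint64(2 * (k - 1 - j))
            rev |= (np.uint64(3) - col) << np.uint64(2 * j)
        out.append(np.minimum(fwd, rev).ravel())
    return np.concatenate(out) if out else np.empty(0, dtype=np.uint64)


def canonical_str(kmer: str) -> str:
    """Canonical (lexicographic min of k-mer / reverse complement) as a string."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc
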