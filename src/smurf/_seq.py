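"""Low-level DNA sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

# IUPAC nucleotide ambiguity codes -> sorted set of concrete bases.
IUPAC_SETS: dict[str, str] = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "S": "CG",
    "W": "AT",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an unambiguous A/C/G/T string as a uint8 code array (A=0..T=3)."""
    out = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(out.shape, 255, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        codes[out == ord(base)] = code
    if (codes == 255).any():
        pos = int(np.argmax(codes == 255))
        raise ValueError(f"non-ACGT base {seq[pos]!r} at position {pos}")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def iupac_match_table(primer: str) -> np.ndarray:
    """Boolean table t[i, c] = primer position i accepts base code c."""
    table = np.zeros((len(primer), 4), dtype=bool)
    for i, ch in enumerate(primer):
        try:
            allowed = IUPAC_SETS[ch]
        except KeyError:
            raise ValueError(f"non-IUPAC character {ch!r} at position {i}") from None
        for b in allowed:
            table[i, _BASE_CODE[b]] = True
    return table


def hamming_matrix(reads: np.ndarray, kmers: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Pairwise Hamming distances between two code arrays of equal row length.

    Returns an (n_reads, n_kmers) int16 matrix; chunked over reads to bound
    the size of the intermediate boolean tensor.
    """
    n, m = reads.shape[0], kmers.shape[0]
    out = np.empty((n, m), dtype=np.int16)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        out[start:stop] = (
            reads[start:stop, None, :] != kmers[None, :, :]
        ).sum(axis=2, dtype=np.int16)
    return out
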