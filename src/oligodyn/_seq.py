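"""Internal nucleotide encoding helpers shared across modules.

Sequences are encoded over the 5-letter alphabet {A, C, G, T, N} as uint8
codes 0..4.  N is a first-class symbol (code 4), never dropped, so reads
with ambiguous calls stay visible to entropy and identity computations.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGTN"
N_SYMBOLS = 5

_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode one sequence to a uint8 code vector; rejects symbols outside ACGTN."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _LUT[raw]
    if (codes == 255).any():
        bad = sorted({chr(c) for c in raw[codes == 255]})
        raise ValueError(f"sequence contains unsupported symbols {bad}")
    return codes


def encode_many(seqs: list[str]) -> np.ndarray:
    """Encode equal-length sequences into an (n, L) uint8 matrix."""
    if not seqs:
        raise ValueError("no sequences to encode")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have mixed lengths {sorted(lengths)}")
    raw = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    codes = _LUT[raw].reshape(len(seqs), lengths.pop())
    if (codes == 255).any():
        raise ValueError("sequences contain symbols outside ACGTN")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def hamming(a: str, b: str) -> int:
    """Mismatch count between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int(np.count_nonzero(encode(a) != encode(b)))


def percent_identity(a: str, b: str) -> float:
    """Ungapped identity (%) between two equal-length sequences."""
    if len(a) == 0:
        raise ValueError("empty sequences")
    return 100.0 * (1.0 - hamming(a, b) / len(a))


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return seq.translate(comp)[::-1]
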