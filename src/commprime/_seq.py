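"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC nucleotide one-letter codes; ambiguity codes other than N collapse to N.
IUPAC_TO_CANONICAL = str.maketrans(
    {c: ("N" if c not in "ACGT" else c) for c in "ACGTNRYSWKMBDHV"}
)
IUPAC_CHARS = frozenset("ACGTNRYSWKMBDHV")

_ENCODE_LUT = np.full(256, 4, dtype=np.int8)  # everything else behaves like N
for _i, _c in enumerate("ACGT"):
    _ENCODE_LUT[ord(_c)] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and anything else (N) as 4 for the DP kernels."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def kmers(seq: str, k: int):
    """Yield (offset, kmer) for every k-window; windows containing N skipped."""
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" not in w:
            yield i, w


def max_homopolymer_run(seq: str) -> int:
    best = run = 1 if seq else 0
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        if run > best:
            best = run
    return best
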