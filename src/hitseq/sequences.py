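"""Small alphabet and k-mer utilities shared across the package.

The randomized segment is RNA (alphabet ACGU) but sequencing reads are DNA
(ACGT); conversion is a plain U<->T swap because the constructs contain no
modified bases. k-mers are enumerated lexicographically over ACGU and encoded
as base-4 integers (A=0, C=1, G=2, U/T=3) for fast vectorised counting.
"""

from __future__ import annotations

import itertools

import numpy as np

RNA_BASES = "ACGU"
DNA_BASES = "ACGT"

#: ASCII-code -> base-4 code lookup (A=0, C=1, G=2, T/U=3); 255 marks invalid.
BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(RNA_BASES):
    BASE_CODE[ord(_b)] = _i
BASE_CODE[ord("T")] = 3

#: base-4 code -> ASCII code, DNA and RNA flavours.
CODE_TO_DNA = np.frombuffer(DNA_BASES.encode(), dtype=np.uint8).copy()
CODE_TO_RNA = np.frombuffer(RNA_BASES.encode(), dtype=np.uint8).copy()


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def validate_sequence(seq: str, alphabet: str = RNA_BASES, *, what: str = "sequence") -> None:
    """Raise ValueError naming the first offending symbol, if any."""
    for ch in seq:
        if ch not in alphabet:
            raise ValueError(
                f"invalid symbol {ch!r} in {what} {seq!r}; allowed alphabet is {alphabet}"
            )


def all_kmers(k: int, alphabet: str = RNA_BASES) -> list[str]:
    """All length-k strings over `alphabet` in lexicographic order."""
    if k < 1:
        raise ValueError(f"k must be positive, got {k}")
    return ["".join(p) for p in itertools.product(alphabet, repeat=k)]


def kmer_to_index(kmer: str) -> int:
    """Base-4 integer code of a k-mer (A=0, C=1, G=2, U/T=3)."""
    idx = 0
    for ch in kmer:
        code = BASE_CODE[ord(ch)]
        if code == 255:
            raise ValueError(f"invalid symbol {ch!r} in k-mer {kmer!r}")
        idx = idx * 4 + int(code)
    return idx


def index_to_kmer(idx: int, k: int, alphabet: str = RNA_BASES) -> str:
    out = []
    for _ in range(k):
        out.append(alphabet[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def encode_kmers(kmers: np.ndarray | list[str]) -> np.ndarray:
    """Vectorised k-mer -> base-4 integer codes for equal-length k-mers."""
    arr = np.asarray(kmers, dtype="U")
    k = arr.dtype.itemsize // 4
    bytes_view = arr.view(np.uint32).reshape(len(arr), k).astype(np.uint8)
    codes = BASE_CODE[bytes_view]
    if (codes == 255).any():
        bad = arr[(codes == 255).any(axis=1)][0]
        raise ValueError(f"invalid symbol in k-mer {bad!r}")
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return codes.astype(np.int64) @ weights
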