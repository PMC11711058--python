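"""Small sequence utilities shared across modules.

Nucleotides are encoded as int8 codes 0..3 (A, C, G, T); any gap or IUPAC
ambiguity character is encoded as -1 and treated as fully missing downstream.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
MISSING = -1

_CODE = np.full(256, MISSING, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (-1 for gap/ambiguity)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode int8 codes back to a string; missing states become '-'."""
    out = np.full(codes.shape, "-", dtype="U1")
    ok = codes >= 0
    out[ok] = np.array(list(BASES))[codes[ok]]
    return "".join(out)


def revcomp(seq: str) -> str:
    return "".join(_COMP.get(c.upper(), "N") for c in reversed(seq))


def ungap(seq: str) -> str:
    return seq.replace("-", "").replace(".", "")


def kmer_set(seq: str, k: int) -> set[str]:
    """Set of k-mers of the ungapped, uppercased sequence."""
    s = ungap(seq).upper()
    return {s[i : i + k] for i in range(len(s) - k + 1)}


def kmer_containment(query: str, reference: str, k: int) -> float:
    """Shared k-mers as a fraction of the query's k-mers."""
    q = kmer_set(query, k)
    if not q:
        return 0.0
    return len(q & kmer_set(reference, k)) / len(q)
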