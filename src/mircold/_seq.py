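"""Small sequence utilities shared across the pipeline.

All pipeline comparisons happen in the DNA alphabet; RNA input (U) is
normalized to T on entry and back to U only where a module's convention
is explicitly RNA (target scoring).
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTUN", "TGCAAN")

DNA_BASES = "ACGT"


def to_dna(seq: str) -> str:
    """Uppercase and convert U -> T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and convert T -> U."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U treated as T)."""
    return seq.upper().translate(_COMP)[::-1]


def gc_percent(seq: str) -> float:
    """GC content as a percentage (e.g. 50.0, not 0.5)."""
    if not seq:
        return 0.0
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random DNA sequence with expected GC fraction ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(DNA_BASES[i] for i in idx)


def min_hamming_to_windows(query: str, subject: str) -> int:
    """Minimum Hamming distance of ``query`` to any same-length window of
    ``subject`` (forward strand only). Returns len(query)+1 if subject is
    shorter than query."""
    L = len(query)
    if len(subject) < L:
        return L + 1
    best = L + 1
    for i in range(len(subject) - L + 1):
        d = hamming(query, subject[i : i + L])
        if d < best:
            best = d
            if best == 0:
                break
    return best
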