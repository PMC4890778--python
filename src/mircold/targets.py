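"""miRNA target prediction by complementarity expectation scoring.

A miRNA read 5'->3' is aligned, ungapped, against each transcript window
read 3'->5' (the biological pairing orientation). Each position scores a
penalty: Watson-Crick pair 0, G:U wobble 0.5, anything else 1.0, and
penalties are doubled at miRNA positions 2-13 (1-based from the miRNA 5'
end) — the seed region that plant cleavage targets must pair tightly.
The expectation is the penalty sum; windows at or below the cutoff
(default 3.0) are reported, together with the canonical predicted
cleavage coordinate: the transcript base paired to miRNA position 10,
i.e. the 5' side of the bond between miRNA positions 10 and 11.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import to_rna

__all__ = ["TargetAlignment", "score_window", "scan_transcript", "cleavage_site"]

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

SEED_START = 2   # 1-based miRNA positions with doubled penalty
SEED_END = 13
DEFAULT_CUTOFF = 3.0


@dataclass
class TargetAlignment:
    """One scored miRNA/transcript window."""

    mirna_name: str
    transcript_id: str
    window_start: int          # 0-based on the transcript
    expectation: float
    pairing: list[str]         # per miRNA position: match | wobble | mismatch
    cleavage_pos: int          # 0-based transcript coordinate


def score_window(mirna: str, window: str) -> tuple[float, list[str]]:
    """Expectation penalty of one window.

    ``mirna`` 5'->3'; ``window`` is the transcript substring 5'->3' — the
    miRNA's 5' end pairs the window's 3' end. Sequences may be DNA or RNA;
    both are normalized to RNA.
    """
    mi = to_rna(mirna)
    win = to_rna(window)
    L = len(mi)
    if len(win) != L:
        raise ValueError("window length must equal miRNA length")
    total = 0.0
    pairing: list[str] = []
    for i in range(L):
        pair = (mi[i], win[L - 1 - i])
        if pair in _WC:
            penalty, sym = 0.0, "match"
        elif pair in _WOBBLE:
            penalty, sym = 0.5, "wobble"
        else:
            penalty, sym = 1.0, "mismatch"
        if SEED_START <= i + 1 <= SEED_END:
            penalty *= 2.0
        total += penalty
        pairing.append(sym)
    return total, pairing


def cleavage_position(window_start: int, mirna_len: int) -> int:
    """Transcript base paired to miRNA position 10 (0-based coordinate).

    The miRNA 5' end pairs the window's 3' end, so miRNA position p
    (1-based) pairs transcript position window_start + L - p.
    """
    return window_start + mirna_len - 10


def cleavage_site(alignment: TargetAlignment) -> int:
    """Predicted cleavage coordinate for an existing alignment."""
    return cleavage_position(alignment.window_start, len(alignment.pairing))


def scan_transcript(mirna: str, transcript: str, cutoff: float = DEFAULT_CUTOFF,
                    mirna_name: str = "mirna", transcript_id: str = "transcript"
                    ) -> list[TargetAlignment]:
    """All windows with expectation <= cutoff, best (lowest) first.

    Ties are ordered by window start. Raising the cutoff only ever adds
    hits.
    """
    mi = to_rna(mirna)
    tr = to_rna(transcript)
    L = len(mi)
    if len(tr) < L:
        raise ValueError("transcript shorter than miRNA")
    hits: list[TargetAlignment] = []
    for start in range(len(tr) - L + 1):
        e, pairing = score_window(mi, tr[start : start + L])
        if e <= cutoff:
            hits.append(TargetAlignment(
                mirna_name=mirna_name, transcript_id=transcript_id,
                window_start=start, expectation=e, pairing=pairing,
                cleavage_pos=cleavage_position(start, L),
            ))
    hits.sort(key=lambda h: (h.expectation, h.window_start))
    return hits
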