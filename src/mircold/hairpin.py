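"""Novel miRNA discovery from stem-loop precursor candidates.

Unassigned tags are mapped exactly onto transcript contigs (both
strands), a window of 150 nt on each side of the hit is excised, folded
to its minimum-free-energy secondary structure, and judged against plant
miRNA annotation criteria:

* the mature tag must lie entirely on one arm of a hairpin (no base in
  the terminal loop);
* at most 4 mature bases unpaired in the miRNA/miRNA* duplex;
* no bulge longer than 2 nt within the mature span;
* MFEI = AMFE / GC% with AMFE = MFE / length * 100 must satisfy
  |MFEI| >= 0.85 (MFEI negative) — the strongest single discriminator of
  miRNA hairpins from other structured RNAs;
* trimmed precursor length within bounds (default 45-400 nt).

The +/-150 window is first trimmed to the enclosing hairpin — the
outermost base pair bracketing the mature and its pairing partners —
and refolded; length, GC% and energies refer to this trimmed precursor.
(Reported precursor lengths for plant pre-miRNAs are typically far below
the raw 300+ nt excision window, so criteria are applied to the hairpin
itself, not the window.)

Folding is delegated to a pluggable backend; the default wraps the
ViennaRNA thermodynamic engine (deterministic MFE structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import pandas as pd

from ._seq import gc_percent, revcomp, to_dna, to_rna

__all__ = [
    "TagHit",
    "PrecursorCandidate",
    "FoldResult",
    "HairpinEvaluation",
    "HairpinConfig",
    "map_tags",
    "extract_precursor",
    "fold",
    "evaluate_hairpin",
    "select_novel",
]

DEFAULT_FLANK = 150
DEFAULT_MAX_HITS = 20


@dataclass(frozen=True)
class TagHit:
    """Exact occurrence of a tag on a contig (strand-aware)."""

    tag_seq: str
    contig_id: str
    start: int   # 0-based
    end: int     # exclusive
    strand: str  # '+' or '-'


@dataclass
class PrecursorCandidate:
    """Excised precursor window, oriented along the tag's strand."""

    contig_id: str
    window_start: int
    window_end: int
    strand: str
    seq: str
    mature_offset: int  # 0-based position of the tag within seq
    tag_seq: str


@dataclass(frozen=True)
class FoldResult:
    """Dot-bracket MFE structure of one sequence."""

    structure: str
    mfe: float  # kcal/mol, <= 0


@dataclass
class HairpinConfig:
    flank: int = DEFAULT_FLANK
    max_hits: int = DEFAULT_MAX_HITS
    max_duplex_mismatches: int = 4
    max_bulge: int = 2
    min_abs_mfei: float = 0.85
    min_precursor_len: int = 45
    max_precursor_len: int = 400


@dataclass
class HairpinEvaluation:
    """Criteria evaluation of one folded precursor candidate."""

    candidate: PrecursorCandidate
    arm: str                    # 5p | 3p | loop-spanning | unpaired
    duplex_mismatches: int      # unpaired mature bases
    max_bulge: int              # longest unpaired run within the mature span
    precursor_seq: str          # trimmed to the enclosing hairpin
    precursor_len: int
    structure: str              # of the trimmed precursor
    mfe: float
    amfe: float                 # mfe / length * 100
    mfei: float                 # amfe / gc_percent
    gc_percent: float
    flags: dict[str, bool] = field(default_factory=dict)
    passed: bool = False


# ---------------------------------------------------------------------------
# mapping and excision


def map_tags(tag_seqs: Sequence[str], contigs: Mapping[str, str],
             max_hits: int = DEFAULT_MAX_HITS) -> list[TagHit]:
    """All exact occurrences of each tag on both strands of the contigs.

    Tags hitting more than ``max_hits`` loci are discarded as repeats.
    """
    by_len: dict[int, dict[str, list[tuple[str, str]]]] = {}
    for t in tag_seqs:
        t = to_dna(t)
        d = by_len.setdefault(len(t), {})
        d.setdefault(t, []).append((t, "+"))
        d.setdefault(revcomp(t), []).append((t, "-"))

    hits: dict[str, list[TagHit]] = {t: [] for t in tag_seqs}
    for contig_id, cseq in contigs.items():
        cseq = to_dna(cseq)
        n = len(cseq)
        for L, lookup in by_len.items():
            for i in range(n - L + 1):
                window = cseq[i : i + L]
                for tag, strand in lookup.get(window, ()):
                    hits[tag].append(TagHit(tag, contig_id, i, i + L, strand))
    out: list[TagHit] = []
    for t in tag_seqs:
        if 0 < len(hits[t]) <= max_hits:
            out.extend(hits[t])
    return out


def extract_precursor(hit: TagHit, contigs: Mapping[str, str],
                      flank: int = DEFAULT_FLANK) -> PrecursorCandidate:
    """Excise the candidate precursor window around a hit.

    The window spans ``flank`` nt on each side, clipped at contig bounds,
    and is reverse-complemented for minus-strand hits so that the mature
    tag always reads 5'->3' within ``seq`` at ``mature_offset``.
    """
    cseq = to_dna(contigs[hit.contig_id])
    w_start = max(0, hit.start - flank)
    w_end = min(len(cseq), hit.end + flank)
    window = cseq[w_start:w_end]
    if hit.strand == "+":
        offset = hit.start - w_start
    else:
        window = revcomp(window)
        offset = w_end - hit.end
    return PrecursorCandidate(
        contig_id=hit.contig_id, window_start=w_start, window_end=w_end,
        strand=hit.strand, seq=window, mature_offset=offset, tag_seq=hit.tag_seq,
    )


# ---------------------------------------------------------------------------
# folding


def _vienna_fold(seq: str) -> FoldResult:
    import RNA

    structure, mfe = RNA.fold(seq)
    return FoldResult(structure=structure, mfe=float(mfe))


def fold(seq: str, backend: Callable[[str], FoldResult] | None = None) -> FoldResult:
    """Deterministic MFE fold of an RNA sequence.

    ``seq`` may be DNA or RNA; it is folded as RNA. Characters outside
    A/C/G/U(T) are rejected. The backend contract is minimal: a balanced
    dot-bracket structure of the same length and an MFE <= 0.
    """
    rna = to_rna(seq)
    if not rna or any(c not in "ACGU" for c in rna):
        raise ValueError("sequence must be non-empty over A/C/G/U (or T)")
    result = (backend or _vienna_fold)(rna)
    if len(result.structure) != len(rna):
        raise RuntimeError("folding backend returned structure of wrong length")
    return result


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 if unpaired) from dot-bracket."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            pt[i], pt[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return pt


def _hairpin_loops(pt: list[int]) -> list[tuple[int, int]]:
    """Terminal-loop intervals [i+1, j) for innermost pairs (i, j)."""
    loops = []
    for i, j in ((i, pt[i]) for i in range(len(pt)) if pt[i] > i):
        if all(pt[k] == -1 for k in range(i + 1, j)):
            loops.append((i + 1, j))
    return loops


# ---------------------------------------------------------------------------
# criteria evaluation


def _mature_geometry(pt: list[int], m0: int, m1: int) -> tuple[str, int, int, list[int]]:
    """(arm, duplex_mismatches, max_bulge, partners) for mature span [m0, m1)."""
    partners = [pt[i] for i in range(m0, m1) if pt[i] != -1]
    mismatches = (m1 - m0) - len(partners)
    run = best_run = 0
    for i in range(m0, m1):
        if pt[i] == -1:
            run += 1
            best_run = max(best_run, run)
        else:
            run = 0
    if not partners:
        return "unpaired", mismatches, best_run, partners
    for lo, hi in _hairpin_loops(pt):
        if not (m1 <= lo or m0 >= hi):
            return "loop-spanning", mismatches, best_run, partners
    mid_mature = (m0 + m1 - 1) / 2
    mid_partner = (min(partners) + max(partners)) / 2
    arm = "5p" if mid_mature < mid_partner else "3p"
    return arm, mismatches, best_run, partners


def _trim_to_hairpin(seq: str, pt: list[int], m0: int, m1: int,
                     partners: list[int], max_interior_gap: int = 15
                     ) -> tuple[int, int]:
    """[lo, hi) bounds of the stem-loop enclosing the mature's duplex.

    Starting from the span of the mature and its partners, enclosing base
    pairs are added outward only while the region stays a simple hairpin
    (exactly one terminal loop — no multiloop branching) and the interior
    gap to the next enclosing pair stays small. This keeps the excision
    window's incidental long-range pairs in the flanking sequence from
    being absorbed into the precursor.
    """
    lo = min([m0] + partners)
    hi = max([m1 - 1] + partners)
    loops = _hairpin_loops(pt)
    cur_lo, cur_hi = lo, hi
    for i in range(lo, -1, -1):
        j = pt[i]
        if j < hi:
            continue
        n_loops = sum(1 for a, b in loops if i < a and b <= j)
        if n_loops != 1:
            break
        if (cur_lo - i) > max_interior_gap or (j - cur_hi) > max_interior_gap:
            break
        cur_lo, cur_hi = i, j
    return cur_lo, cur_hi + 1


def evaluate_hairpin(candidate: PrecursorCandidate, fold_result: FoldResult,
                     config: HairpinConfig | None = None,
                     backend: Callable[[str], FoldResult] | None = None
                     ) -> HairpinEvaluation:
    """Apply the annotation criteria to a folded precursor window.

    The window is trimmed to the enclosing hairpin and refolded; all
    reported statistics (arm, duplex mismatches, bulges, MFE/AMFE/MFEI,
    length, GC%) refer to the trimmed precursor.
    """
    cfg = config or HairpinConfig()
    seq = candidate.seq
    m0 = candidate.mature_offset
    m1 = m0 + len(candidate.tag_seq)
    pt = pair_table(fold_result.structure)

    arm, mm, bulge, partners = _mature_geometry(pt, m0, m1)
    if partners:
        lo, hi = _trim_to_hairpin(seq, pt, m0, m1, partners)
    else:
        lo, hi = m0, m1
    trimmed = seq[lo:hi]
    t_m0, t_m1 = m0 - lo, m1 - lo

    if partners and len(trimmed) >= 10:
        t_fold = fold(trimmed, backend=backend)
        t_pt = pair_table(t_fold.structure)
        arm, mm, bulge, t_partners = _mature_geometry(t_pt, t_m0, t_m1)
        structure, mfe = t_fold.structure, t_fold.mfe
    else:
        structure, mfe = fold_result.structure[lo:hi], 0.0

    length = len(trimmed)
    gc = gc_percent(trimmed)
    amfe = mfe / length * 100.0 if length else 0.0
    mfei = amfe / gc if gc > 0 else 0.0

    flags = {
        "one_arm": arm in ("5p", "3p"),
        "duplex_mismatches": mm <= cfg.max_duplex_mismatches,
        "max_bulge": bulge <= cfg.max_bulge,
        "mfei": mfei < 0 and abs(mfei) >= cfg.min_abs_mfei,
        "length": cfg.min_precursor_len <= length <= cfg.max_precursor_len,
    }
    return HairpinEvaluation(
        candidate=candidate, arm=arm, duplex_mismatches=mm, max_bulge=bulge,
        precursor_seq=trimmed, precursor_len=length, structure=structure,
        mfe=mfe, amfe=amfe, mfei=mfei, gc_percent=gc,
        flags=flags, passed=all(flags.values()),
    )


def select_novel(evaluations: Sequence[HairpinEvaluation]) -> pd.DataFrame:
    """One novel miRNA per distinct mature sequence.

    Among passing loci sharing a mature sequence, the locus with the
    largest |MFEI| is reported. The returned frame includes locus
    coordinates, arm, energies and flags; mature-length distribution and
    arm tallies are derivable directly from it.
    """
    best: dict[str, HairpinEvaluation] = {}
    for ev in evaluations:
        if not ev.passed:
            continue
        seq = ev.candidate.tag_seq
        if seq not in best or abs(ev.mfei) > abs(best[seq].mfei):
            best[seq] = ev
    rows = []
    for seq in sorted(best):
        ev = best[seq]
        c = ev.candidate
        rows.append({
            "mature_seq": seq, "length": len(seq), "contig_id": c.contig_id,
            "window_start": c.window_start, "window_end": c.window_end,
            "strand": c.strand, "arm": ev.arm,
            "precursor_len": ev.precursor_len, "mfe": ev.mfe,
            "amfe": ev.amfe, "mfei": ev.mfei, "gc_percent": ev.gc_percent,
        })
    cols = ["mature_seq", "length", "contig_id", "window_start", "window_end",
            "strand", "arm", "precursor_len", "mfe", "amfe", "mfei", "gc_percent"]
    return pd.DataFrame(rows, columns=cols)


def arm_tally(novel: pd.DataFrame) -> dict[str, int]:
    """Count of novel matures on each precursor arm."""
    if novel.empty:
        return {"5p": 0, "3p": 0}
    vc = novel["arm"].value_counts()
    return {"5p": int(vc.get("5p", 0)), "3p": int(vc.get("3p", 0))}
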