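"""Contaminant removal and conserved-miRNA assignment.

Tags matching rRNA/tRNA/snoRNA/organellar sequences are removed first;
the remainder are matched against a mature-miRNA catalog allowing up to
two mismatches, then aggregated into families for size-distribution and
tissue/condition specificity analyses.

Matching is deterministic Hamming matching with explicit overlap
semantics (rather than a heuristic local aligner): mismatches are counted
over the best ungapped end-to-end overlap that covers the full shorter
sequence. At tag scale this is exhaustively verifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from ._seq import hamming, revcomp, to_dna

__all__ = [
    "CatalogEntry",
    "ConservedAssignment",
    "SpecificitySets",
    "load_fasta",
    "filter_contaminants",
    "match_conserved",
    "family_of",
    "family_distribution",
    "specificity_sets",
]


@dataclass(frozen=True)
class CatalogEntry:
    """A known mature miRNA: name, family, sequence (DNA alphabet)."""

    name: str
    mature_seq: str

    @property
    def family(self) -> str:
        return family_of(self.name)


@dataclass
class ConservedAssignment:
    """Best catalog hit for one tag (<= 2 mismatches by default)."""

    tag_seq: str
    entry: CatalogEntry
    mismatches: int
    offset: int


@dataclass
class SpecificitySets:
    """Families partitioned by tissue/condition presence."""

    anther_only: set[str]
    ovary_only: set[str]
    stress_only: set[str]
    control_only: set[str]
    shared: set[str]

    def to_dict(self) -> dict[str, list[str]]:
        return {
            "anther_only": sorted(self.anther_only),
            "ovary_only": sorted(self.ovary_only),
            "stress_only": sorted(self.stress_only),
            "control_only": sorted(self.control_only),
            "shared": sorted(self.shared),
        }


def load_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: DNA sequence} (U normalized to T)."""
    return {rec.id: to_dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def load_catalog(path: str | Path) -> list[CatalogEntry]:
    return [CatalogEntry(name, seq) for name, seq in load_fasta(path).items()]


# ---------------------------------------------------------------------------
# contaminant filtering


def _contaminant_kmers(contaminants: Mapping[str, str], lengths: Iterable[int]) -> set[str]:
    kmers: set[str] = set()
    for seq in contaminants.values():
        for strand_seq in (seq, revcomp(seq)):
            n = len(strand_seq)
            for L in lengths:
                for i in range(n - L + 1):
                    kmers.add(strand_seq[i : i + L])
    return kmers


def filter_contaminants(tag_seqs: Sequence[str], contaminants: Mapping[str, str],
                        max_mm: int = 0) -> tuple[list[str], list[str]]:
    """Partition tags into (contaminant, retained).

    A tag is a contaminant iff it occurs as a substring of any contaminant
    sequence, on either strand, with at most ``max_mm`` mismatches. The
    partition is exhaustive and disjoint.
    """
    if not contaminants:
        warnings.warn("empty contaminant set: all tags retained")
        return [], list(tag_seqs)

    removed: list[str] = []
    retained: list[str] = []
    if max_mm == 0:
        lengths = sorted({len(t) for t in tag_seqs})
        kmers = _contaminant_kmers(contaminants, lengths)
        for t in tag_seqs:
            (removed if t in kmers else retained).append(t)
        return removed, retained

    subjects = [s for seq in contaminants.values() for s in (seq, revcomp(seq))]
    for t in tag_seqs:
        hit = False
        for subj in subjects:
            if len(subj) < len(t):
                continue
            for i in range(len(subj) - len(t) + 1):
                if hamming(t, subj[i : i + len(t)]) <= max_mm:
                    hit = True
                    break
            if hit:
                break
        (removed if hit else retained).append(t)
    return removed, retained


# ---------------------------------------------------------------------------
# conserved matching


def _overlap_mismatches(a: str, b: str) -> tuple[int, int]:
    """Best (mismatches, offset) over ungapped end-to-end overlaps in which
    the shorter sequence is fully covered by the longer."""
    if len(a) > len(b):
        short, long_, sign = b, a, -1
    else:
        short, long_, sign = a, b, 1
    best_mm, best_off = len(short) + 1, 0
    for off in range(len(long_) - len(short) + 1):
        mm = hamming(short, long_[off : off + len(short)])
        if mm < best_mm:
            best_mm, best_off = mm, off
            if mm == 0:
                break
    return best_mm, sign * best_off


def match_conserved(tag_seqs: Sequence[str], catalog: Sequence[CatalogEntry],
                    max_mm: int = 2, max_len_diff: int = 2
                    ) -> tuple[list[ConservedAssignment], list[str]]:
    """Assign each tag to its best catalog entry.

    Best = fewest mismatches, then smallest |length difference|, then
    lexicographically smallest name. Tags whose best exceeds ``max_mm``
    (or with no length-compatible entry) are returned unassigned.
    The result is invariant under catalog order.
    """
    entries = sorted(catalog, key=lambda e: e.name)
    assigned: list[ConservedAssignment] = []
    unassigned: list[str] = []
    for t in tag_seqs:
        best: tuple[int, int, str] | None = None
        best_rec: ConservedAssignment | None = None
        for e in entries:
            ldiff = abs(len(t) - len(e.mature_seq))
            if ldiff > max_len_diff:
                continue
            mm, off = _overlap_mismatches(t, e.mature_seq)
            key = (mm, ldiff, e.name)
            if best is None or key < best:
                best = key
                best_rec = ConservedAssignment(t, e, mm, off)
        if best_rec is not None and best_rec.mismatches <= max_mm:
            assigned.append(best_rec)
        else:
            unassigned.append(t)
    return assigned, unassigned


# ---------------------------------------------------------------------------
# family analytics

import re

# optional species prefix (e.g. pdu-), then miR<number>; variant letters
# and the -5p/-3p arm suffix are discarded
_FAMILY_RE = re.compile(r"^(?:[a-z]{2,4}-)?(?:mir|miR|MIR)(?P<num>\d+)")


def family_of(name: str) -> str:
    """Collapse a mature-miRNA name to its family: pdu-miR482b-5p -> miR482.

    Strips the species prefix, variant letter(s) and the -5p/-3p arm
    suffix; unparseable names are returned verbatim with a warning.
    """
    m = _FAMILY_RE.match(name)
    if m is None:
        warnings.warn(f"unparseable miRNA name {name!r}; using it verbatim as family")
        return name
    return "miR" + m.group("num")


def family_distribution(assignments: Sequence[ConservedAssignment],
                        tag_counts: Mapping[str, Mapping[str, int]] | None = None
                        ) -> pd.DataFrame:
    """Family member counts: distinct assigned catalog entries per family.

    With ``tag_counts`` (tag seq -> library -> count) supplied, per-library
    member counts are included (an entry is counted in a library when any
    of its assigned tags has count > 0 there); a 'pooled' column is always
    present.
    """
    fam_entries: dict[str, set[str]] = {}
    fam_lib_entries: dict[str, dict[str, set[str]]] = {}
    libs: list[str] = []
    for a in assignments:
        fam = a.entry.family
        fam_entries.setdefault(fam, set()).add(a.entry.name)
        if tag_counts is not None:
            per_lib = tag_counts.get(a.tag_seq, {})
            for lib, c in per_lib.items():
                if lib not in libs:
                    libs.append(lib)
                if c > 0:
                    fam_lib_entries.setdefault(fam, {}).setdefault(lib, set()).add(a.entry.name)
    rows = {}
    for fam in sorted(fam_entries):
        row = {"pooled": len(fam_entries[fam])}
        for lib in libs:
            row[lib] = len(fam_lib_entries.get(fam, {}).get(lib, set()))
        rows[fam] = row
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    df.index.name = "family"
    return df


def presence_matrix(assignments: Sequence[ConservedAssignment],
                    tag_counts: Mapping[str, Mapping[str, int]],
                    library_ids: Sequence[str], min_count: int = 1) -> pd.DataFrame:
    """family x library boolean presence (total assigned count >= min_count)."""
    fam_counts: dict[str, dict[str, int]] = {}
    for a in assignments:
        fam = a.entry.family
        per = tag_counts.get(a.tag_seq, {})
        row = fam_counts.setdefault(fam, {lib: 0 for lib in library_ids})
        for lib in library_ids:
            row[lib] += per.get(lib, 0)
    df = pd.DataFrame.from_dict(fam_counts, orient="index").reindex(columns=library_ids).fillna(0)
    df.index.name = "family"
    return df >= min_count


def specificity_sets(presence: pd.DataFrame,
                     library_meta: Mapping[str, tuple[str, str]]) -> SpecificitySets:
    """Tissue/condition-specific family sets from a presence matrix.

    ``library_meta`` maps library_id -> (tissue, condition) with tissue in
    {anther, ovary} and condition in {control, stress}. A family is e.g.
    anther-only when present in some anther library and absent from every
    ovary library; the condition axis is evaluated independently, so a
    family can be both anther-only and control-only. ``shared`` collects
    families specific on neither axis.
    """
    groups: dict[str, list[str]] = {"anther": [], "ovary": [], "control": [], "stress": []}
    for lib, (tissue, condition) in library_meta.items():
        groups[tissue].append(lib)
        groups[condition].append(lib)

    def present_in(fams: pd.DataFrame, libs: list[str]) -> pd.Series:
        if not libs:
            return pd.Series(False, index=fams.index)
        return fams[libs].any(axis=1)

    in_anther = present_in(presence, groups["anther"])
    in_ovary = present_in(presence, groups["ovary"])
    in_control = present_in(presence, groups["control"])
    in_stress = present_in(presence, groups["stress"])

    anther_only = set(presence.index[in_anther & ~in_ovary])
    ovary_only = set(presence.index[in_ovary & ~in_anther])
    stress_only = set(presence.index[in_stress & ~in_control])
    control_only = set(presence.index[in_control & ~in_stress])
    tissue_or_cond = anther_only | ovary_only | stress_only | control_only
    shared = set(presence.index[presence.any(axis=1)]) - tissue_or_cond
    return SpecificitySets(anther_only, ovary_only, stress_only, control_only, shared)
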