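"""Raw FASTQ -> collapsed unique tags.

Adapter trimming, quality and size filtering, and per-library collapsing
of identical inserts into :class:`UniqueTag` records. These tags carry the
per-library raw counts that every downstream stage (contaminant removal,
catalog matching, hairpin discovery, differential expression) consumes,
and the surviving-read totals ("clean reads") that serve as normalization
denominators.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadRecord",
    "UniqueTag",
    "LibraryStats",
    "trim_adapter",
    "quality_filter",
    "size_filter",
    "collapse",
    "process_library",
    "TagTable",
]

MIN_TAG_LEN = 18
MAX_TAG_LEN = 24


@dataclass
class ReadRecord:
    """One sequencer read: identifier, bases, per-base Phred scores."""

    id: str
    seq: str
    qual: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id}: seq/qual length mismatch")


@dataclass
class UniqueTag:
    """A distinct 18-24 nt insert sequence with per-library raw counts."""

    seq: str
    counts: dict[str, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class LibraryStats:
    """Read-survival bookkeeping for one library.

    ``clean_reads`` is the total-clean-reads denominator used by the
    expression normalization downstream.
    """

    library_id: str
    raw_reads: int = 0
    clean_reads: int = 0
    unique_tags: int = 0


def trim_adapter(seq: str, adapter: str, min_overlap: int = 6) -> str | None:
    """Return the insert upstream of the left-most 3' adapter occurrence.

    The adapter is located by an exact prefix match: at candidate position
    ``i`` the read must match ``adapter[:k]`` where ``k`` extends to the end
    of the read or the full adapter, with ``k >= min_overlap``. Returns None
    when no adapter is found or the insert would be empty.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n, m = len(seq), len(adapter)
    for i in range(0, n - min_overlap + 1):
        k = min(m, n - i)
        if seq[i : i + k] == adapter[:k]:
            return seq[:i] if i > 0 else None
    return None


def quality_filter(insert: str, quals: Iterable[int], min_mean_q: float = 20.0) -> bool:
    """True iff mean Phred over the insert >= threshold and the insert is N-free."""
    if "N" in insert:
        return False
    qs = list(quals)
    if not qs:
        return False
    return sum(qs) / len(qs) >= min_mean_q


def size_filter(seq: str, min_len: int = MIN_TAG_LEN, max_len: int = MAX_TAG_LEN) -> bool:
    """True iff the insert length lies in [min_len, max_len], both inclusive."""
    return min_len <= len(seq) <= max_len


def collapse(inserts: Iterable[str], library_id: str, raw_reads: int | None = None
             ) -> tuple[dict[str, int], LibraryStats]:
    """Collapse clean inserts into distinct tag counts.

    Counts sum to ``clean_reads`` by construction; the result is invariant
    under permutation of the input stream.
    """
    counts = Counter(inserts)
    clean = sum(counts.values())
    stats = LibraryStats(
        library_id=library_id,
        raw_reads=clean if raw_reads is None else raw_reads,
        clean_reads=clean,
        unique_tags=len(counts),
    )
    return dict(counts), stats


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_clean_inserts(path: str | Path, adapter: str, *, min_overlap: int = 6,
                       min_mean_q: float = 20.0, min_len: int = MIN_TAG_LEN,
                       max_len: int = MAX_TAG_LEN) -> Iterator[str]:
    """Stream trimmed, quality- and size-filtered inserts from a FASTQ file."""
    with _open_maybe_gzip(path) as fh:
        for _title, seq, qual in FastqGeneralIterator(fh):
            seq = seq.upper()
            insert = trim_adapter(seq, adapter, min_overlap)
            if insert is None:
                continue
            quals = [ord(c) - 33 for c in qual[: len(insert)]]
            if not quality_filter(insert, quals, min_mean_q):
                continue
            if not size_filter(insert, min_len, max_len):
                continue
            yield insert


def process_library(path: str | Path, library_id: str, adapter: str, *,
                    min_overlap: int = 6, min_mean_q: float = 20.0,
                    min_len: int = MIN_TAG_LEN, max_len: int = MAX_TAG_LEN
                    ) -> tuple[dict[str, int], LibraryStats]:
    """Run trim -> quality -> size -> collapse on one FASTQ library."""
    raw = 0

    def _gen():
        nonlocal raw
        with _open_maybe_gzip(path) as fh:
            for _title, seq, qual in FastqGeneralIterator(fh):
                raw += 1
                seq = seq.upper()
                insert = trim_adapter(seq, adapter, min_overlap)
                if insert is None:
                    continue
                quals = [ord(c) - 33 for c in qual[: len(insert)]]
                if not quality_filter(insert, quals, min_mean_q):
                    continue
                if not size_filter(insert, min_len, max_len):
                    continue
                yield insert

    counts, stats = collapse(_gen(), library_id)
    stats.raw_reads = raw
    return counts, stats


class TagTable:
    """Unique tags across libraries with explicit zero counts.

    A tag observed in any library gets a count (possibly 0) in every
    library — required by the differential-expression zero-replacement
    rule downstream.
    """

    def __init__(self) -> None:
        self.counts: dict[str, dict[str, int]] = {}
        self.stats: dict[str, LibraryStats] = {}

    @property
    def library_ids(self) -> list[str]:
        return list(self.stats)

    def add_library(self, library_id: str, counts: dict[str, int],
                    stats: LibraryStats) -> None:
        self.stats[library_id] = stats
        for seq, c in counts.items():
            self.counts.setdefault(seq, {})[library_id] = c

    def tags(self) -> list[UniqueTag]:
        libs = self.library_ids
        return [
            UniqueTag(seq=s, counts={lib: per.get(lib, 0) for lib in libs})
            for s, per in sorted(self.counts.items())
        ]

    def totals(self) -> dict[str, int]:
        """Total clean reads per library (normalization denominators)."""
        return {lib: st.clean_reads for lib, st in self.stats.items()}

    def write_tsv(self, path: str | Path) -> None:
        libs = self.library_ids
        with open(path, "w") as fh:
            fh.write("seq\t" + "\t".join(libs) + "\n")
            for tag in self.tags():
                fh.write(tag.seq + "\t" + "\t".join(str(tag.counts[lib]) for lib in libs) + "\n")

    def write_stats_json(self, path: str | Path) -> None:
        payload = {
            lib: {"raw_reads": st.raw_reads, "clean_reads": st.clean_reads,
                  "unique_tags": st.unique_tags}
            for lib, st in self.stats.items()
        }
        Path(path).write_text(json.dumps(payload, indent=2))
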