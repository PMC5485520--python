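"""Read preprocessing: adapter trimming, filtering and tag collapsing.

Raw reads are trimmed of the 3' (and optionally 5') adapter, filtered by
length and alphabet, and collapsed into unique sequence tags carrying
per-library counts — the unit every later stage works with.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .seqtools import read_fastq_seqs, write_fasta

MIN_LEN = 18
MAX_LEN = 30
#: minimum 3'-adapter overlap required at the read end for trimming
MIN_ADAPTER_OVERLAP = 6

_VALID = set("ACGTN")


@dataclass
class UniqueTag:
    """A collapsed read sequence with per-library counts."""

    tag_id: str
    sequence: str
    counts: dict[str, int]

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class LibraryStats:
    """Per-library read accounting, mirroring the usual sequencing summary."""

    library_id: str
    total_reads: int = 0
    high_quality_reads: int = 0
    unique_reads: int = 0
    mapped_reads: int = 0
    unique_mapped: int = 0
    rejected_reads: int = 0

    def validate(self) -> None:
        assert self.total_reads == self.high_quality_reads + self.rejected_reads
        assert self.unique_reads <= self.high_quality_reads


def trim_adapter(read: str, adapter3: str = "", adapter5: str = "") -> str | None:
    """Remove adapter sequence from a read; ``None`` means the read is rejected.

    The 3' adapter is searched as its leftmost full occurrence, else as the
    longest adapter prefix (>= MIN_ADAPTER_OVERLAP nt, exact match) ending
    the read. A read reduced to nothing (adapter dimer) is rejected, as is
    any read containing characters outside A/C/G/T/N.
    """
    read = read.upper()
    if set(read) - _VALID:
        return None
    if adapter5:
        idx = read.find(adapter5.upper())
        if idx >= 0:
            read = read[idx + len(adapter5) :]
    if adapter3:
        adapter3 = adapter3.upper()
        idx = read.find(adapter3)
        if idx >= 0:
            read = read[:idx]
        else:
            for olap in range(min(len(adapter3) - 1, len(read)), MIN_ADAPTER_OVERLAP - 1, -1):
                if read.endswith(adapter3[:olap]):
                    read = read[: len(read) - olap]
                    break
    return read if read else None


def collapse_and_filter(
    reads_per_library: dict[str, list[str]],
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
) -> tuple[list[UniqueTag], dict[str, LibraryStats]]:
    """Collapse trimmed reads into unique tags with per-library counts.

    Reads shorter than ``min_len``, longer than ``max_len`` or containing N
    are rejected (counted per library, not fatal). Tags are ordered by
    descending total count (ties by sequence) and given serial ids.
    """
    counts: dict[str, Counter] = defaultdict(Counter)
    stats: dict[str, LibraryStats] = {}
    for lib, reads in reads_per_library.items():
        st = LibraryStats(library_id=lib)
        for read in reads:
            st.total_reads += 1
            if read is None or not (min_len <= len(read) <= max_len) or "N" in read:
                st.rejected_reads += 1
                continue
            st.high_quality_reads += 1
            counts[read.upper()][lib] += 1
        stats[lib] = st
    libs = list(reads_per_library)
    tags = [
        UniqueTag(tag_id="", sequence=seq, counts={lib: c[lib] for lib in libs if c[lib]})
        for seq, c in counts.items()
    ]
    tags.sort(key=lambda t: (-t.total_count, t.sequence))
    for i, tag in enumerate(tags):
        tag.tag_id = f"tag{i + 1}"
    for lib in libs:
        stats[lib].unique_reads = sum(1 for t in tags if t.counts.get(lib, 0) > 0)
        stats[lib].validate()
    return tags, stats


def preprocess_fastq(
    fastq_paths: dict[str, str | Path],
    adapter3: str = "",
    adapter5: str = "",
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
) -> tuple[list[UniqueTag], dict[str, LibraryStats]]:
    """FASTQ files -> trimmed, collapsed unique tags plus library stats."""
    trimmed = {
        lib: [trim_adapter(r, adapter3, adapter5) for r in read_fastq_seqs(path)]
        for lib, path in fastq_paths.items()
    }
    return collapse_and_filter(trimmed, min_len=min_len, max_len=max_len)


def length_distribution(tags: list[UniqueTag], by: str = "total") -> dict[int, int]:
    """Read-length histogram over tags, weighted by count (total) or not (unique)."""
    if by not in ("total", "unique"):
        raise ValueError("by must be 'total' or 'unique'")
    out: Counter = Counter()
    for tag in tags:
        out[len(tag.sequence)] += tag.total_count if by == "total" else 1
    return dict(sorted(out.items()))


def tags_to_fasta(tags: list[UniqueTag], path: str | Path) -> None:
    """Collapsed-tag FASTA with ``>tag{serial}_x{total_count}`` headers."""
    write_fasta(((f"{t.tag_id}_x{t.total_count}", t.sequence) for t in tags), path)


def tag_count_table(tags: list[UniqueTag], libraries: list[str]) -> pd.DataFrame:
    """Per-library tag count matrix (rows in tag-id order)."""
    data = {
        "tag_id": [t.tag_id for t in tags],
        "sequence": [t.sequence for t in tags],
    }
    for lib in libraries:
        data[lib] = [t.counts.get(lib, 0) for t in tags]
    return pd.DataFrame(data).set_index("tag_id")


def stats_table(stats: dict[str, LibraryStats]) -> pd.DataFrame:
    rows = [
        {
            "library": st.library_id,
            "total_reads": st.total_reads,
            "high_quality_reads": st.high_quality_reads,
            "unique_reads": st.unique_reads,
            "mapped_reads": st.mapped_reads,
            "unique_mapped": st.unique_mapped,
        }
        for st in stats.values()
    ]
    return pd.DataFrame(rows).set_index("library")
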