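"""Adapter trimming, 16-35 nt length filtering, and tag collapsing.

Reads are adapter-ligated inserts; the 3' adapter is located by its leftmost
seed match (a ``min_overlap``-long prefix of the adapter with at most
``max_mismatches`` substitutions), the insert is everything before it, and
reads with no detectable adapter are discarded as unligated read-through.
Surviving inserts are length-filtered to the inclusive [16, 35] window and
collapsed into unique tags with clone counts; the total clone count (sum of
all tag frequencies) is the library's normalization denominator.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from hypoxamir._seq import to_dna

NO_ADAPTER = None  # sentinel returned when no adapter seed is found


@dataclass
class TagLibrary:
    """Collapsed unique tags with read counts for one sample."""

    sample_id: str
    condition: str
    tags: dict[str, int] = field(default_factory=dict)

    @property
    def total_clone_count(self) -> int:
        return sum(self.tags.values())

    def __len__(self) -> int:
        return len(self.tags)


def trim_adapter3(
    read: str,
    adapter: str,
    min_overlap: int = 8,
    max_mismatches: int = 1,
) -> str | None:
    """Trim the 3' adapter; return the insert, or None when no adapter found.

    A position matches when the first ``min_overlap`` adapter bases align
    there with at most ``max_mismatches`` substitutions; the leftmost match
    wins, so the result is idempotent under re-trimming.  An empty read
    yields an empty insert (not an error).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    read = to_dna(read)
    if not read:
        return ""
    seed = to_dna(adapter[:min_overlap])
    for i in range(len(read) - min_overlap + 1):
        mm = 0
        for a, b in zip(read[i:i + min_overlap], seed):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        if mm <= max_mismatches:
            return read[:i]
    return NO_ADAPTER


def length_filter(
    seqs: Iterable[str], min_len: int = 16, max_len: int = 35
) -> Iterator[str]:
    """Keep sequences with length in [min_len, max_len], order preserved."""
    if min_len <= 0 or max_len <= 0 or min_len > max_len:
        raise ValueError("length bounds must be positive with min <= max")
    for s in seqs:
        if min_len <= len(s) <= max_len:
            yield s


def collapse_reads(
    seqs: Iterable[str], sample_id: str, condition: str
) -> TagLibrary:
    """Collapse a read stream into unique tags with clone counts."""
    counts = Counter()
    for s in seqs:
        if not s:
            raise ValueError("collapse_reads requires non-empty sequences")
        counts[to_dna(s)] += 1
    return TagLibrary(sample_id, condition, dict(counts))


@dataclass
class PreprocessStats:
    n_input: int = 0
    n_no_adapter: int = 0
    n_length_filtered: int = 0
    n_kept: int = 0


def preprocess_reads(
    reads: Iterable[str],
    sample_id: str,
    condition: str,
    adapter: str,
    min_overlap: int = 8,
    max_mismatches: int = 1,
    min_len: int = 16,
    max_len: int = 35,
) -> tuple[TagLibrary, PreprocessStats]:
    """Full preprocessing: trim, length-filter, collapse, with accounting."""
    stats = PreprocessStats()
    kept: list[str] = []
    for read in reads:
        stats.n_input += 1
        insert = trim_adapter3(read, adapter, min_overlap, max_mismatches)
        if insert is NO_ADAPTER:
            stats.n_no_adapter += 1
            continue
        if min_len <= len(insert) <= max_len:
            kept.append(insert)
        else:
            stats.n_length_filtered += 1
    stats.n_kept = len(kept)
    lib = collapse_reads(kept, sample_id, condition)
    return lib, stats


def read_fastq_sequences(path: str | Path) -> Iterator[str]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield str(rec.seq)


def preprocess_fastq(
    path: str | Path, sample_id: str, condition: str, adapter: str, **kwargs
) -> tuple[TagLibrary, PreprocessStats]:
    return preprocess_reads(
        read_fastq_sequences(path), sample_id, condition, adapter, **kwargs
    )


def write_tags_fasta(lib: TagLibrary, path: str | Path) -> None:
    """Collapsed tags as FASTA with ``>tag_<i>_x<count>`` headers."""
    items = sorted(lib.tags.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(items):
            fh.write(f">tag_{i + 1}_x{count}\n{seq}\n")


def read_tags_tsv(
    path: str | Path, sample_id: str, condition: str
) -> TagLibrary:
    tags = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("tag\t"):
            raise ValueError(f"{path}: expected a 'tag<TAB>count' table")
        for line in fh:
            seq, count = line.split()
            tags[seq] = int(count)
    return TagLibrary(sample_id, condition, tags)


def write_tags_tsv(lib: TagLibrary, path: str | Path) -> None:
    items = sorted(lib.tags.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "w") as fh:
        fh.write("tag\tcount\n")
        for seq, count in items:
            fh.write(f"{seq}\t{count}\n")
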