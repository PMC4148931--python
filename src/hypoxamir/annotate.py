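"""Hierarchical elimination annotation of small-RNA tags.

Tags are matched, in a fixed stage order, against mature miRNAs (exact,
U/T-insensitive), other ncRNAs, piRNAs, an rRNA/mRNA collection, and the
genome (exonic before intergenic/intronic); the first matching stage claims
the tag.  Matching is ungapped substring alignment counting Hamming
mismatches only — indels in 16-35 nt tags are indistinguishable from isomiR
end variation, so they are deliberately not modelled.  Transcript databases
are searched on the forward strand; the genome on both strands.  Tags left
with an exact intergenic/intronic placement are the input to novel-hairpin
discovery: each is extracted with 70 nt of flanking genome on either side
as a potential precursor window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hypoxamir._seq import revcomp, to_dna
from hypoxamir.errors import ConfigurationError
from hypoxamir.preprocess import TagLibrary
from hypoxamir.synthetic import ReferenceBundle

CLASSES = (
    "mature_miRNA",
    "ncRNA",
    "piRNA",
    "rna_db",
    "exon",
    "intergenic_intronic",
    "unassigned",
)


@dataclass
class TagAnnotation:
    tag: str
    count: int
    class_: str
    ref_name: str | None = None
    mismatches: int | None = None
    contig: str | None = None
    start: int | None = None  # 0-based half-open on the reference
    end: int | None = None
    strand: str | None = None
    all_hits: list[str] = field(default_factory=list)


@dataclass
class AnnotationTable:
    """One record per tag; each tag belongs to exactly one class."""

    records: dict[str, TagAnnotation]

    def by_class(self, class_: str) -> list[TagAnnotation]:
        return [r for r in self.records.values() if r.class_ == class_]

    def class_read_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CLASSES}
        for r in self.records.values():
            out[r.class_] += r.count
        return out

    def class_read_percentages(self) -> dict[str, float]:
        counts = self.class_read_counts()
        total = sum(counts.values())
        if total == 0:
            return {c: 0.0 for c in CLASSES}
        return {c: 100.0 * n / total for c, n in counts.items()}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class _SeqIndex:
    """Sliding-window Hamming search against one long sequence."""

    def __init__(self, seq: str):
        self.seq = seq
        self.arr = _encode(seq)
        self._windows: dict[int, np.ndarray] = {}

    def windows(self, k: int) -> np.ndarray | None:
        if len(self.arr) < k:
            return None
        if k not in self._windows:
            self._windows[k] = np.lib.stride_tricks.sliding_window_view(
                self.arr, k
            )
        return self._windows[k]

    def find_exact(self, tag: str) -> list[int]:
        """All exact-match starts, ascending (str.find fast path)."""
        out = []
        i = self.seq.find(tag)
        while i >= 0:
            out.append(i)
            i = self.seq.find(tag, i + 1)
        return out

    def search(self, tag: str, max_mm: int) -> list[tuple[int, int]]:
        """All (start, mismatches) with mismatches <= max_mm, start ascending."""
        if max_mm == 0:
            return [(i, 0) for i in self.find_exact(tag)]
        w = self.windows(len(tag))
        if w is None:
            return []
        mm = (w != _encode(tag)).sum(axis=1)
        idx = np.nonzero(mm <= max_mm)[0]
        return [(int(i), int(mm[i])) for i in idx]


def match_exact_mature(
    lib: TagLibrary, mature_set: dict[str, str]
) -> AnnotationTable:
    """Assign tags equal (U/T-insensitive) to a mature sequence; no mismatch.

    Tags identical to several mature entries are assigned to the
    lexicographically first name, with all hits recorded.
    """
    if not mature_set:
        raise ValueError("mature set is empty")
    by_seq: dict[str, list[str]] = {}
    for name in sorted(mature_set):
        by_seq.setdefault(to_dna(mature_set[name]), []).append(name)
    records = {}
    for tag, count in lib.tags.items():
        hits = by_seq.get(to_dna(tag))
        if hits:
            records[tag] = TagAnnotation(
                tag, count, "mature_miRNA", ref_name=hits[0], mismatches=0,
                all_hits=list(hits),
            )
        else:
            records[tag] = TagAnnotation(tag, count, "unassigned")
    return AnnotationTable(records)


def _best_db_hit(
    tag: str, indexes: dict[str, _SeqIndex], max_mm: int
) -> TagAnnotation | None:
    """Best forward-strand hit across a transcript database.

    Preference: fewest mismatches, then lexicographic reference name, then
    leftmost position — a fixed deterministic order.  Exact matches are
    located first with plain substring search; the mismatch scan only runs
    when no entry contains the tag verbatim.  ``all_hits`` records the
    references hit at the winning mismatch tier.
    """
    exact = [
        (0, name, indexes[name].find_exact(tag)[0])
        for name in sorted(indexes)
        if tag in indexes[name].seq
    ]
    hits = exact
    if not hits and max_mm > 0:
        hits = []
        for name in sorted(indexes):
            for start, mm in indexes[name].search(tag, max_mm):
                hits.append((mm, name, start))
        hits.sort()
    if not hits:
        return None
    best_mm = hits[0][0]
    mm, name, start = hits[0]
    return TagAnnotation(
        tag, 0, "", ref_name=name, mismatches=mm,
        start=start, end=start + len(tag), strand="+",
        all_hits=sorted({h[1] for h in hits if h[0] == best_mm}),
    )


def _genome_hits(
    tag: str, genome_idx: dict[str, _SeqIndex], max_mm: int
) -> list[tuple[int, str, int, str]]:
    """All genomic hits as (mismatches, contig, plus-strand start, strand).

    Exact occurrences short-circuit the sliding-window mismatch scan: when
    a tag is present verbatim the 0-mismatch tier is the winning tier, so
    mismatched placements cannot change the assignment.
    """
    rc = revcomp(tag)
    out = []
    for contig in sorted(genome_idx):
        idx = genome_idx[contig]
        out.extend((0, contig, s, "+") for s in idx.find_exact(tag))
        out.extend((0, contig, s, "-") for s in idx.find_exact(rc))
    if not out and max_mm > 0:
        for contig in sorted(genome_idx):
            idx = genome_idx[contig]
            for start, mm in idx.search(tag, max_mm):
                out.append((mm, contig, start, "+"))
            for start, mm in idx.search(rc, max_mm):
                out.append((mm, contig, start, "-"))
    out.sort()
    return out


def eliminate_hierarchy(
    lib: TagLibrary,
    ref: ReferenceBundle,
    max_mismatches: int = 2,
) -> AnnotationTable:
    """Run the full elimination hierarchy over a tag library.

    Stage order: mature (0 mismatches) -> ncRNA -> piRNA -> rna_db ->
    exon -> intergenic/intronic; the first matching stage wins.  Genomic
    hits overlapping an annotated exon claim the exon stage.
    """
    for attr in ("other_ncrna", "pirnas", "rna_db", "genome"):
        if getattr(ref, attr, None) is None:
            raise ConfigurationError(f"reference bundle missing {attr}")
    mature_table = match_exact_mature(lib, ref.mature_mirnas)
    db_stages = [
        ("ncRNA", {n: _SeqIndex(to_dna(s)) for n, s in ref.other_ncrna.items()}),
        ("piRNA", {n: _SeqIndex(to_dna(s)) for n, s in ref.pirnas.items()}),
        ("rna_db", {n: _SeqIndex(to_dna(s)) for n, s in ref.rna_db.items()}),
    ]
    genome_idx = {c: _SeqIndex(to_dna(s)) for c, s in ref.genome.items()}
    # the exon stage is its own sequence database (slices of the genome),
    # searched on both strands like the genomic stage
    exon_idx = [
        (c, s, _SeqIndex(to_dna(ref.genome[c][s:e])))
        for c, s, e, _strand in sorted(ref.exon_annotation)
    ]

    def exon_hits(tag: str) -> list[tuple[int, str, int, str]]:
        rc = revcomp(tag)
        out = []
        for contig, offset, idx in exon_idx:
            for query, strand in ((tag, "+"), (rc, "-")):
                for start, mm in idx.search(query, max_mismatches):
                    out.append((mm, contig, offset + start, strand))
        out.sort()
        return out

    records = {}
    for tag, count in lib.tags.items():
        rec = mature_table.records[tag]
        if rec.class_ == "mature_miRNA":
            records[tag] = rec
            continue
        assigned = None
        for stage_name, indexes in db_stages:
            hit = _best_db_hit(to_dna(tag), indexes, max_mismatches)
            if hit is not None:
                hit.tag, hit.count, hit.class_ = tag, count, stage_name
                assigned = hit
                break
        if assigned is None:
            for class_, hits in (
                ("exon", exon_hits(to_dna(tag))),
                ("intergenic_intronic",
                 _genome_hits(to_dna(tag), genome_idx, max_mismatches)),
            ):
                if hits:
                    mm, contig, start, strand = hits[0]
                    best_mm = hits[0][0]
                    assigned = TagAnnotation(
                        tag, count, class_,
                        ref_name=contig, mismatches=mm, contig=contig,
                        start=start, end=start + len(tag), strand=strand,
                        all_hits=[
                            f"{h[1]}:{h[2]}:{h[3]}"
                            for h in hits if h[0] == best_mm
                        ],
                    )
                    break
        records[tag] = assigned or TagAnnotation(tag, count, "unassigned")
    return AnnotationTable(records)


@dataclass
class HairpinCandidate:
    """A potential precursor window: tag plus flanking genome, strand-oriented."""

    candidate_id: str
    tag: str
    count: int
    contig: str
    start: int  # window interval, 0-based half-open, plus-strand coordinates
    end: int
    strand: str
    sequence: str  # strand-oriented window sequence
    tag_offset: int  # tag start within `sequence`

    @property
    def tag_interval(self) -> tuple[int, int]:
        return (self.tag_offset, self.tag_offset + len(self.tag))


def extract_genomic_candidates(
    table: AnnotationTable,
    genome: dict[str, str],
    flank: int = 70,
    require_exact: bool = True,
) -> list[HairpinCandidate]:
    """Extract intergenic/intronic tags with flanking genome as candidates.

    Only exact (0-mismatch) placements are extended by default, since the
    candidate's mature sequence is the tag itself.  Windows are truncated at
    contig bounds; minus-strand windows are reverse-complemented so the tag
    is always a forward substring of the window.
    """
    out = []
    recs = sorted(
        table.by_class("intergenic_intronic"),
        key=lambda r: (r.contig, r.start, r.strand, r.tag),
    )
    for i, rec in enumerate(recs):
        if require_exact and rec.mismatches != 0:
            continue
        contig_seq = to_dna(genome[rec.contig])
        ws = max(0, rec.start - flank)
        we = min(len(contig_seq), rec.end + flank)
        window = contig_seq[ws:we]
        if rec.strand == "+":
            offset = rec.start - ws
        else:
            window = revcomp(window)
            offset = we - rec.end
        out.append(
            HairpinCandidate(
                candidate_id=f"cand_{i + 1}",
                tag=to_dna(rec.tag),
                count=rec.count,
                contig=rec.contig,
                start=ws,
                end=we,
                strand=rec.strand,
                sequence=window,
                tag_offset=offset,
            )
        )
    return out


def write_annotation_tsv(table: AnnotationTable, path: str | Path) -> None:
    """Annotation table as TSV; genomic coordinates 1-based inclusive."""
    recs = sorted(
        table.records.values(), key=lambda r: (-r.count, r.tag)
    )
    with open(path, "w") as fh:
        fh.write("tag\tcount\tclass\tref\tmismatches\tcontig\tstart\tend\tstrand\n")
        for r in recs:
            start = "" if r.start is None else str(r.start + 1)
            end = "" if r.end is None else str(r.end)
            fh.write(
                f"{r.tag}\t{r.count}\t{r.class_}\t{r.ref_name or ''}\t"
                f"{'' if r.mismatches is None else r.mismatches}\t"
                f"{r.contig or ''}\t{start}\t{end}\t{r.strand or ''}\n"
            )
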