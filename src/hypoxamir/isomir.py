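"""IsomiR grouping: end-variant tags anchored to a precursor.

An isomiR differs from the representative mature sequence by a few
nucleotides at its 5' and/or 3' end — templated shifts within the
precursor, optionally followed by a short non-templated 3' addition.
Tags join a precursor's group when their maximal precursor-matching
prefix aligns within +/-3 nt of the mature anchor's 5' end, the 3'
templated offset is within +/-4 nt, and at most 2 trailing nucleotides
are untemplated.  The representative is the variant with the highest
read count (ties broken lexicographically).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from hypoxamir._seq import to_dna
from hypoxamir.errors import ReferenceLookupError
from hypoxamir.preprocess import TagLibrary


@dataclass
class IsomirVariant:
    sequence: str
    offset5: int  # positive = 5' end trimmed relative to the anchor
    offset3: int  # positive = 3' end extended relative to the anchor
    nta_suffix: str  # non-templated 3' nucleotides
    counts: dict[str, int] = field(default_factory=dict)  # condition -> reads

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class IsomirGroup:
    precursor_name: str
    anchor: str
    variants: list[IsomirVariant] = field(default_factory=list)

    @property
    def representative(self) -> IsomirVariant | None:
        if not self.variants:
            return None
        return min(self.variants, key=lambda v: (-v.total_count, v.sequence))

    @property
    def total_count(self) -> int:
        return sum(v.total_count for v in self.variants)


def _align_to_anchor(
    tag: str,
    precursor: str,
    anchor_start: int,
    anchor_end: int,
    max_offset5: int,
    max_offset3: int,
    max_nta: int,
) -> tuple[int, int, str] | None:
    """Place a tag on the precursor near the anchor.

    Tries 5' offsets in ascending |offset| order (ties: negative first) and
    keeps the placement whose templated prefix is longest; returns
    (offset5, offset3, nta_suffix) or None when the tag does not qualify.
    """
    best = None
    offsets = sorted(
        range(-max_offset5, max_offset5 + 1), key=lambda d: (abs(d), d)
    )
    for d5 in offsets:
        start = anchor_start + d5
        if start < 0 or start >= len(precursor):
            continue
        # longest common prefix of tag and precursor[start:]
        lcp = 0
        for a, b in zip(tag, precursor[start:]):
            if a != b:
                break
            lcp += 1
        suffix = tag[lcp:]
        if lcp == 0 or len(suffix) > max_nta:
            continue
        d3 = (start + lcp) - anchor_end
        if abs(d3) > max_offset3:
            continue
        if best is None or lcp > best[0]:
            best = (lcp, d5, d3, suffix)
    if best is None:
        return None
    _, d5, d3, suffix = best
    return d5, d3, suffix


def group_isomirs(
    lib: TagLibrary,
    precursor: str,
    anchor: str,
    precursor_name: str = "precursor",
    max_offset5: int = 3,
    max_offset3: int = 4,
    max_nta: int = 2,
    exclude: set[str] | None = None,
) -> IsomirGroup:
    """Collect one condition's end variants of ``anchor`` on ``precursor``.

    ``exclude`` holds exact mature sequences of *other* miRNAs: a tag
    identical to another annotated mature is claimed by that annotation and
    never treated as an isomiR here.
    """
    precursor = to_dna(precursor)
    anchor = to_dna(anchor)
    astart = precursor.find(anchor)
    if astart < 0:
        raise ReferenceLookupError("anchor is not a substring of the precursor")
    aend = astart + len(anchor)
    exclude = {to_dna(s) for s in (exclude or set())} - {anchor}
    group = IsomirGroup(precursor_name, anchor)
    for tag in sorted(lib.tags):
        seq = to_dna(tag)
        if seq in exclude:
            continue
        placed = _align_to_anchor(
            seq, precursor, astart, aend, max_offset5, max_offset3, max_nta
        )
        if placed is None:
            continue
        d5, d3, suffix = placed
        group.variants.append(
            IsomirVariant(
                seq, d5, d3, suffix, counts={lib.condition: lib.tags[tag]}
            )
        )
    group.variants.sort(key=lambda v: (v.offset5, v.offset3, v.sequence))
    return group


def merge_groups(groups: list[IsomirGroup]) -> IsomirGroup:
    """Merge per-condition groups of the same precursor into one catalog."""
    if not groups:
        raise ValueError("nothing to merge")
    names = {g.precursor_name for g in groups}
    if len(names) > 1:
        raise ValueError("groups belong to different precursors")
    merged = IsomirGroup(groups[0].precursor_name, groups[0].anchor)
    by_seq: dict[str, IsomirVariant] = {}
    for g in groups:
        for v in g.variants:
            if v.sequence not in by_seq:
                by_seq[v.sequence] = IsomirVariant(
                    v.sequence, v.offset5, v.offset3, v.nta_suffix, {}
                )
            for cond, c in v.counts.items():
                tgt = by_seq[v.sequence].counts
                tgt[cond] = tgt.get(cond, 0) + c
    merged.variants = sorted(
        by_seq.values(), key=lambda v: (v.offset5, v.offset3, v.sequence)
    )
    return merged


def isomir_condition_summary(
    groups_by_condition: dict[str, list[IsomirGroup]]
) -> pd.DataFrame:
    """Per-condition species/singleton/read totals across a precursor set.

    A species is expressed in a condition when its count there is nonzero;
    a singleton has exactly one read.  The union row counts species seen in
    any condition.
    """
    rows = []
    union: set[tuple[str, str]] = set()
    for cond in sorted(groups_by_condition):
        species = 0
        singletons = 0
        reads = 0
        for g in groups_by_condition[cond]:
            for v in g.variants:
                c = v.counts.get(cond, 0)
                if c >= 1:
                    species += 1
                    union.add((g.precursor_name, v.sequence))
                    reads += c
                    if c == 1:
                        singletons += 1
        rows.append(
            {"condition": cond, "species": species, "singletons": singletons,
             "reads": reads}
        )
    rows.append(
        {"condition": "union", "species": len(union), "singletons": pd.NA,
         "reads": pd.NA}
    )
    return pd.DataFrame(rows, columns=["condition", "species", "singletons", "reads"])


def write_isomir_catalog(
    groups: list[IsomirGroup], path: str | Path, conditions: list[str]
) -> None:
    with open(path, "w") as fh:
        cols = "\t".join(f"reads_{c}" for c in conditions)
        fh.write(f"precursor\tsequence\toffset5\toffset3\tnta\t{cols}\trepresentative\n")
        for g in sorted(groups, key=lambda g: g.precursor_name):
            rep = g.representative
            for v in g.variants:
                counts = "\t".join(
                    str(v.counts.get(c, 0)) for c in conditions
                )
                fh.write(
                    f"{g.precursor_name}\t{v.sequence}\t{v.offset5}\t"
                    f"{v.offset3}\t{v.nta_suffix or '.'}\t{counts}\t"
                    f"{int(rep is not None and v.sequence == rep.sequence)}\n"
                )
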