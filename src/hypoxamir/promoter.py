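"""Promoter extraction and hypoxia response element (HRE) scanning.

Hypoxia-inducible factor binds the core consensus RCGTG (R = A/G).  For
each pre-miRNA the 5 kb upstream of its 5' end is extracted strand-aware
(truncated at contig bounds) and scanned for the motif on both strands,
overlaps allowed.  Hit positions are reported as negative offsets relative
to the precursor 5' end: -1 is the base immediately upstream.  The motif
is configurable as any IUPAC string so a matrix-based scanner can be
slotted in behind the same interface.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from hypoxamir._seq import iupac_regex, revcomp, revcomp_iupac, to_dna
from hypoxamir.synthetic import Precursor

DEFAULT_MOTIF = "RCGTG"


@dataclass(frozen=True)
class PromoterSequence:
    mirna: str
    sequence: str  # strand-oriented upstream sequence, 5'->3'
    span: int  # requested span (actual length may be truncated)

    def offset_of(self, index: int) -> int:
        """Signed upstream offset of a promoter position (-1 = adjacent)."""
        return index - len(self.sequence)


@dataclass(frozen=True)
class HREHit:
    mirna: str
    offset: int  # offset of the motif's leftmost promoter base, in [-span, -1]
    strand: str  # strand of the motif match relative to the promoter
    matched: str  # the matched bases, promoter orientation


def extract_upstream(
    locus: Precursor, genome: dict[str, str], span: int = 5000
) -> PromoterSequence:
    """Strand-aware upstream span of a precursor's 5' end.

    Plus strand: [start - span, start); minus strand: reverse complement of
    (end, end + span].  Truncated at contig bounds.
    """
    contig = to_dna(genome[locus.contig])
    if locus.start < 0 or locus.end > len(contig) or locus.start >= locus.end:
        raise ValueError(f"locus off contig: {locus}")
    if locus.strand == "+":
        seq = contig[max(0, locus.start - span):locus.start]
    else:
        seq = revcomp(contig[locus.end:min(len(contig), locus.end + span)])
    name = getattr(locus, "name", "") or ""
    return PromoterSequence(name, seq, span)


def scan_hre(
    promoter: PromoterSequence | str,
    motif: str = DEFAULT_MOTIF,
    mirna: str | None = None,
) -> list[HREHit]:
    """All motif matches (both strands, overlapping) in ascending offset."""
    if isinstance(promoter, str):
        promoter = PromoterSequence(mirna or "", to_dna(promoter), len(promoter))
    seq = to_dna(promoter.sequence)
    name = mirna if mirna is not None else promoter.mirna
    hits = []
    for strand, pattern in (("+", motif), ("-", revcomp_iupac(motif))):
        rx = re.compile(f"(?=({iupac_regex(pattern)}))")
        for m in rx.finditer(seq):
            hits.append(
                HREHit(name, promoter.offset_of(m.start()), strand, m.group(1))
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_mirna_hres(
    precursors: dict[str, Precursor],
    genome: dict[str, str],
    mirnas: list[str] | None = None,
    span: int = 5000,
    motif: str = DEFAULT_MOTIF,
) -> pd.DataFrame:
    """HRE hits for a set of precursors as a tidy table."""
    rows = []
    for name in sorted(mirnas if mirnas is not None else precursors):
        prom = extract_upstream(precursors[name], genome, span)
        for h in scan_hre(prom, motif, mirna=name):
            rows.append(
                {"mirna": name, "offset": h.offset, "strand": h.strand,
                 "motif": h.matched}
            )
    return pd.DataFrame(rows, columns=["mirna", "offset", "strand", "motif"])


def write_hre_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_hre_bed(
    table: pd.DataFrame,
    precursors: dict[str, Precursor],
    path: str | Path,
    motif_len: int = 5,
) -> None:
    """Hits as BED (0-based half-open) in genome coordinates."""
    with open(path, "w") as fh:
        for _, row in table.iterrows():
            p = precursors[row["mirna"]]
            if p.strand == "+":
                start = p.start + int(row["offset"])
            else:
                start = p.end - int(row["offset"]) - motif_len
            fh.write(
                f"{p.contig}\t{start}\t{start + motif_len}\t"
                f"{row['mirna']}_HRE\t0\t{row['strand']}\n"
            )
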