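"""Seed-match target sites and the >=3-of-N prediction consensus.

The canonical seed taxonomy classifies 3'UTR sites by their match to the
miRNA seed (nucleotides 2-7/2-8) and the presence of an adenine opposite
miRNA position 1: 8mer > 7mer-m8 > 7mer-A1 > 6mer, mutually exclusive per
locus.  External prediction programs are not re-implemented; their outputs
enter as named gene sets and the combining rule keeps genes supported by
at least ``min_support`` sources.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from hypoxamir._seq import revcomp, to_dna, to_rna
from hypoxamir.errors import ConfigurationError

SITE_PRIORITY = ("8mer", "7mer-m8", "7mer-A1", "6mer")


@dataclass(frozen=True)
class SeedSite:
    utr_id: str
    site_type: str
    start: int  # 1-based position of the matched subsequence in the UTR
    matched: str


def find_seed_sites(
    utr: str, mirna: str, utr_id: str = "utr"
) -> list[SeedSite]:
    """Canonical seed-match sites of a miRNA in a 3'UTR.

    Scans for the reverse complement of the seed 6mer (miRNA 2-7); each
    locus is then upgraded by an m8 match (UTR base pairing miRNA position
    8) and/or an A across from position 1, and classified once by priority.
    """
    mirna = to_rna(mirna)
    if len(mirna) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    utr = to_dna(utr)
    if len(utr) < 6:
        return []
    seed6 = to_dna(mirna[1:7])
    core = revcomp(seed6)  # matches miRNA 2-7
    m8 = revcomp(to_dna(mirna[7]))  # UTR base pairing miRNA position 8
    sites = []
    for p in range(len(utr) - 5):
        if utr[p:p + 6] != core:
            continue
        has_m8 = p >= 1 and utr[p - 1] == m8
        has_a1 = p + 6 < len(utr) and utr[p + 6] == "A"
        if has_m8 and has_a1:
            site_type, start, length = "8mer", p - 1, 8
        elif has_m8:
            site_type, start, length = "7mer-m8", p - 1, 7
        elif has_a1:
            site_type, start, length = "7mer-A1", p, 7
        else:
            site_type, start, length = "6mer", p, 6
        sites.append(
            SeedSite(utr_id, site_type, start + 1, utr[start:start + length])
        )
    return sites


@dataclass(frozen=True)
class ConsensusTarget:
    gene: str
    sources: tuple[str, ...]
    support: int


def consensus_targets(
    prediction_sets: dict[str, set[str]], min_support: int = 3
) -> list[ConsensusTarget]:
    """Genes supported by >= min_support sources, support-descending.

    Mirrors the rule of keeping only targets predicted by at least three
    of the available prediction programs.
    """
    if min_support < 1:
        raise ConfigurationError("min_support must be >= 1")
    if min_support > len(prediction_sets):
        raise ConfigurationError(
            f"min_support={min_support} exceeds the {len(prediction_sets)} "
            "supplied sources"
        )
    support: dict[str, list[str]] = {}
    for source in sorted(prediction_sets):
        for gene in prediction_sets[source]:
            support.setdefault(gene, []).append(source)
    out = [
        ConsensusTarget(gene, tuple(sources), len(sources))
        for gene, sources in support.items()
        if len(sources) >= min_support
    ]
    out.sort(key=lambda t: (-t.support, t.gene))
    return out


def read_prediction_sets(paths: dict[str, str | Path]) -> dict[str, set[str]]:
    """Load one-gene-per-line files into named prediction sets."""
    out = {}
    for source, path in paths.items():
        with open(path) as fh:
            out[source] = {
                line.strip() for line in fh if line.strip()
            }
    return out


def write_consensus_tsv(
    targets: list[ConsensusTarget], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tsupport\tsources\n")
        for t in targets:
            fh.write(f"{t.gene}\t{t.support}\t{','.join(t.sources)}\n")
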