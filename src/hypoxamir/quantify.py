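"""TPM/RPKM normalization, fold-change differential calling, cluster
co-regulation and correlation statistics.

TPM here is "transcript parts per million" over a small-RNA library: a
tag's read count divided by the library's total clone count, times 10^6.
RPKM (as used for mature miRNAs) is TPM divided by the mature length in
nucleotides, so RPKM * L == TPM exactly and fold changes are identical
under either normalization (the length cancels).  Differential expression
uses a minimum fold-change threshold of 1.5, strict: FC > 1.5 is up,
FC < 1/1.5 is down, anything else (including equality) is unchanged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from hypoxamir.errors import UndefinedLibraryError
from hypoxamir.preprocess import TagLibrary
from hypoxamir.synthetic import Precursor

FOLD_CHANGE_THRESHOLD = 1.5


def normalize_tpm(count: int, total_clone_count: int) -> float:
    """Reads per million of library clone count."""
    if total_clone_count <= 0:
        raise UndefinedLibraryError("library has zero total clone count")
    if count < 0 or count > total_clone_count:
        raise ValueError("count must lie in [0, total_clone_count]")
    return count / total_clone_count * 1e6


def normalize_rpkm(tpm: float, length: int) -> float:
    """TPM per nucleotide of mature length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return tpm / length


def compute_fold_change(
    count_h: int,
    total_h: int,
    count_n: int,
    total_n: int,
    pseudocount: int = 1,
) -> float:
    """Hypoxic/normoxic TPM ratio.

    The pseudocount is added to both raw counts only when either is zero,
    keeping reported TPM exact for abundant species while giving
    condition-specific species a finite fold.  Swapping conditions yields
    the reciprocal.
    """
    s = pseudocount if (count_h == 0 or count_n == 0) else 0
    return normalize_tpm(count_h + s, total_h) / normalize_tpm(
        count_n + s, total_n
    )


@dataclass
class DifferentialRecord:
    mirna: str
    fold_change: float
    direction: str  # up / down / unchanged
    threshold: float = FOLD_CHANGE_THRESHOLD


def _direction(fc: float, threshold: float) -> str:
    if fc > threshold:
        return "up"
    if fc < 1.0 / threshold:
        return "down"
    return "unchanged"


def expression_table(
    lib: TagLibrary,
    mature_assignments: dict[str, str],
    mature_lengths: dict[str, int],
) -> pd.DataFrame:
    """Per-miRNA raw count, TPM and RPKM for one library.

    ``mature_assignments`` maps tag sequence -> miRNA name (the exact-match
    stage of the annotation); the TPM denominator is the library's full
    total clone count, so the sum of TPM over *all* tags of the library is
    10^6 while the miRNA subset sums to less.
    """
    total = lib.total_clone_count
    counts: dict[str, int] = {}
    for tag, name in mature_assignments.items():
        counts[name] = counts.get(name, 0) + lib.tags.get(tag, 0)
    rows = []
    for name in sorted(mature_lengths):
        c = counts.get(name, 0)
        tpm = normalize_tpm(c, total) if total > 0 else 0.0
        length = mature_lengths[name]
        rows.append(
            {
                "mirna": name,
                "count": c,
                "tpm": tpm,
                "rpkm": normalize_rpkm(tpm, length),
                "length": length,
            }
        )
    return pd.DataFrame(rows, columns=["mirna", "count", "tpm", "rpkm", "length"])


def call_differential(
    counts_h: dict[str, int],
    total_h: int,
    counts_n: dict[str, int],
    total_n: int,
    threshold: float = FOLD_CHANGE_THRESHOLD,
    pseudocount: int = 1,
) -> list[DifferentialRecord]:
    """Fold-change DE calls, sorted by |log FC| descending (ties by name)."""
    names = sorted(set(counts_h) | set(counts_n))
    records = [
        DifferentialRecord(
            name,
            compute_fold_change(
                counts_h.get(name, 0), total_h, counts_n.get(name, 0), total_n,
                pseudocount,
            ),
            "",
            threshold,
        )
        for name in names
    ]
    for r in records:
        r.direction = _direction(r.fold_change, threshold)
    records.sort(key=lambda r: (-abs(math.log(r.fold_change)), r.mirna))
    return records


@dataclass
class ClusterSummary:
    cluster: str
    members: list[str]
    n_up: int
    n_down: int
    co_regulated: bool  # >=1 regulated member and all share one direction


def cluster_coregulation(
    de: list[DifferentialRecord], clusters: dict[str, list[str]]
) -> list[ClusterSummary]:
    by_name = {r.mirna: r for r in de}
    out = []
    for cid in sorted(clusters):
        dirs = []
        members = []
        for m in clusters[cid]:
            if m not in by_name:
                warnings.warn(f"cluster {cid}: {m} absent from DE table; skipped")
                continue
            members.append(m)
            dirs.append(by_name[m].direction)
        n_up = dirs.count("up")
        n_down = dirs.count("down")
        co = (n_up + n_down) > 0 and (n_up == 0 or n_down == 0)
        out.append(ClusterSummary(cid, members, n_up, n_down, co))
    return out


def derive_clusters(
    precursors: dict[str, Precursor], max_gap: int = 10_000
) -> dict[str, list[str]]:
    """Group precursors within ``max_gap`` on the same strand and contig.

    This is the miRBase-style genomic-cluster convention; chains are built
    along each contig/strand so consecutive members < max_gap apart join.
    """
    out: dict[str, list[str]] = {}
    by_key: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for name, p in precursors.items():
        by_key.setdefault((p.contig, p.strand), []).append((p.start, name))
    cid = 0
    for key in sorted(by_key):
        loci = sorted(by_key[key])
        chain = [loci[0]]
        for s, name in loci[1:]:
            if s - chain[-1][0] <= max_gap:
                chain.append((s, name))
            else:
                if len(chain) > 1:
                    cid += 1
                    out[f"cluster-{cid}"] = [n for _, n in chain]
                chain = [(s, name)]
        if len(chain) > 1:
            cid += 1
            out[f"cluster-{cid}"] = [n for _, n in chain]
    return out


def pearson_correlation(x, y) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def write_differential_tsv(
    records: list[DifferentialRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tfold_change\tdirection\tthreshold\n")
        for r in records:
            fh.write(
                f"{r.mirna}\t{r.fold_change:.4f}\t{r.direction}\t"
                f"{r.threshold:.4f}\n"
            )


def write_expression_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.4f")
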