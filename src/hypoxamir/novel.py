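"""Novel miRNA discovery: hairpin folding and stem-placement filtering.

Candidate precursor windows (intergenic tags with 70 nt flanks) are folded
with a weighted base-pair maximization DP (GC=3, AU=2, GU=1; minimum
hairpin loop 3; nested structures only).  The full thermodynamic nearest-
neighbour model is out of scope by design: the weighted DP preserves the
stem/loop geometry decisions the downstream filter needs.

A candidate passes when the mature tag sits on the stem of a clean
hairpin: the structure must carry exactly one terminal loop of moderate
size, the mature must not intersect that loop, the weighted pair score
must clear a floor, and most mature positions must be paired.  Because a
162 nt genomic window folds flanking sequence into incidental structure,
the filter is applied to the mature's stem-loop unit: the subsequence
under the innermost base pair enclosing the mature, re-folded in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hypoxamir import isomir
from hypoxamir._seq import to_rna
from hypoxamir.annotate import HairpinCandidate
from hypoxamir.preprocess import TagLibrary

PAIR_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}
MIN_LOOP = 3  # minimum unpaired span closed by a pair


@dataclass
class SecondaryStructure:
    sequence: str  # RNA
    dotbracket: str
    score: int  # total weighted pair score
    pairs: list[tuple[int, int]]  # (i, j), i < j, 0-based

    @property
    def paired(self) -> list[bool]:
        flags = [False] * len(self.sequence)
        for i, j in self.pairs:
            flags[i] = flags[j] = True
        return flags

    @property
    def hairpin_loops(self) -> list[tuple[int, int]]:
        """Terminal loops: (start, end) half-open unpaired spans closed by a
        pair with no pairs inside."""
        flags = self.paired
        loops = []
        for i, j in sorted(self.pairs):
            if not any(flags[i + 1:j]):
                loops.append((i + 1, j))
        return loops


def _pair_weight_matrix(seq: str) -> np.ndarray:
    n = len(seq)
    w = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            w[i, j] = PAIR_WEIGHTS.get((seq[i], seq[j]), 0)
    return w


def fold_hairpin(seq: str) -> SecondaryStructure:
    """Maximum weighted base-pairing structure of an RNA sequence.

    Dynamic programming over intervals; ties during traceback are broken
    deterministically by preferring the pair (i, j) with the smallest i,
    then the smallest j.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGU"):
        raise ValueError("fold_hairpin expects an RNA string over ACGU")
    n = len(seq)
    wmat = _pair_weight_matrix(seq)
    # W[i, j] = best score on inclusive interval [i, j]; extra row/col so
    # empty intervals index cleanly as zero.
    W = np.zeros((n + 1, n + 1), dtype=np.int64)
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = W[i + 1, j]
            ks = np.nonzero(wmat[i, i:j + 1])[0] + i
            if ks.size:
                vals = wmat[i, ks] + W[i + 1, ks - 1] + W[ks + 1, j]
                best = max(best, int(vals.max()))
            W[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < MIN_LOOP + 1:
            continue
        target = W[i, j]
        paired_here = False
        ks = np.nonzero(wmat[i, i:j + 1])[0] + i
        for k in ks:
            if wmat[i, k] + W[i + 1, k - 1] + W[k + 1, j] == target:
                pairs.append((i, int(k)))
                stack.append((int(k) + 1, j))
                stack.append((i + 1, int(k) - 1))
                paired_here = True
                break
        if not paired_here:
            stack.append((i + 1, j))

    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return SecondaryStructure(seq, "".join(db), int(W[0, n - 1]), sorted(pairs))


@dataclass(frozen=True)
class HairpinCriteria:
    min_score: int = 25
    loop_min: int = 3
    loop_max: int = 20
    min_paired_frac: float = 0.6


@dataclass
class HairpinVerdict:
    candidate_id: str
    passes: bool
    reasons: list[str] = field(default_factory=list)
    mature_arm: str = "none"  # 5p / 3p / none


def evaluate_precursor(
    structure: SecondaryStructure,
    mature: tuple[int, int],
    criteria: HairpinCriteria = HairpinCriteria(),
    candidate_id: str = "candidate",
) -> HairpinVerdict:
    """Stem-placement filter: pass iff the mature arises from the stem of a
    single clean hairpin, with all failures enumerated."""
    ms, me = mature
    if not (0 <= ms < me <= len(structure.sequence)):
        raise ValueError("mature interval outside the candidate window")
    reasons = []
    if structure.score < criteria.min_score:
        reasons.append("low_pair_score")
    loops = structure.hairpin_loops
    arm = "none"
    clean_hairpin = len(loops) == 1 and (
        criteria.loop_min <= loops[0][1] - loops[0][0] <= criteria.loop_max
    )
    if not clean_hairpin:
        # zero loops, branched structure, or an oversized terminal loop
        reasons.append("multi_loop")
    else:
        ls, le = loops[0]
        if ms < le and me > ls:
            reasons.append("mature_in_loop")
        elif me <= ls:
            arm = "5p"
        elif ms >= le:
            arm = "3p"
    flags = structure.paired
    frac = sum(flags[ms:me]) / (me - ms)
    if frac < criteria.min_paired_frac:
        reasons.append("short_stem")
    return HairpinVerdict(candidate_id, not reasons, reasons, arm)


def assess_candidate(
    window: str,
    mature: tuple[int, int],
    criteria: HairpinCriteria = HairpinCriteria(),
    candidate_id: str = "candidate",
    max_extension: int | None = None,
    step: int = 5,
    pad: int = 3,
) -> tuple[HairpinVerdict, SecondaryStructure | None]:
    """Search the candidate window for a hairpin hosting the mature on a stem.

    A pre-miRNA places the mature on one arm with its partner arm within a
    few tens of nucleotides on one side, so the window is scanned with
    subwindows anchored at the mature: ``pad`` nt behind its 5' end and
    one-sided 3' extensions up to ``max_extension`` (and the mirror-image
    family for a 3p-arm mature).  Each subwindow is folded and judged with
    :func:`evaluate_precursor`; the highest-scoring passing subwindow wins,
    otherwise the closest-to-passing verdict is reported.  The extension
    step is kept small (<= 5 nt) so some subwindow overshoots the true
    partner arm by at most 4 nt — too little flanking sequence to fold
    into a spurious second loop.
    """
    rna = to_rna(window)
    ms, me = mature
    n = len(rna)
    if max_extension is None:
        # the partner arm can sit at most one arm plus the largest
        # acceptable loop away; longer subwindows cannot pass anyway
        max_extension = (me - ms) + criteria.loop_max + pad + step
    best_pass: tuple[HairpinVerdict, SecondaryStructure] | None = None
    best_fail: tuple[HairpinVerdict, SecondaryStructure] | None = None
    tried: set[tuple[int, int]] = set()
    min_ext = (me - ms) + criteria.loop_min  # partner arm + loop must fit
    for arm in ("5p", "3p"):
        for ext in range(min_ext, max_extension + 1, step):
            if arm == "5p":
                s, t = max(0, ms - pad), min(n, me + ext)
            else:
                s, t = max(0, ms - ext), min(n, me + pad)
            if t - s < 10 or (s, t) in tried:
                continue
            tried.add((s, t))
            sub = fold_hairpin(rna[s:t])
            verdict = evaluate_precursor(
                sub, (ms - s, me - s), criteria, candidate_id
            )
            if verdict.passes:
                if best_pass is None or sub.score > best_pass[1].score:
                    best_pass = (verdict, sub)
            else:
                key = (len(verdict.reasons), -sub.score)
                if best_fail is None or key < (
                    len(best_fail[0].reasons), -best_fail[1].score
                ):
                    best_fail = (verdict, sub)
    if best_pass is not None:
        return best_pass
    if best_fail is not None:
        return best_fail
    return HairpinVerdict(candidate_id, False, ["short_stem"], "none"), None


@dataclass
class NovelMirna:
    novel_id: str
    contig: str
    start: int
    end: int
    strand: str
    mature: str  # DNA
    precursor: str  # RNA of the accepted stem-loop unit
    structure: str  # dot-bracket of the unit
    score: int
    mature_arm: str
    counts: dict[str, int]
    isomirs: isomir.IsomirGroup | None = None

    @property
    def present_in(self) -> dict[str, bool]:
        return {c: n > 0 for c, n in self.counts.items()}

    @property
    def common_to_all(self) -> bool:
        return all(self.present_in.values())

    @property
    def high_count(self) -> bool:
        return sum(self.counts.values()) > 10


def predict_novel(
    candidates: list[HairpinCandidate],
    libraries: dict[str, TagLibrary],
    criteria: HairpinCriteria = HairpinCriteria(),
    known_matures: set[str] | None = None,
) -> tuple[list[NovelMirna], list[HairpinVerdict]]:
    """Filter candidate windows into novel miRNA records.

    Candidates (possibly pooled from several samples) are deduplicated by
    genomic window; per-condition counts come from the tag libraries and
    each accepted record carries its isomiR group built against the
    accepted stem-loop unit.
    """
    seen: set[tuple] = set()
    accepted: list[NovelMirna] = []
    rejected: list[HairpinVerdict] = []
    ordered = sorted(
        candidates, key=lambda c: (c.contig, c.start, c.end, c.strand, c.tag)
    )
    for cand in ordered:
        key = (cand.contig, cand.start, cand.end, cand.strand, cand.tag)
        if key in seen:
            continue
        seen.add(key)
        verdict, sub = assess_candidate(
            cand.sequence, cand.tag_interval, criteria, cand.candidate_id
        )
        if not verdict.passes or sub is None:
            rejected.append(verdict)
            continue
        counts = {
            cond: lib.tags.get(cand.tag, 0)
            for cond, lib in sorted(libraries.items())
        }
        pre_dna = sub.sequence.replace("U", "T")
        groups = [
            isomir.group_isomirs(
                lib, pre_dna, cand.tag,
                precursor_name=f"novel_{len(accepted) + 1}",
                exclude=known_matures,
            )
            for _, lib in sorted(libraries.items())
        ]
        accepted.append(
            NovelMirna(
                novel_id=f"novel_{len(accepted) + 1}",
                contig=cand.contig,
                start=cand.start,
                end=cand.end,
                strand=cand.strand,
                mature=cand.tag,
                precursor=sub.sequence,
                structure=sub.dotbracket,
                score=sub.score,
                mature_arm=verdict.mature_arm,
                counts=counts,
                isomirs=isomir.merge_groups(groups),
            )
        )
    return accepted, rejected


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (Altschul-Erickson Euler-path walk)."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    verts = [v for v in edges if v != last]
    for _ in range(1000):
        lasts = {v: edges[v][int(rng.integers(len(edges[v])))] for v in verts}
        ok = True
        for v in verts:
            cur, hops = v, 0
            while cur != last and hops <= len(lasts):
                if cur not in lasts:
                    break
                cur, hops = lasts[cur], hops + 1
            if cur != last:
                ok = False
                break
        if ok:
            break
    else:  # pragma: no cover - rejection sampling essentially always succeeds
        return seq
    shuffled: dict[str, list[str]] = {}
    for v, outs in edges.items():
        rest = list(outs)
        if v in lasts:
            rest.remove(lasts[v])
        order = [rest[i] for i in rng.permutation(len(rest))]
        if v in lasts:
            order.append(lasts[v])
        shuffled[v] = order
    out = [seq[0]]
    ptr = {v: 0 for v in shuffled}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def write_novel_tsv(records: list[NovelMirna], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "novel_id\tcontig\tstart\tend\tstrand\tmature\tarm\tscore\t"
            "counts\tcommon\thigh_count\n"
        )
        for r in records:
            counts = ",".join(f"{c}={n}" for c, n in sorted(r.counts.items()))
            fh.write(
                f"{r.novel_id}\t{r.contig}\t{r.start + 1}\t{r.end}\t"
                f"{r.strand}\t{r.mature}\t{r.mature_arm}\t{r.score}\t"
                f"{counts}\t{int(r.common_to_all)}\t{int(r.high_count)}\n"
            )


def write_novel_gff3(records: list[NovelMirna], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            fh.write(
                f"{r.contig}\thypoxamir\tmiRNA_primary_transcript\t"
                f"{r.start + 1}\t{r.end}\t{r.score}\t{r.strand}\t.\t"
                f"ID={r.novel_id}\n"
            )


def write_structures(records: list[NovelMirna], path: str | Path) -> None:
    """Dot-bracket structures alongside their sequences."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.novel_id}\n{r.precursor}\n{r.structure}\n")
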