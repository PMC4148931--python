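"""Seeded synthetic reference bundles and two-condition small-RNA libraries.

The generator emulates the data a hypoxia vs normoxia small-RNA sequencing
experiment produces: a genome hosting miRNA hairpin loci (some clustered
within 10 kb, some on the minus strand), transcript databases for the
annotation hierarchy (other ncRNAs, piRNAs, an rRNA/mRNA collection),
exon annotation, intergenic hairpins that play the role of undiscovered
miRNAs, and promoters carrying hypoxia response elements (RCGTG) within
5 kb upstream of induced precursors.  Libraries are adapter-ligated
16-30 nt inserts with negative-binomial per-miRNA counts, a planted
strongly induced species mimicking miR-210, isomiR end heterogeneity with
non-templated 3' additions, and background piRNA/rRNA/mRNA/exon fragments.
Every random draw flows from one master seed, so identical inputs give
byte-identical outputs, and the full ground truth (per-species counts per
condition, true fold multipliers, isomiR variant histograms, hairpin and
HRE plant coordinates) is returned alongside the reads.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from hypoxamir._seq import revcomp, to_dna
from hypoxamir.errors import ReferenceLookupError, SizingError

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # Illumina small-RNA 3' adapter

@dataclass(frozen=True)
class Precursor:
    """A miRNA hairpin locus: sequence plus strand-aware genomic placement."""

    sequence: str
    contig: str
    start: int  # 0-based half-open genomic interval
    end: int
    strand: str
    mature_arm: str  # which arm carries the annotated mature ('5p'/'3p')
    mature_offset: tuple[int, int]  # mature interval within `sequence`


@dataclass(frozen=True)
class PlantedHairpin:
    """An intergenic hairpin with no mature annotation (a 'novel' miRNA)."""

    name: str
    sequence: str
    contig: str
    start: int
    end: int
    strand: str
    mature_offset: tuple[int, int]

    @property
    def mature_sequence(self) -> str:
        s, e = self.mature_offset
        return self.sequence[s:e]


@dataclass
class ReferenceBundle:
    genome: dict[str, str]
    exon_annotation: list[tuple[str, int, int, str]]
    mature_mirnas: dict[str, str]
    precursors: dict[str, Precursor]
    other_ncrna: dict[str, str]
    pirnas: dict[str, str]
    rna_db: dict[str, str]
    clusters: dict[str, list[str]]
    planted_hairpins: list[PlantedHairpin]
    planted_hres: dict[str, list[int]]

    def precursor_sequence_at_locus(self, name: str) -> str:
        """Genomic sequence at the precursor's coordinates, strand-oriented."""
        p = self.precursors[name]
        s = self.genome[p.contig][p.start:p.end]
        return s if p.strand == "+" else revcomp(s)

    def validate(self) -> None:
        for name, p in self.precursors.items():
            mat = self.mature_mirnas[name]
            ms, me = p.mature_offset
            if p.sequence[ms:me] != mat:
                raise AssertionError(f"mature {name} not inside its precursor")
            if self.precursor_sequence_at_locus(name) != p.sequence:
                raise AssertionError(f"precursor {name} absent at its locus")
        for name, offs in self.planted_hres.items():
            if any(not (-5000 <= o <= -1) for o in offs):
                raise AssertionError(f"HRE offset out of range for {name}")
        for hp in self.planted_hairpins:
            g = self.genome[hp.contig][hp.start:hp.end]
            if (g if hp.strand == "+" else revcomp(g)) != hp.sequence:
                raise AssertionError(f"planted hairpin {hp.name} not at locus")


@dataclass(frozen=True)
class ReferenceSizes:
    """Feature counts and geometry for :func:`build_toy_reference`."""

    contig_name: str = "chrS"
    contig_length: int = 200_000
    n_mirnas: int = 30
    cluster_size: int = 3  # last `cluster_size` miRNAs form one <10 kb cluster
    n_novel_hairpins: int = 1
    n_ncrna: int = 6
    n_pirna: int = 6
    n_rna_db: int = 6
    n_exons: int = 3
    exon_length: int = 300
    promoter_span: int = 5000
    n_hre_mirnas: int = 5
    hres_per_mirna: int = 2
    mature_len: tuple[int, int] = (20, 23)
    loop_len: int = 4
    pad: int = 3
    stem_mutations: int = 2


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, 4, size=n, dtype=np.uint8)
    return _BASE_BYTES[idx].tobytes().decode("ascii")


_DNA_PAIRS = {
    ("G", "C"), ("C", "G"), ("A", "T"), ("T", "A"), ("G", "T"), ("T", "G"),
}


def _build_hairpin(
    rng: np.random.Generator, sizes: ReferenceSizes, arm: str
) -> tuple[str, str, tuple[int, int]]:
    """Design a hairpin precursor and return (sequence, mature, offsets).

    The terminal loop is poly-C, which cannot pair internally, and the six
    loop-adjacent stem positions are restricted to A/T so no loop C finds a
    profitable G partner across the junction — otherwise a maximum-weight
    folder trades one stem pair for two junction pairs and splits the
    terminal loop in two.  The off arm is the mature's reverse complement
    with a couple of non-pairing substitutions placed away from the loop,
    giving an imperfect but dominant stem.
    """
    mlen = int(rng.integers(sizes.mature_len[0], sizes.mature_len[1] + 1))
    mature = list(_random_dna(rng, mlen))
    at = np.array(["A", "T"])
    gc = np.array(["G", "C"])
    loop_adjacent = (
        range(mlen - 8, mlen) if arm == "5p" else range(8)
    )
    for k in loop_adjacent:
        mature[k] = str(rng.choice(at))
    # strong G/C pairs clamp the outer stem end so end fraying cannot trade
    # a designed pair for an equal-weight junk pair
    outer = range(3) if arm == "5p" else range(mlen - 3, mlen)
    for k in outer:
        mature[k] = str(rng.choice(gc))
    mature = "".join(mature)
    off_arm = list(revcomp(mature))
    # mismatches >= 8 nt from the loop-adjacent end of the off arm (a
    # mismatch next to the loop would leave a loop C free to pair it) and
    # >= 4 nt from the outer end
    mut_pool = (
        list(range(8, mlen - 4)) if arm == "5p" else list(range(4, mlen - 8))
    )
    for i in rng.choice(mut_pool, size=sizes.stem_mutations, replace=False):
        facing = mature[mlen - 1 - i]
        choices = [
            b for b in "ACGT"
            if b != off_arm[i] and (facing, b) not in _DNA_PAIRS
        ]
        off_arm[int(i)] = str(rng.choice(choices))
    off_arm = "".join(off_arm)
    loop = "C" * sizes.loop_len
    pad5 = _random_dna(rng, sizes.pad)
    pad3 = _random_dna(rng, sizes.pad)
    if arm == "5p":
        seq = pad5 + mature + loop + off_arm + pad3
        off = (sizes.pad, sizes.pad + mlen)
    else:
        seq = pad5 + off_arm + loop + mature + pad3
        start = sizes.pad + len(off_arm) + sizes.loop_len
        off = (start, start + mlen)
    return seq, mature, off


def build_toy_reference(
    seed: int, sizes: ReferenceSizes | None = None
) -> ReferenceBundle:
    """Construct a deterministic reference bundle hosting all planted features.

    Layout on one contig, left to right: promoter-bearing standalone miRNA
    loci in slots wide enough to host an untruncated 5 kb promoter and to
    stay clear of the 10 kb clustering distance, then the remaining miRNAs
    packed into dense blocks (~1.8 kb spacing; real miRNA genes are often
    clustered, and packing keeps the toy genome small), then one designated
    co-regulated cluster with promoter space before its first member, then
    intergenic hairpins and exon blocks.  Every dense block is declared as
    a genomic cluster, consistent with the 10 kb clustering convention.
    """
    sizes = sizes or ReferenceSizes()
    if sizes.n_mirnas < 1 or sizes.cluster_size > sizes.n_mirnas:
        raise SizingError("need >= 1 miRNA and cluster_size <= n_mirnas")
    rng = np.random.default_rng(seed)
    contig = sizes.contig_name
    span = sizes.promoter_span
    n_hre_standalone = max(
        0, sizes.n_hre_mirnas - (1 if sizes.cluster_size else 0)
    )
    n_plain = sizes.n_mirnas - sizes.cluster_size - n_hre_standalone
    if n_plain < 0:
        raise SizingError("more HRE miRNAs requested than miRNAs available")
    pre_slot = 2 * span + 2000 + 120  # promoter fits on either strand
    block_cap = 10  # members per dense block
    n_blocks = (n_plain + block_cap - 1) // block_cap
    plain_width = n_plain * 1800 + n_blocks * 11_000
    cluster_block = span + sizes.cluster_size * 2000 + 1000
    hairpin_block = sizes.n_novel_hairpins * 2500
    exon_block = sizes.n_exons * (sizes.exon_length + 1000)
    required = (
        2000 + n_hre_standalone * pre_slot + plain_width + cluster_block
        + hairpin_block + exon_block + 2000
    )
    if sizes.contig_length < max(required, 20_000):
        raise SizingError(
            f"contig of {sizes.contig_length} nt cannot host the requested "
            f"features ({required} nt needed)"
        )

    genome = list(_random_dna(rng, sizes.contig_length))

    def place(seq: str, pos: int) -> None:
        genome[pos:pos + len(seq)] = list(seq)

    mature_mirnas: dict[str, str] = {}
    precursors: dict[str, Precursor] = {}
    cursor = 1000

    def add_mirna(name: str, pos: int, strand: str, arm: str) -> None:
        seq, mature, off = _build_hairpin(rng, sizes, arm)
        place(seq if strand == "+" else revcomp(seq), pos)
        mature_mirnas[name] = mature
        precursors[name] = Precursor(
            seq, contig, pos, pos + len(seq), strand, arm, off
        )

    names = [f"mir-{i + 1:02d}" for i in range(sizes.n_mirnas)]
    standalone = names[:n_hre_standalone]
    plain = names[n_hre_standalone:n_hre_standalone + n_plain]
    cluster_members = names[n_hre_standalone + n_plain:]
    clusters: dict[str, list[str]] = {}
    if cluster_members:
        clusters["cluster-1"] = list(cluster_members)
    for i, name in enumerate(standalone):
        strand = "+" if i % 2 == 0 else "-"
        arm = "5p" if i % 2 == 0 else "3p"
        add_mirna(name, cursor + span, strand, arm)
        cursor += pre_slot
    for b in range(n_blocks):
        block = plain[b * block_cap:(b + 1) * block_cap]
        for i, name in enumerate(block):
            add_mirna(name, cursor, "+", "5p" if i % 2 == 0 else "3p")
            cursor += 1800
        if len(block) > 1:
            clusters[f"cluster-{len(clusters) + 1}"] = list(block)
        cursor += 11_000
    cursor += span
    for i, name in enumerate(cluster_members):
        add_mirna(name, cursor, "+", "5p" if i % 2 == 0 else "3p")
        cursor += 2000
    cursor += 1000

    planted_hairpins: list[PlantedHairpin] = []
    for i in range(sizes.n_novel_hairpins):
        seq, _, off = _build_hairpin(rng, sizes, "5p")
        strand = "+" if i % 2 == 0 else "-"
        pos = cursor + 1000
        place(seq if strand == "+" else revcomp(seq), pos)
        planted_hairpins.append(
            PlantedHairpin(
                f"hairpin-{i + 1}", seq, contig, pos, pos + len(seq), strand, off
            )
        )
        cursor += 2500

    exon_annotation: list[tuple[str, int, int, str]] = []
    for i in range(sizes.n_exons):
        pos = cursor + 1000
        exon_annotation.append((contig, pos, pos + sizes.exon_length, "+"))
        cursor += sizes.exon_length + 1000

    # HREs go to the first standalone miRNAs plus the first cluster member;
    # cluster members past the first would overlap a neighbour's promoter.
    hre_names = standalone[: max(0, sizes.n_hre_mirnas - 1)]
    if cluster_members and sizes.n_hre_mirnas > 0:
        hre_names = hre_names + [cluster_members[0]]
    planted_hres: dict[str, list[int]] = {}
    for name in hre_names:
        p = precursors[name]
        offs = sorted(
            int(o)
            for o in rng.choice(
                np.arange(-span + 200, -100), size=sizes.hres_per_mirna,
                replace=False,
            )
        )
        # keep plants >=10 nt apart so motifs never overwrite each other
        offs = [o for i, o in enumerate(offs) if i == 0 or o - offs[i - 1] >= 10]
        for o in offs:
            motif = str(rng.choice(np.array(["ACGTG", "GCGTG"])))
            if p.strand == "+":
                place(motif, p.start + o)
            else:
                place(revcomp(motif), p.end - o - 5)
        planted_hres[name] = offs

    # the ncRNA collection includes the precursor hairpins themselves, as
    # real ncRNA databases do; isomiR end-variants of known miRNAs therefore
    # resolve at the ncRNA stage instead of leaking into the genomic stages.
    other_ncrna = {
        f"ncrna-{i + 1}": _random_dna(rng, int(rng.integers(60, 121)))
        for i in range(sizes.n_ncrna)
    }
    other_ncrna.update(
        {f"pre-{n}": p.sequence for n, p in precursors.items()}
    )
    pirnas = {
        f"pirna-{i + 1}": _random_dna(rng, int(rng.integers(26, 32)))
        for i in range(sizes.n_pirna)
    }
    rna_db = {
        f"rnadb-{i + 1}": _random_dna(rng, int(rng.integers(150, 301)))
        for i in range(sizes.n_rna_db)
    }

    bundle = ReferenceBundle(
        genome={contig: "".join(genome)},
        exon_annotation=exon_annotation,
        mature_mirnas=mature_mirnas,
        precursors=precursors,
        other_ncrna=other_ncrna,
        pirnas=pirnas,
        rna_db=rna_db,
        clusters=clusters,
        planted_hairpins=planted_hairpins,
        planted_hres=planted_hres,
    )
    bundle.validate()
    return bundle


@dataclass(frozen=True)
class IsomirProfile:
    """End-heterogeneity model: representative mass plus shift multinomials.

    Offsets are templated shifts within the precursor; positive 5' offset
    trims the 5' end, positive 3' offset extends the 3' end.  Non-templated
    additions append untemplated A/T to the 3' end of non-representative
    variants.
    """

    p_representative: float = 0.6
    shift5: dict[int, float] = field(
        default_factory=lambda: {-1: 0.1, 0: 0.8, 1: 0.1}
    )
    shift3: dict[int, float] = field(
        default_factory=lambda: {-2: 0.1, -1: 0.2, 0: 0.4, 1: 0.2, 2: 0.1}
    )
    nta_rate: float = 0.15
    nta_alphabet: str = "AT"


@dataclass(frozen=True)
class SimulationProfile:
    """Study conditions for one two-condition simulation.

    ``fold`` multiplies the hypoxic abundance.  Counts are Poisson draws
    around a per-species Gamma baseline shared between the two conditions
    (marginally negative binomial with variance m + dispersion * m^2;
    dispersion 0 degenerates to Poisson).  Background fractions scale with
    the summed miRNA baseline so a profile with all-zero means yields
    empty libraries.
    """

    baseline_mean: dict[str, float]
    fold: dict[str, float]
    dispersion: float = 0.05
    isomir: IsomirProfile = field(default_factory=IsomirProfile)
    error_rate: float = 0.001
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 50
    background_fractions: dict[str, float] = field(
        default_factory=lambda: {"pirna": 0.04, "rna_db": 0.06, "exon": 0.03}
    )
    novel_mean: float = 25.0
    novel_fold: float = 3.0
    # Sequencing depth is an instrument setting, not a biological quantity:
    # with depth matching the hypoxic means are rescaled so both conditions
    # have the same expected library size, making the planted fold a fold in
    # relative (TPM) abundance, which is what differential calling measures.
    depth_match: bool = True
    seed: int = 0


def default_profile(ref: ReferenceBundle, seed: int = 0) -> SimulationProfile:
    """Default study conditions over a toy reference.

    The first miRNA is the strongly induced miR-210-like species (25-fold,
    modest baseline, as the real one rises from rarity); the remaining
    HRE-bearing miRNAs and the designated co-regulated cluster are induced
    4-fold, the two miRNAs after the HRE set are repressed 4-fold, and the
    rest are null.  Differentially expressed species carry a small share of
    total library mass — as in real libraries, where most of the
    transcriptome is unchanged — so planted folds survive the compositional
    (parts-per-million) normalization.
    """
    rng = np.random.default_rng([seed, 99])
    names = sorted(ref.mature_mirnas)
    fold = {n: 1.0 for n in names}
    up = set(ref.planted_hres) | set(ref.clusters.get("cluster-1", []))
    means = {}
    for n in names:
        if n in up:
            means[n] = float(rng.integers(100, 151))
            fold[n] = 4.0
        else:
            means[n] = float(rng.integers(1000, 2001))
    star = names[0]
    fold[star] = 25.0
    means[star] = 30.0
    null_pool = [n for n in names if n not in up and n != star]
    for n in null_pool[:2]:
        fold[n] = 0.25
        means[n] = float(rng.integers(150, 251))
    return SimulationProfile(baseline_mean=means, fold=fold, seed=seed)


@dataclass
class SimulationResult:
    reads: dict[str, list[str]]  # condition -> reads (full FASTQ sequences)
    truth: pd.DataFrame  # name, kind, count_normoxic, count_hypoxic, true_fold
    truth_isomirs: pd.DataFrame  # name, condition, offset5, offset3, nta, count
    # expected elimination-hierarchy class per condition, valid at error rate
    # 0: exact matures annotate as mature_miRNA, shifted/NTA variants as
    # ncRNA (the precursor entries), hairpin tags as intergenic/intronic.
    expected_class_counts: dict[str, dict[str, int]] = field(
        default_factory=dict
    )

    def class_counts(self, condition: str) -> dict[str, int]:
        t = self.truth
        col = f"count_{condition}"
        return t.groupby("kind")[col].sum().to_dict()


_CONDITIONS = ("normoxic", "hypoxic")


def _draw_baseline(
    rng: np.random.Generator, mean: float, dispersion: float
) -> float:
    """Per-species biological abundance for one experiment.

    Gamma with mean m and variance dispersion * m^2; Poisson sampling on
    top gives marginal counts that are negative binomial with variance
    m + dispersion * m^2 (dispersion 0 degenerates to Poisson).  The draw
    is shared between the two conditions of one simulated experiment —
    the libraries come from one culture split and treated — so biological
    variability moves both conditions together and the planted fold is the
    only systematic between-condition signal.
    """
    if mean <= 0:
        return 0.0
    if dispersion <= 0:
        return float(mean)
    return float(rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion))


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


def _draw_variant(
    rng: np.random.Generator,
    iso: IsomirProfile,
    precursor: str,
    mature_off: tuple[int, int],
) -> tuple[str, int, int, str]:
    """Draw one isomiR variant: (insert, offset5, offset3, nta_suffix)."""
    ms, me = mature_off
    if rng.random() < iso.p_representative:
        return precursor[ms:me], 0, 0, ""
    k5 = sorted(iso.shift5)
    k3 = sorted(iso.shift3)
    d5 = int(rng.choice(k5, p=np.array([iso.shift5[k] for k in k5])))
    d3 = int(rng.choice(k3, p=np.array([iso.shift3[k] for k in k3])))
    s, e = ms + d5, me + d3
    if s < 0 or e > len(precursor) or e - s < 16:
        d5, d3, s, e = 0, 0, ms, me
    nta = ""
    if rng.random() < iso.nta_rate:
        nta = str(rng.choice(list(iso.nta_alphabet)))
    return precursor[s:e] + nta, d5, d3, nta


def simulate_srna_libraries(
    ref: ReferenceBundle, profile: SimulationProfile
) -> SimulationResult:
    """Simulate the normoxic and hypoxic libraries with full ground truth."""
    for name in list(profile.baseline_mean) + list(profile.fold):
        if name not in ref.mature_mirnas:
            raise ReferenceLookupError(
                f"profile references unknown miRNA {name!r}"
            )
    reads: dict[str, list[str]] = {c: [] for c in _CONDITIONS}
    truth_rows: list[dict] = []
    iso_rows: list[dict] = []
    total_baseline = float(sum(profile.baseline_mean.values()))

    rngs = {c: np.random.default_rng([profile.seed, i]) for i, c in
            enumerate(_CONDITIONS)}
    rng_bio = np.random.default_rng([profile.seed, 2])  # shared baselines
    expected: dict[str, dict[str, int]] = {c: {} for c in _CONDITIONS}

    hyp_scale = 1.0
    if profile.depth_match and total_baseline > 0:
        total_hypoxic = sum(
            m * profile.fold.get(n, 1.0)
            for n, m in profile.baseline_mean.items()
        )
        if total_hypoxic > 0:
            hyp_scale = total_baseline / total_hypoxic

    def emit(cond: str, insert: str, expected_class: str) -> None:
        insert = _apply_errors(rngs[cond], insert, profile.error_rate)
        reads[cond].append((insert + profile.adapter)[: profile.read_length])
        expected[cond][expected_class] = (
            expected[cond].get(expected_class, 0) + 1
        )

    for name in sorted(profile.baseline_mean):
        mean = profile.baseline_mean[name]
        fold = profile.fold.get(name, 1.0)
        if fold <= 0:
            raise ValueError(f"fold multiplier for {name} must be > 0")
        pre = ref.precursors[name]
        lam = _draw_baseline(rng_bio, mean, profile.dispersion)
        counts = {}
        for cond in _CONDITIONS:
            m = lam * (fold * hyp_scale if cond == "hypoxic" else 1.0)
            n = int(rngs[cond].poisson(m)) if m > 0 else 0
            counts[cond] = n
            variant_counts: dict[tuple[int, int, str], int] = {}
            ms, me = pre.mature_offset
            mature = pre.sequence[ms:me]
            for _ in range(n):
                insert, d5, d3, nta = _draw_variant(
                    rngs[cond], profile.isomir, pre.sequence, pre.mature_offset
                )
                key = (d5, d3, nta)
                variant_counts[key] = variant_counts.get(key, 0) + 1
                emit(
                    cond, insert,
                    "mature_miRNA" if insert == mature else "ncRNA",
                )
            for (d5, d3, nta), c in sorted(variant_counts.items()):
                iso_rows.append(
                    {"name": name, "condition": cond, "offset5": d5,
                     "offset3": d3, "nta": nta, "count": c}
                )
        truth_rows.append(
            {"name": name, "kind": "mirna",
             "count_normoxic": counts["normoxic"],
             "count_hypoxic": counts["hypoxic"], "true_fold": fold}
        )

    for hp in ref.planted_hairpins:
        mean = profile.novel_mean if total_baseline > 0 else 0.0
        lam = _draw_baseline(rng_bio, mean, profile.dispersion)
        counts = {}
        for cond in _CONDITIONS:
            m = lam * (
                profile.novel_fold * hyp_scale if cond == "hypoxic" else 1.0
            )
            n = int(rngs[cond].poisson(m)) if m > 0 else 0
            counts[cond] = n
            for _ in range(n):
                emit(cond, hp.mature_sequence, "intergenic_intronic")
        truth_rows.append(
            {"name": hp.name, "kind": "novel",
             "count_normoxic": counts["normoxic"],
             "count_hypoxic": counts["hypoxic"],
             "true_fold": profile.novel_fold}
        )

    bg_sources = {
        "pirna": ref.pirnas,
        "rna_db": ref.rna_db,
    }
    for cond in _CONDITIONS:
        rng = rngs[cond]
        for kind, frac in sorted(profile.background_fractions.items()):
            n = int(rng.poisson(frac * total_baseline))
            if n == 0:
                continue
            if kind == "exon":
                for _ in range(n):
                    contig, s, e, _strand = ref.exon_annotation[
                        int(rng.integers(len(ref.exon_annotation)))
                    ]
                    flen = int(rng.integers(18, 29))
                    pos = int(rng.integers(s, e - flen))
                    frag = ref.genome[contig][pos:pos + flen]
                    emit(cond, frag, "exon")
            else:
                entries = sorted(bg_sources[kind])
                cls = "piRNA" if kind == "pirna" else "rna_db"
                for _ in range(n):
                    name = entries[int(rng.integers(len(entries)))]
                    seq = bg_sources[kind][name]
                    if kind == "pirna":
                        frag = seq
                    else:
                        flen = int(rng.integers(18, 29))
                        pos = int(rng.integers(0, len(seq) - flen + 1))
                        frag = seq[pos:pos + flen]
                    emit(cond, frag, cls)
            truth_rows.append(
                {"name": f"{kind}:{cond}", "kind": kind,
                 "count_normoxic": n if cond == "normoxic" else 0,
                 "count_hypoxic": n if cond == "hypoxic" else 0,
                 "true_fold": float("nan")}
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=["name", "kind", "count_normoxic", "count_hypoxic",
                 "true_fold"],
    )
    truth_iso = pd.DataFrame(
        iso_rows,
        columns=["name", "condition", "offset5", "offset3", "nta", "count"],
    )
    return SimulationResult(
        reads=reads, truth=truth, truth_isomirs=truth_iso,
        expected_class_counts=expected,
    )


# ---------------------------------------------------------------------------
# writers (FASTA / GFF3 / FASTQ / TSV)

def _write_fasta(path: Path, entries: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in entries:
            fh.write(f">{name}\n")
            seq = entries[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_fastq(path: str | Path, reads: list[str], prefix: str = "read") -> None:
    """Phred+33 FASTQ with constant quality (quality realism is a non-goal)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i + 1}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_reference_bundle(ref: ReferenceBundle, outdir: str | Path) -> dict[str, Path]:
    """Serialize the bundle: FASTA for sequences, GFF3 (1-based) for loci."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "mature": outdir / "mature_mirnas.fa",
        "precursor_fa": outdir / "precursors.fa",
        "precursor_gff": outdir / "precursors.gff3",
        "ncrna": outdir / "other_ncrna.fa",
        "pirna": outdir / "pirna.fa",
        "rna_db": outdir / "rna_db.fa",
        "exons": outdir / "exons.gff3",
        "clusters": outdir / "clusters.tsv",
        "truth_hres": outdir / "truth_hres.tsv",
        "truth_hairpins": outdir / "truth_hairpins.tsv",
    }
    _write_fasta(paths["genome"], ref.genome)
    _write_fasta(paths["mature"], dict(sorted(ref.mature_mirnas.items())))
    _write_fasta(
        paths["precursor_fa"],
        {n: p.sequence for n, p in sorted(ref.precursors.items())},
    )
    with open(paths["precursor_gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for n, p in sorted(ref.precursors.items()):
            fh.write(
                f"{p.contig}\thypoxamir\tmiRNA_primary_transcript\t"
                f"{p.start + 1}\t{p.end}\t.\t{p.strand}\t.\tID={n}\n"
            )
    with open(paths["exons"], "w") as fh:
        fh.write("##gff-version 3\n")
        for i, (contig, s, e, strand) in enumerate(ref.exon_annotation):
            fh.write(
                f"{contig}\thypoxamir\texon\t{s + 1}\t{e}\t.\t{strand}\t.\t"
                f"ID=exon-{i + 1}\n"
            )
    _write_fasta(paths["ncrna"], dict(sorted(ref.other_ncrna.items())))
    _write_fasta(paths["pirna"], dict(sorted(ref.pirnas.items())))
    _write_fasta(paths["rna_db"], dict(sorted(ref.rna_db.items())))
    with open(paths["clusters"], "w") as fh:
        fh.write("cluster\tmember\n")
        for cid, members in sorted(ref.clusters.items()):
            for m in members:
                fh.write(f"{cid}\t{m}\n")
    with open(paths["truth_hres"], "w") as fh:
        fh.write("mirna\toffset\n")
        for n, offs in sorted(ref.planted_hres.items()):
            for o in offs:
                fh.write(f"{n}\t{o}\n")
    with open(paths["truth_hairpins"], "w") as fh:
        fh.write("name\tcontig\tstart\tend\tstrand\tmature\n")
        for hp in ref.planted_hairpins:
            fh.write(
                f"{hp.name}\t{hp.contig}\t{hp.start}\t{hp.end}\t{hp.strand}\t"
                f"{hp.mature_sequence}\n"
            )
    return paths


def profile_to_dict(profile: SimulationProfile) -> dict:
    return dataclasses.asdict(profile)


def _read_fasta(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def load_reference_bundle(refdir: str | Path) -> ReferenceBundle:
    """Load a bundle previously written by :func:`write_reference_bundle`.

    Mature offsets are recovered by locating each mature inside its
    precursor; plant truth files are optional (absent for real data).
    """
    refdir = Path(refdir)
    genome = _read_fasta(refdir / "genome.fa")
    mature = _read_fasta(refdir / "mature_mirnas.fa")
    pre_seqs = _read_fasta(refdir / "precursors.fa")
    loci: dict[str, tuple[str, int, int, str]] = {}
    with open(refdir / "precursors.gff3") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            name = f[8].split("ID=")[1].split(";")[0]
            loci[name] = (f[0], int(f[3]) - 1, int(f[4]), f[6])
    precursors = {}
    for name, seq in pre_seqs.items():
        contig, start, end, strand = loci[name]
        ms = seq.find(to_dna(mature[name]))
        if ms < 0:
            raise ReferenceLookupError(f"mature {name} not in its precursor")
        me = ms + len(mature[name])
        arm = "5p" if ms < len(seq) - me else "3p"
        precursors[name] = Precursor(seq, contig, start, end, strand, arm, (ms, me))
    exons = []
    exon_path = refdir / "exons.gff3"
    if exon_path.exists():
        with open(exon_path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                exons.append((f[0], int(f[3]) - 1, int(f[4]), f[6]))
    clusters: dict[str, list[str]] = {}
    cl_path = refdir / "clusters.tsv"
    if cl_path.exists():
        with open(cl_path) as fh:
            next(fh)
            for line in fh:
                cid, member = line.split()
                clusters.setdefault(cid, []).append(member)
    hres: dict[str, list[int]] = {}
    hre_path = refdir / "truth_hres.tsv"
    if hre_path.exists():
        with open(hre_path) as fh:
            next(fh)
            for line in fh:
                name, off = line.split()
                hres.setdefault(name, []).append(int(off))
    hairpins = []
    hp_path = refdir / "truth_hairpins.tsv"
    if hp_path.exists():
        with open(hp_path) as fh:
            next(fh)
            for line in fh:
                name, contig, start, end, strand, mat = line.split()
                g = genome[contig][int(start):int(end)]
                seq = g if strand == "+" else revcomp(g)
                ms = seq.find(mat)
                hairpins.append(
                    PlantedHairpin(
                        name, seq, contig, int(start), int(end), strand,
                        (ms, ms + len(mat)),
                    )
                )
    return ReferenceBundle(
        genome=genome,
        exon_annotation=exons,
        mature_mirnas=mature,
        precursors=precursors,
        other_ncrna=_read_fasta(refdir / "other_ncrna.fa"),
        pirnas=_read_fasta(refdir / "pirna.fa"),
        rna_db=_read_fasta(refdir / "rna_db.fa"),
        clusters=clusters,
        planted_hairpins=hairpins,
        planted_hres=hres,
    )
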