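"""End-to-end orchestration of the small-RNA hypoxia analysis.

One call runs preprocessing, elimination annotation, TPM/RPKM
quantification with differential calling, isomiR cataloguing, novel
hairpin prediction, promoter HRE scanning and target consensus over a
two-condition experiment, writing one table per stage plus a summary
report.  All tables use fixed column orders and 4-decimal floats so
reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from hypoxamir import annotate, isomir, novel, preprocess, promoter, quantify
from hypoxamir import synthetic, targets
from hypoxamir._seq import revcomp, to_dna
from hypoxamir.config import PipelineConfig

CONDITIONS = ("normoxic", "hypoxic")


@dataclass
class PipelineReport:
    outdir: Path
    stats: dict[str, preprocess.PreprocessStats]
    class_percentages: dict[str, dict[str, float]]
    class_read_counts: dict[str, dict[str, int]]
    n_up: int = 0
    n_down: int = 0
    n_novel: int = 0
    n_hre_mirnas: int = 0
    n_consensus_targets: int = 0
    outputs: dict[str, Path] = field(default_factory=dict)

    def conservation_ok(self) -> bool:
        """reads in == no-adapter + length-filtered + annotated classes."""
        for cond, st in self.stats.items():
            annotated = sum(self.class_read_counts[cond].values())
            if st.n_input != st.n_no_adapter + st.n_length_filtered + annotated:
                return False
        return True


def _planted_seed_site(mirna_dna: str) -> str:
    """An 8mer target site for a miRNA: revcomp of positions 2-8 plus A."""
    return revcomp(mirna_dna[1:8]) + "A"


def emulated_prediction_sources(
    star: str,
    star_seq: str,
    rng: np.random.Generator,
    n_sources: int = 5,
    n_true: int = 8,
    n_decoy: int = 22,
    utr_len: int = 120,
) -> tuple[dict[str, set[str]], set[str], dict[str, str]]:
    """Stand-in for external target-prediction programs.

    Builds a synthetic UTR pool in which ``n_true`` genes carry a planted
    8mer site for the miRNA; the built-in seed matcher is one source and
    the remaining sources are noisy views of the truth (true targets kept
    with probability 0.85, decoys admitted with probability 0.1).
    Returns (prediction_sets, true_target_genes, utrs).
    """
    site = _planted_seed_site(to_dna(star_seq))
    utrs: dict[str, str] = {}
    true_genes = set()
    bases = np.array(list("ACGT"))
    for g in range(n_true + n_decoy):
        gene = f"gene-{g + 1:03d}"
        seq = "".join(rng.choice(bases, size=utr_len))
        if g < n_true:
            pos = int(rng.integers(10, utr_len - 20))
            seq = seq[:pos] + site + seq[pos + len(site):]
            true_genes.add(gene)
        utrs[gene] = seq
    sets: dict[str, set[str]] = {
        "seed_match": {
            gene for gene, seq in utrs.items()
            if targets.find_seed_sites(seq, star_seq, gene)
        }
    }
    for s in range(n_sources - 1):
        picked = {
            g for g in sorted(utrs)
            if (g in true_genes and rng.random() < 0.85)
            or (g not in true_genes and rng.random() < 0.1)
        }
        sets[f"program-{s + 1}"] = picked
    return sets, true_genes, utrs


def run_pipeline(
    config: PipelineConfig, sizes: synthetic.ReferenceSizes | None = None
) -> PipelineReport:
    """Run every stage; ``sizes`` optionally scales the synthetic reference."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # --- stage 0: inputs -------------------------------------------------
    if config.simulate:
        ref = synthetic.build_toy_reference(config.seed, sizes)
        profile = synthetic.default_profile(ref, config.seed)
        sim = synthetic.simulate_srna_libraries(ref, profile)
        refdir = outdir / "reference"
        synthetic.write_reference_bundle(ref, refdir)
        fastqs = {}
        for cond in CONDITIONS:
            path = outdir / f"{cond}.fastq"
            synthetic.write_fastq(path, sim.reads[cond], prefix=cond)
            fastqs[cond] = path
        sim.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        outputs["truth"] = outdir / "truth.tsv"
    else:
        ref = synthetic.load_reference_bundle(config.reference_dir)
        fastqs = {
            "normoxic": Path(config.fastq_normoxic),
            "hypoxic": Path(config.fastq_hypoxic),
        }

    # --- stage 1: preprocess ---------------------------------------------
    libs: dict[str, preprocess.TagLibrary] = {}
    stats: dict[str, preprocess.PreprocessStats] = {}
    for cond in CONDITIONS:
        lib, st = preprocess.preprocess_fastq(
            fastqs[cond], cond, cond, config.adapter,
            min_overlap=config.adapter_min_overlap,
            max_mismatches=config.adapter_max_mismatches,
            min_len=config.min_len, max_len=config.max_len,
        )
        libs[cond], stats[cond] = lib, st
        preprocess.write_tags_tsv(lib, outdir / f"tags_{cond}.tsv")
        preprocess.write_tags_fasta(lib, outdir / f"tags_{cond}.fa")
        outputs[f"tags_{cond}"] = outdir / f"tags_{cond}.tsv"

    # --- stage 2: annotate -----------------------------------------------
    tables: dict[str, annotate.AnnotationTable] = {}
    class_pct: dict[str, dict[str, float]] = {}
    class_counts: dict[str, dict[str, int]] = {}
    for cond in CONDITIONS:
        tab = annotate.eliminate_hierarchy(
            libs[cond], ref, config.max_mismatches
        )
        tables[cond] = tab
        class_pct[cond] = tab.class_read_percentages()
        class_counts[cond] = tab.class_read_counts()
        annotate.write_annotation_tsv(tab, outdir / f"annotation_{cond}.tsv")
        outputs[f"annotation_{cond}"] = outdir / f"annotation_{cond}.tsv"

    # --- stage 3: quantify + differential --------------------------------
    lengths = {n: len(s) for n, s in ref.mature_mirnas.items()}
    mirna_counts: dict[str, dict[str, int]] = {}
    for cond in CONDITIONS:
        assign = {
            r.tag: r.ref_name
            for r in tables[cond].by_class("mature_miRNA")
        }
        expr = quantify.expression_table(libs[cond], assign, lengths)
        quantify.write_expression_tsv(expr, outdir / f"expression_{cond}.tsv")
        outputs[f"expression_{cond}"] = outdir / f"expression_{cond}.tsv"
        mirna_counts[cond] = dict(zip(expr["mirna"], expr["count"]))
    de = quantify.call_differential(
        mirna_counts["hypoxic"], libs["hypoxic"].total_clone_count,
        mirna_counts["normoxic"], libs["normoxic"].total_clone_count,
        threshold=config.de_threshold, pseudocount=config.pseudocount,
    )
    quantify.write_differential_tsv(de, outdir / "differential.tsv")
    outputs["differential"] = outdir / "differential.tsv"
    clusters = ref.clusters or quantify.derive_clusters(
        ref.precursors, config.cluster_gap
    )
    cluster_summary = quantify.cluster_coregulation(de, clusters)
    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("cluster\tmembers\tn_up\tn_down\tco_regulated\n")
        for c in cluster_summary:
            fh.write(
                f"{c.cluster}\t{','.join(c.members)}\t{c.n_up}\t{c.n_down}\t"
                f"{int(c.co_regulated)}\n"
            )
    outputs["clusters"] = outdir / "clusters.tsv"

    # --- stage 4: isomiR catalog ------------------------------------------
    all_matures = {to_dna(s) for s in ref.mature_mirnas.values()}
    groups_by_cond: dict[str, list[isomir.IsomirGroup]] = {c: [] for c in CONDITIONS}
    merged_groups = []
    for name in sorted(ref.mature_mirnas):
        p = ref.precursors[name]
        per_cond = []
        for cond in CONDITIONS:
            g = isomir.group_isomirs(
                libs[cond], p.sequence, ref.mature_mirnas[name],
                precursor_name=name,
                max_offset5=config.isomir_max_offset5,
                max_offset3=config.isomir_max_offset3,
                max_nta=config.isomir_max_nta,
                exclude=all_matures - {to_dna(ref.mature_mirnas[name])},
            )
            per_cond.append(g)
            groups_by_cond[cond].append(g)
        merged_groups.append(isomir.merge_groups(per_cond))
    isomir.write_isomir_catalog(
        merged_groups, outdir / "isomirs.tsv", list(CONDITIONS)
    )
    summary = isomir.isomir_condition_summary(groups_by_cond)
    summary.to_csv(outdir / "isomir_summary.tsv", sep="\t", index=False)
    outputs["isomirs"] = outdir / "isomirs.tsv"
    outputs["isomir_summary"] = outdir / "isomir_summary.tsv"

    # --- stage 5: novel miRNA discovery ----------------------------------
    candidates = []
    for cond in CONDITIONS:
        candidates.extend(
            annotate.extract_genomic_candidates(
                tables[cond], ref.genome, config.flank
            )
        )
    criteria = novel.HairpinCriteria(
        config.hairpin_min_score, config.hairpin_loop_min,
        config.hairpin_loop_max, config.hairpin_min_paired_frac,
    )
    accepted, rejected = novel.predict_novel(
        candidates, libs, criteria, known_matures=all_matures
    )
    novel.write_novel_tsv(accepted, outdir / "novel.tsv")
    novel.write_novel_gff3(accepted, outdir / "novel.gff3")
    novel.write_structures(accepted, outdir / "novel_structures.txt")
    with open(outdir / "novel_rejects.tsv", "w") as fh:
        fh.write("candidate_id\treasons\n")
        for v in rejected:
            fh.write(f"{v.candidate_id}\t{','.join(v.reasons)}\n")
    outputs["novel"] = outdir / "novel.tsv"

    # --- stage 6: promoter HRE scan (up-regulated miRNAs) -----------------
    up = [r.mirna for r in de if r.direction == "up"]
    hre_table = promoter.scan_mirna_hres(
        ref.precursors, ref.genome, mirnas=sorted(up),
        span=config.hre_span, motif=config.hre_motif,
    )
    promoter.write_hre_tsv(hre_table, outdir / "hres.tsv")
    promoter.write_hre_bed(
        hre_table, ref.precursors, outdir / "hres.bed",
        motif_len=len(config.hre_motif),
    )
    outputs["hres"] = outdir / "hres.tsv"

    # --- stage 7: target consensus ----------------------------------------
    star = de[0].mirna if de else None
    n_consensus = 0
    if star is not None:
        rng = np.random.default_rng([config.seed, 7])
        sets, _, _ = emulated_prediction_sources(
            star, ref.mature_mirnas[star], rng, config.n_target_sources
        )
        consensus = targets.consensus_targets(sets, config.min_support)
        targets.write_consensus_tsv(consensus, outdir / "consensus_targets.tsv")
        outputs["consensus"] = outdir / "consensus_targets.tsv"
        n_consensus = len(consensus)

    report = PipelineReport(
        outdir=outdir,
        stats=stats,
        class_percentages=class_pct,
        class_read_counts=class_counts,
        n_up=sum(1 for r in de if r.direction == "up"),
        n_down=sum(1 for r in de if r.direction == "down"),
        n_novel=len(accepted),
        n_hre_mirnas=int(hre_table["mirna"].nunique()) if len(hre_table) else 0,
        n_consensus_targets=n_consensus,
        outputs=outputs,
    )
    config.to_yaml(outdir / "params.yaml")
    _write_report(report, outdir / "report.txt")
    return report


def _write_report(report: PipelineReport, path: Path) -> None:
    lines = ["small-RNA hypoxia pipeline report", "=" * 34]
    for cond, st in report.stats.items():
        lines.append(
            f"{cond}: {st.n_input} reads in, {st.n_no_adapter} no-adapter, "
            f"{st.n_length_filtered} length-filtered, {st.n_kept} kept"
        )
        pct = report.class_percentages[cond]
        top = ", ".join(
            f"{c}={pct[c]:.1f}%" for c in annotate.CLASSES if pct[c] > 0
        )
        lines.append(f"  class read fractions: {top}")
    lines.append(
        f"differential: {report.n_up} up / {report.n_down} down"
    )
    lines.append(f"novel miRNAs: {report.n_novel}")
    lines.append(f"miRNAs with promoter HREs: {report.n_hre_mirnas}")
    lines.append(f"consensus targets: {report.n_consensus_targets}")
    lines.append(f"read conservation: {'ok' if report.conservation_ok() else 'VIOLATED'}")
    path.write_text("\n".join(lines) + "\n")
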