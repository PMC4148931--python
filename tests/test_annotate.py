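"""Elimination-hierarchy annotation: stage order, mismatch bounds, windows."""

import numpy as np

from hypoxamir import annotate, synthetic
from hypoxamir._seq import revcomp
from hypoxamir.annotate import (
    AnnotationTable,
    eliminate_hierarchy,
    extract_genomic_candidates,
    match_exact_mature,
)
from hypoxamir.preprocess import TagLibrary


def _lib(tags, condition="normoxic"):
    return TagLibrary("t", condition, dict(tags))


def brute_force_best_hit(tag, db, max_mm):
    """Oracle: full Hamming scan of every window of every entry."""
    hits = []
    for name in sorted(db):
        seq = db[name]
        for i in range(len(seq) - len(tag) + 1):
            mm = sum(a != b for a, b in zip(tag, seq[i:i + len(tag)]))
            if mm <= max_mm:
                hits.append((mm, name, i))
    return min(hits) if hits else None


class TestExactMature:
    def test_identity_assignment(self, small_ref):
        name = sorted(small_ref.mature_mirnas)[0]
        seq = small_ref.mature_mirnas[name]
        table = match_exact_mature(_lib({seq: 5}), small_ref.mature_mirnas)
        rec = table.records[seq]
        assert rec.class_ == "mature_miRNA"
        assert rec.ref_name == name and rec.mismatches == 0

    def test_u_t_insensitive(self, small_ref):
        name = sorted(small_ref.mature_mirnas)[0]
        rna = small_ref.mature_mirnas[name].replace("T", "U")
        table = match_exact_mature(_lib({rna: 1}), small_ref.mature_mirnas)
        assert table.records[rna].class_ == "mature_miRNA"

    def test_one_mismatch_stays_unassigned_here(self, small_ref):
        name = sorted(small_ref.mature_mirnas)[0]
        seq = small_ref.mature_mirnas[name]
        mutated = ("G" if seq[0] != "G" else "T") + seq[1:]
        table = match_exact_mature(_lib({mutated: 1}), small_ref.mature_mirnas)
        assert table.records[mutated].class_ == "unassigned"

    def test_simulated_error_free_tags_all_recovered(
        self, small_ref, small_libs
    ):
        """Every exact-mature tag in the error-free simulation maps back to
        the miRNA that generated it."""
        lib = small_libs["normoxic"]
        table = match_exact_mature(lib, small_ref.mature_mirnas)
        matched = [r for r in table.records.values()
                   if r.class_ == "mature_miRNA"]
        assert matched
        for rec in matched:
            assert small_ref.mature_mirnas[rec.ref_name] == rec.tag


class TestEliminationHierarchy:
    def test_stage_precedence_pirna_before_exon(self, small_ref):
        # a piRNA sequence also planted inside an exon must stay piRNA
        pirna_name = sorted(small_ref.pirnas)[0]
        seq = small_ref.pirnas[pirna_name]
        contig, s, e, _ = small_ref.exon_annotation[0]
        genome = dict(small_ref.genome)
        genome[contig] = (
            genome[contig][:s] + seq
            + genome[contig][s + len(seq):]
        )
        ref = synthetic.ReferenceBundle(
            genome=genome,
            exon_annotation=small_ref.exon_annotation,
            mature_mirnas=small_ref.mature_mirnas,
            precursors=small_ref.precursors,
            other_ncrna=small_ref.other_ncrna,
            pirnas=small_ref.pirnas,
            rna_db=small_ref.rna_db,
            clusters=small_ref.clusters,
            planted_hairpins=[],
            planted_hres={},
        )
        table = eliminate_hierarchy(_lib({seq: 1}), ref)
        assert table.records[seq].class_ == "piRNA"

    def test_two_mismatches_allowed_three_rejected(self, small_ref):
        entry = sorted(small_ref.other_ncrna)[0]
        frag = small_ref.other_ncrna[entry][10:34]

        def mutate(s, k):
            out = list(s)
            for i in range(k):
                out[2 + 3 * i] = "A" if out[2 + 3 * i] != "A" else "C"
            return "".join(out)

        t2, t3 = mutate(frag, 2), mutate(frag, 3)
        table = eliminate_hierarchy(_lib({t2: 1, t3: 1}), small_ref)
        assert table.records[t2].class_ == "ncRNA"
        assert table.records[t2].mismatches == 2
        assert table.records[t3].class_ != "ncRNA"

    def test_class_counts_match_simulation_truth(self, small_ref, small_libs):
        """With error rate 0 the per-class read counts equal the generator's
        expected class bookkeeping, and the classes partition the tags."""
        for cond in ("normoxic", "hypoxic"):
            lib = small_libs[cond]
            table = eliminate_hierarchy(lib, small_ref)
            counts = table.class_read_counts()
            total = sum(counts.values())
            assert total == lib.total_clone_count
            # compare against the simulation's expected classes
            sim_expected = _expected(small_ref, cond)
            for cls, n in sim_expected.items():
                assert counts[cls] == n, cls

    def test_mismatch_monotonicity(self, small_ref):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        tags = {}
        entries = list(small_ref.other_ncrna.values()) + list(
            small_ref.rna_db.values()
        )
        for i in range(40):
            src = entries[i % len(entries)]
            s = list(src[5:29])
            for _ in range(int(rng.integers(0, 4))):
                j = int(rng.integers(len(s)))
                s[j] = str(rng.choice(bases))
            tags["".join(s)] = 1
        assigned = []
        for mm in (0, 1, 2):
            table = eliminate_hierarchy(_lib(tags), small_ref, mm)
            assigned.append(
                sum(1 for r in table.records.values()
                    if r.class_ != "unassigned")
            )
        assert assigned[0] <= assigned[1] <= assigned[2]

    def test_agrees_with_brute_force_hamming_oracle(self, small_ref):
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        tags = []
        for entry in list(small_ref.pirnas.values())[:3]:
            s = list(entry[:24])
            s[5] = str(rng.choice(bases))
            s[11] = str(rng.choice(bases))
            tags.append("".join(s))
        table = eliminate_hierarchy(_lib({t: 1 for t in tags}), small_ref)
        for t in tags:
            oracle = brute_force_best_hit(t, small_ref.pirnas, 2)
            rec = table.records[t]
            if oracle is None:
                assert rec.class_ != "piRNA"
            elif rec.class_ == "piRNA":
                assert rec.mismatches == oracle[0]
                assert rec.ref_name == oracle[1]


def _expected(ref, cond):
    # regenerate the error-free simulation's expected class counts
    profile = synthetic.default_profile(ref, seed=7)
    profile = synthetic.SimulationProfile(
        baseline_mean=profile.baseline_mean, fold=profile.fold,
        dispersion=0.05, error_rate=0.0, seed=7,
    )
    sim = synthetic.simulate_srna_libraries(ref, profile)
    return sim.expected_class_counts[cond]


class TestCandidateExtraction:
    def _table_for(self, tag, contig, start, strand, mm=0):
        rec = annotate.TagAnnotation(
            tag, 3, "intergenic_intronic", ref_name=contig, mismatches=mm,
            contig=contig, start=start, end=start + len(tag), strand=strand,
        )
        return AnnotationTable({tag: rec})

    def test_mid_contig_window_arithmetic(self):
        genome = {"c": "A" * 500}
        tag = "G" * 22
        table = self._table_for(tag, "c", 200, "+")
        (cand,) = extract_genomic_candidates(table, genome, flank=70)
        assert (cand.start, cand.end) == (130, 292)
        assert len(cand.sequence) == 162 and cand.tag_offset == 70

    def test_truncation_at_contig_start(self):
        genome = {"c": "A" * 500}
        tag = "G" * 20
        table = self._table_for(tag, "c", 10, "+")
        (cand,) = extract_genomic_candidates(table, genome, flank=70)
        assert cand.start == 0 and cand.tag_offset == 10

    def test_minus_strand_window_is_revcomp_oracle(self, small_ref):
        contig = sorted(small_ref.genome)[0]
        seq = small_ref.genome[contig]
        start = 1000
        tag = revcomp(seq[start:start + 22])
        table = self._table_for(tag, contig, start, "-")
        (cand,) = extract_genomic_candidates(table, small_ref.genome, 70)
        assert cand.sequence == revcomp(seq[start - 70:start + 22 + 70])
        assert cand.sequence[cand.tag_offset:cand.tag_offset + 22] == tag

    def test_inexact_placements_excluded_by_default(self):
        genome = {"c": "A" * 300}
        table = self._table_for("G" * 20, "c", 100, "+", mm=1)
        assert extract_genomic_candidates(table, genome) == []
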