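"""Hairpin folding DP, stem-placement filter, and novel-miRNA prediction."""

import numpy as np
import pytest

from hypoxamir import novel, synthetic
from hypoxamir.novel import (
    HairpinCriteria,
    assess_candidate,
    dinucleotide_shuffle,
    evaluate_precursor,
    fold_hairpin,
)

PAIR = novel.PAIR_WEIGHTS


def brute_force_max_score(seq):
    """Independent oracle: exhaustively enumerate every nested structure."""

    def best(i, j):
        if j - i < novel.MIN_LOOP + 1:
            return 0
        score = best(i + 1, j)
        for k in range(i + novel.MIN_LOOP + 1, j + 1):
            w = PAIR.get((seq[i], seq[k]), 0)
            if w:
                score = max(score, w + best(i + 1, k - 1) + best(k + 1, j))
        return score

    return best(0, len(seq) - 1)


def parse_pairs(db):
    stack, pairs = [], []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            pairs.append((stack.pop(), i))
    assert not stack, "unbalanced brackets"
    return pairs


class TestFoldHairpin:
    def test_perfect_mini_hairpin(self):
        s = fold_hairpin("GGGAAACCC")
        assert s.dotbracket == "(((...)))"
        assert s.score == 9

    def test_unpairable_sequence_stays_open(self):
        s = fold_hairpin("AAAAAAAAAA")
        assert s.dotbracket == "." * 10 and s.score == 0

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            fold_hairpin("ACGTACGTAC")  # T is DNA; folding wants RNA

    def test_empty_rejected_and_short_unpaired(self):
        with pytest.raises(ValueError):
            fold_hairpin("")
        # below the minimum loop span nothing can pair
        assert fold_hairpin("GGCC").dotbracket == "...."

    def test_dp_equals_exhaustive_enumeration(self):
        """100 random sequences of length <= 14: DP score must equal the
        brute-force maximum over all nested structures."""
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGU"))
        for _ in range(100):
            n = int(rng.integers(10, 15))
            seq = "".join(rng.choice(bases, size=n))
            assert fold_hairpin(seq).score == brute_force_max_score(seq)

    def test_structure_is_wellformed(self):
        rng = np.random.default_rng(23)
        bases = np.array(list("ACGU"))
        for _ in range(40):
            seq = "".join(rng.choice(bases, size=int(rng.integers(10, 60))))
            s = fold_hairpin(seq)
            pairs = parse_pairs(s.dotbracket)
            assert sorted(pairs) == sorted(s.pairs)
            for i, j in pairs:
                assert j - i - 1 >= novel.MIN_LOOP
                assert PAIR.get((seq[i], seq[j]), 0) > 0
            # recomputed score from the pair list matches
            assert s.score == sum(PAIR[(seq[i], seq[j])] for i, j in pairs)


class TestEvaluatePrecursor:
    def _perfect_hairpin(self, stem=15, loop=4):
        arm = "G" * 3 + "AUAUCGCGAU" * 2
        arm = arm[:stem]
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        other = "".join(comp[c] for c in reversed(arm))
        return arm + "C" * loop + other

    def test_clean_stem_mature_passes(self):
        seq = self._perfect_hairpin()
        s = fold_hairpin(seq)
        v = evaluate_precursor(s, (0, 14))
        assert v.passes and v.mature_arm == "5p"

    def test_mature_on_loop_fails(self):
        seq = self._perfect_hairpin(stem=15, loop=8)
        s = fold_hairpin(seq)
        v = evaluate_precursor(s, (12, 20))  # straddles the terminal loop
        assert not v.passes
        assert "mature_in_loop" in v.reasons

    def test_low_score_reported(self):
        s = fold_hairpin("GGGAAACCCAAA")
        v = evaluate_precursor(s, (0, 3), HairpinCriteria(min_score=25))
        assert "low_pair_score" in v.reasons

    def test_mature_interval_validated(self):
        s = fold_hairpin("GGGAAACCCAAA")
        with pytest.raises(ValueError):
            evaluate_precursor(s, (5, 30))

    def test_planted_vs_shuffled_discrimination(self):
        """Planted hairpin windows against dinucleotide-shuffled windows:
        sensitivity >= 0.9 and specificity >= 0.8 at default thresholds."""
        sizes = synthetic.ReferenceSizes(
            n_mirnas=1, cluster_size=0, n_hre_mirnas=0,
            n_novel_hairpins=50, n_exons=0, contig_length=160_000,
        )
        ref = synthetic.build_toy_reference(31, sizes)
        rng = np.random.default_rng(31)
        tp = fp = 0
        n = len(ref.planted_hairpins)
        for hp in ref.planted_hairpins:
            g = ref.genome[hp.contig]
            ms, me = hp.mature_offset
            win = g[hp.start + ms - 70:hp.start + me + 70]
            mature = (70, 70 + (me - ms))
            v, _ = assess_candidate(win, mature)
            tp += v.passes
            v2, _ = assess_candidate(dinucleotide_shuffle(win, rng), mature)
            fp += v2.passes
        assert tp / n >= 0.9, f"sensitivity {tp / n}"
        assert 1 - fp / n >= 0.8, f"specificity {1 - fp / n}"


class TestShuffle:
    def test_preserves_dinucleotide_counts(self):
        from collections import Counter

        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(np.array(list("ACGT")), size=120))
        shuf = dinucleotide_shuffle(seq, rng)
        assert shuf != seq
        assert Counter(zip(seq, seq[1:])) == Counter(zip(shuf, shuf[1:]))
        assert shuf[0] == seq[0] and shuf[-1] == seq[-1]


class TestPredictNovel:
    def test_empty_candidates(self, small_libs):
        accepted, rejected = novel.predict_novel([], small_libs)
        assert accepted == [] and rejected == []

    def test_planted_hairpin_recovered_and_flagged_common(
        self, small_ref, small_libs
    ):
        from hypoxamir import annotate

        hp = small_ref.planted_hairpins[0]
        candidates = []
        for cond in ("normoxic", "hypoxic"):
            table = annotate.eliminate_hierarchy(small_libs[cond], small_ref)
            candidates.extend(
                annotate.extract_genomic_candidates(table, small_ref.genome)
            )
        accepted, _ = novel.predict_novel(
            candidates, small_libs,
            known_matures=set(small_ref.mature_mirnas.values()),
        )
        matures = {r.mature for r in accepted}
        assert hp.mature_sequence in matures
        rec = next(r for r in accepted if r.mature == hp.mature_sequence)
        assert rec.common_to_all
        assert rec.mature.replace("T", "U") in rec.precursor

    def test_failing_candidate_lands_in_reject_log(self, small_libs):
        from hypoxamir.annotate import HairpinCandidate

        junk = HairpinCandidate(
            "cand_x", "A" * 22, 1, "c", 0, 162, "+", "A" * 162, 70
        )
        accepted, rejected = novel.predict_novel([junk], small_libs)
        assert accepted == []
        assert rejected and rejected[0].candidate_id == "cand_x"

    def test_min_score_monotonicity(self, small_ref, small_libs):
        from hypoxamir import annotate

        table = annotate.eliminate_hierarchy(
            small_libs["hypoxic"], small_ref
        )
        candidates = annotate.extract_genomic_candidates(
            table, small_ref.genome
        )
        counts = []
        for min_score in (10, 25, 60):
            accepted, _ = novel.predict_novel(
                candidates, small_libs,
                HairpinCriteria(min_score=min_score),
            )
            counts.append(len(accepted))
        assert counts[0] >= counts[1] >= counts[2]
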