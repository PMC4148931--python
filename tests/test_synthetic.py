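"""Generator contracts: determinism, geometry, ground-truth bookkeeping."""

import numpy as np
import pytest

from hypoxamir import synthetic
from hypoxamir.errors import ReferenceLookupError, SizingError

from conftest import SMALL_SIZES


def _bare_profile(ref, **kwargs):
    defaults = dict(
        baseline_mean={n: 0.0 for n in ref.mature_mirnas},
        fold={},
        dispersion=0.0,
        error_rate=0.0,
        seed=3,
    )
    defaults.update(kwargs)
    return synthetic.SimulationProfile(**defaults)


class TestBuildToyReference:
    def test_every_mature_inside_its_precursor(self, small_ref):
        for name, p in small_ref.precursors.items():
            assert small_ref.mature_mirnas[name] in p.sequence

    def test_precursors_placed_at_their_loci(self, small_ref):
        # strand-aware: the oriented genomic slice equals the precursor
        for name in small_ref.precursors:
            assert (
                small_ref.precursor_sequence_at_locus(name)
                == small_ref.precursors[name].sequence
            )

    def test_planted_hre_offsets_upstream_window(self, small_ref):
        assert small_ref.planted_hres, "reference must plant HREs"
        for offs in small_ref.planted_hres.values():
            assert all(-5000 <= o <= -1 for o in offs)

    def test_same_seed_reproduces_files_byte_identically(self, tmp_path):
        sizes = SMALL_SIZES
        dirs = []
        for i in (1, 2):
            ref = synthetic.build_toy_reference(5, sizes)
            d = tmp_path / f"ref{i}"
            synthetic.write_reference_bundle(ref, d)
            dirs.append(d)
        for f in sorted(dirs[0].iterdir()):
            assert f.read_bytes() == (dirs[1] / f.name).read_bytes(), f.name

    def test_infeasible_geometry_raises_sizing_error(self):
        with pytest.raises(SizingError):
            synthetic.build_toy_reference(
                1, synthetic.ReferenceSizes(contig_length=100)
            )

    def test_declared_clusters_obey_ten_kb_rule(self, small_ref):
        for members in small_ref.clusters.values():
            loci = sorted(small_ref.precursors[m].start for m in members)
            gaps = np.diff(loci)
            assert (gaps <= 10_000).all()


class TestSimulateLibraries:
    def test_zero_means_give_empty_libraries(self, small_ref):
        sim = synthetic.simulate_srna_libraries(
            small_ref, _bare_profile(small_ref)
        )
        assert sim.reads == {"normoxic": [], "hypoxic": []}

    def test_unknown_mirna_in_profile_rejected(self, small_ref):
        prof = synthetic.SimulationProfile(
            baseline_mean={"mir-nonexistent": 10.0}, fold={}, seed=1
        )
        with pytest.raises(ReferenceLookupError):
            synthetic.simulate_srna_libraries(small_ref, prof)

    def test_reads_are_insert_plus_adapter_truncated(self, small_ref):
        prof = _bare_profile(
            small_ref,
            baseline_mean={sorted(small_ref.mature_mirnas)[0]: 50.0},
            novel_mean=0.0,
            background_fractions={},
        )
        sim = synthetic.simulate_srna_libraries(small_ref, prof)
        adapter = prof.adapter
        for reads in sim.reads.values():
            for r in reads:
                assert len(r) <= prof.read_length
                # insert is a precursor substring; the rest is adapter prefix
                matched = any(
                    (r[:k] in p.sequence or r[:k - 1] in p.sequence)
                    and adapter.startswith(r[k:])
                    for p in small_ref.precursors.values()
                    for k in range(16, len(r) + 1)
                )
                assert matched  # templated insert (+/- one NTA) then adapter

    def test_total_reads_equal_ground_truth_counts(self, small_sim):
        sim, _ = small_sim
        for cond in ("normoxic", "hypoxic"):
            assert len(sim.reads[cond]) == sim.truth[f"count_{cond}"].sum()
            assert len(sim.reads[cond]) == sum(
                sim.expected_class_counts[cond].values()
            )

    def test_error_free_inserts_trace_back_to_reference(
        self, small_ref, small_sim
    ):
        """At error rate 0 every insert (minus a possible non-templated 3'
        base) is a substring of a reference sequence or the genome."""
        sim, prof = small_sim
        sources = (
            [p.sequence for p in small_ref.precursors.values()]
            + list(small_ref.pirnas.values())
            + list(small_ref.rna_db.values())
            + list(small_ref.genome.values())
        )
        for cond in ("normoxic", "hypoxic"):
            for r in sim.reads[cond][:300]:
                cut = r.find(prof.adapter[:10])
                insert = r[:cut] if cut >= 0 else r
                assert any(
                    insert in s or insert[:-1] in s for s in sources
                ), insert

    def test_identical_profile_reproduces_reads_bit_for_bit(self, small_ref):
        prof = _bare_profile(
            small_ref,
            baseline_mean={n: 20.0 for n in small_ref.mature_mirnas},
            dispersion=0.05,
        )
        a = synthetic.simulate_srna_libraries(small_ref, prof)
        b = synthetic.simulate_srna_libraries(small_ref, prof)
        assert a.reads == b.reads
        assert a.truth.equals(b.truth)

    def test_planted_fold_recovered_at_low_dispersion(self, small_ref):
        """Law of large numbers: count ratio approaches the fold multiplier.

        Expected values derived by independent resampling: with shared
        baselines and Poisson sampling the hypoxic/normoxic total ratio is
        fold +- O(1/sqrt(n)); over several seeds the pooled ratio must sit
        within 20% of the planted 4.
        """
        name = sorted(small_ref.mature_mirnas)[0]
        tot_n = tot_h = 0
        for seed in range(5):
            prof = synthetic.SimulationProfile(
                baseline_mean={name: 100.0},
                fold={name: 4.0},
                dispersion=0.0,
                error_rate=0.0,
                depth_match=False,
                seed=seed,
            )
            sim = synthetic.simulate_srna_libraries(small_ref, prof)
            row = sim.truth[sim.truth["name"] == name].iloc[0]
            tot_n += row["count_normoxic"]
            tot_h += row["count_hypoxic"]
        assert 4.0 * 0.8 <= tot_h / tot_n <= 4.0 * 1.2
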