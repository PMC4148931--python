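import pytest

from hypoxamir import synthetic


SMALL_SIZES = synthetic.ReferenceSizes(
    contig_length=80_000,
    n_mirnas=6,
    cluster_size=2,
    n_hre_mirnas=3,
    n_exons=2,
    n_ncrna=3,
    n_pirna=3,
    n_rna_db=3,
)


@pytest.fixture(scope="session")
def small_ref():
    """A compact reference bundle: 6 miRNAs, one cluster, one planted hairpin."""
    return synthetic.build_toy_reference(7, SMALL_SIZES)


@pytest.fixture(scope="session")
def small_sim(small_ref):
    """Error-free simulation over the small reference (ground truth exact)."""
    profile = synthetic.default_profile(small_ref, seed=7)
    profile = synthetic.SimulationProfile(
        baseline_mean=profile.baseline_mean,
        fold=profile.fold,
        dispersion=0.05,
        error_rate=0.0,
        seed=7,
    )
    return synthetic.simulate_srna_libraries(small_ref, profile), profile


@pytest.fixture(scope="session")
def small_libs(small_sim, small_ref):
    """Preprocessed tag libraries for both conditions of the small simulation."""
    from hypoxamir import preprocess

    sim, profile = small_sim
    libs = {}
    for cond in ("normoxic", "hypoxic"):
        lib, _ = preprocess.preprocess_reads(
            sim.reads[cond], cond, cond, profile.adapter
        )
        libs[cond] = lib
    return libs
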