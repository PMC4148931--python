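#!/usr/bin/env python
"""Generate the synthetic two-condition small-RNA experiment.

Builds the toy reference (30 miRNA loci including a co-regulated cluster,
planted intergenic hairpin, promoter HREs) and simulates the normoxic and
hypoxic adapter-ligated libraries with full ground truth.  Raw FASTQ and
reference files go to scratch/analysis/; the ground-truth table goes to
results/.
"""

from common import RESULTS, SCRATCH, ensure_dirs, reference_and_simulation

from hypoxamir import synthetic


def main():
    ensure_dirs()
    ref, profile, sim = reference_and_simulation()
    synthetic.write_reference_bundle(ref, SCRATCH / "reference")
    for cond in ("normoxic", "hypoxic"):
        synthetic.write_fastq(SCRATCH / f"{cond}.fastq", sim.reads[cond], cond)
    sim.truth.to_csv(RESULTS / "simulated_truth.tsv", sep="\t", index=False)
    sim.truth_isomirs.to_csv(
        SCRATCH / "truth_isomirs.tsv", sep="\t", index=False
    )
    n_n = len(sim.reads["normoxic"])
    n_h = len(sim.reads["hypoxic"])
    mirna = sim.truth[sim.truth["kind"] == "mirna"]
    print(f"simulated {n_n} normoxic and {n_h} hypoxic reads")
    print(
        f"{len(mirna)} miRNAs: "
        f"{(mirna['true_fold'] > 1).sum()} induced, "
        f"{(mirna['true_fold'] < 1).sum()} repressed, "
        f"{(mirna['true_fold'] == 1).sum()} unchanged; "
        f"1 planted intergenic hairpin; "
        f"{sum(len(v) for v in ref.planted_hres.values())} planted HREs "
        f"upstream of {len(ref.planted_hres)} miRNAs"
    )
    print(f"raw data under {SCRATCH}, truth table in {RESULTS}")


if __name__ == "__main__":
    main()
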