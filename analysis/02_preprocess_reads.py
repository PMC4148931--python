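#!/usr/bin/env python
"""Adapter-trim, length-filter (16-35 nt) and collapse both libraries.

Reads the FASTQ files written by 01 (regenerating them if absent), writes
collapsed tag tables to scratch/analysis/ and the read-accounting summary
to results/preprocess_stats.tsv.
"""

import pandas as pd
from common import RESULTS, SCRATCH, ensure_dirs, reference_and_simulation

from hypoxamir import preprocess


def main():
    ensure_dirs()
    _, profile, sim = reference_and_simulation()
    rows = []
    for cond in ("normoxic", "hypoxic"):
        fq = SCRATCH / f"{cond}.fastq"
        if fq.exists():
            lib, st = preprocess.preprocess_fastq(fq, cond, cond, profile.adapter)
        else:
            lib, st = preprocess.preprocess_reads(
                sim.reads[cond], cond, cond, profile.adapter
            )
        preprocess.write_tags_tsv(lib, SCRATCH / f"tags_{cond}.tsv")
        preprocess.write_tags_fasta(lib, SCRATCH / f"tags_{cond}.fa")
        rows.append(
            {"condition": cond, "reads_in": st.n_input,
             "no_adapter": st.n_no_adapter,
             "length_filtered": st.n_length_filtered,
             "reads_kept": st.n_kept, "unique_tags": len(lib),
             "total_clone_count": lib.total_clone_count}
        )
        print(
            f"{cond}: {st.n_input} reads -> {st.n_kept} kept "
            f"({len(lib)} unique tags, clone count {lib.total_clone_count})"
        )
    pd.DataFrame(rows).to_csv(
        RESULTS / "preprocess_stats.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
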