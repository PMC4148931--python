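#!/usr/bin/env python
"""Scan 5 kb upstream promoters of up-regulated miRNAs for HREs (RCGTG).

Promoters are extracted strand-aware from the precursor 5' ends; hits on
either strand are reported as negative upstream offsets.  Writes
results/hre_hits.tsv and prints recall of the planted motifs.
"""

from common import RESULTS, ensure_dirs, tag_libraries

from hypoxamir import annotate, promoter, quantify


def main():
    ensure_dirs()
    ref, _, _, libs, _ = tag_libraries()
    counts = {}
    for cond, lib in libs.items():
        assign = {
            r.tag: r.ref_name
            for r in annotate.match_exact_mature(
                lib, ref.mature_mirnas
            ).records.values()
            if r.class_ == "mature_miRNA"
        }
        counts[cond] = {}
        for tag, name in assign.items():
            counts[cond][name] = counts[cond].get(name, 0) + lib.tags[tag]
    de = quantify.call_differential(
        counts["hypoxic"], libs["hypoxic"].total_clone_count,
        counts["normoxic"], libs["normoxic"].total_clone_count,
    )
    up = sorted(r.mirna for r in de if r.direction == "up")
    table = promoter.scan_mirna_hres(ref.precursors, ref.genome, mirnas=up)
    promoter.write_hre_tsv(table, RESULTS / "hre_hits.tsv")
    promoter.write_hre_bed(table, ref.precursors, RESULTS / "hre_hits.bed")
    with_hre = table["mirna"].nunique() if len(table) else 0
    print(
        f"{len(up)} up-regulated miRNAs scanned; {with_hre} carry >=1 HRE "
        f"({len(table)} total hits within 5 kb upstream)"
    )
    planted = total = 0
    for name, offsets in ref.planted_hres.items():
        found = set(table[table["mirna"] == name]["offset"])
        total += len(offsets)
        planted += len(set(offsets) & found)
    print(f"planted HRE recall: {planted}/{total}")


if __name__ == "__main__":
    main()
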