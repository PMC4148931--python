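#!/usr/bin/env python
"""Catalogue isomiR end variants of the strongly induced miRNA.

Groups end-variant tags (5' shift <= 3 nt, 3' shift <= 4 nt, up to 2
non-templated 3' nucleotides) against each precursor, selects the
highest-count representative, and summarizes per-condition species and
singleton counts.  Writes results/isomir_catalog.tsv and
results/isomir_summary.tsv.
"""

from common import RESULTS, ensure_dirs, tag_libraries

from hypoxamir import isomir


def main():
    ensure_dirs()
    ref, _, _, libs, _ = tag_libraries()
    matures = set(ref.mature_mirnas.values())
    groups_by_cond = {c: [] for c in libs}
    merged = []
    for name in sorted(ref.mature_mirnas):
        pre = ref.precursors[name]
        per_cond = []
        for cond, lib in sorted(libs.items()):
            g = isomir.group_isomirs(
                lib, pre.sequence, ref.mature_mirnas[name],
                precursor_name=name,
                exclude=matures - {ref.mature_mirnas[name]},
            )
            per_cond.append(g)
            groups_by_cond[cond].append(g)
        merged.append(isomir.merge_groups(per_cond))
    isomir.write_isomir_catalog(
        merged, RESULTS / "isomir_catalog.tsv", ["normoxic", "hypoxic"]
    )
    summary = isomir.isomir_condition_summary(groups_by_cond)
    summary.to_csv(RESULTS / "isomir_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))

    star = sorted(ref.mature_mirnas)[0]
    g = next(m for m in merged if m.precursor_name == star)
    rep = g.representative
    print(
        f"{star}: {len(g.variants)} variants; representative "
        f"offsets ({rep.offset5:+d}, {rep.offset3:+d}) with "
        f"{rep.total_count} reads"
    )


if __name__ == "__main__":
    main()
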