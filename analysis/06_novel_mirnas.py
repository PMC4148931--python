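#!/usr/bin/env python
"""Discover novel miRNA hairpins among unannotated intergenic tags.

Exact intergenic tags are extended by 70 nt of flanking genome, folded
with the weighted base-pair DP, and kept when the tag sits on the stem of
a clean single-loop hairpin.  Writes results/novel_mirnas.tsv and the
dot-bracket structures to results/novel_structures.txt.
"""

from common import RESULTS, ensure_dirs, tag_libraries

from hypoxamir import annotate, novel


def main():
    ensure_dirs()
    ref, _, _, libs, _ = tag_libraries()
    candidates = []
    for cond, lib in sorted(libs.items()):
        table = annotate.eliminate_hierarchy(lib, ref)
        candidates.extend(
            annotate.extract_genomic_candidates(table, ref.genome)
        )
    accepted, rejected = novel.predict_novel(
        candidates, libs, known_matures=set(ref.mature_mirnas.values())
    )
    novel.write_novel_tsv(accepted, RESULTS / "novel_mirnas.tsv")
    novel.write_structures(accepted, RESULTS / "novel_structures.txt")
    print(
        f"{len(candidates)} candidate windows -> {len(accepted)} novel "
        f"miRNAs accepted, {len(rejected)} rejected"
    )
    planted = {hp.mature_sequence for hp in ref.planted_hairpins}
    for rec in accepted:
        tag = " (planted hairpin)" if rec.mature in planted else ""
        print(
            f"{rec.novel_id}: {rec.contig}:{rec.start + 1}-{rec.end} "
            f"{rec.strand}, {rec.mature_arm} arm, pair score {rec.score}, "
            f"reads {rec.counts}{tag}"
        )
        print(f"  {rec.precursor}")
        print(f"  {rec.structure}")


if __name__ == "__main__":
    main()
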