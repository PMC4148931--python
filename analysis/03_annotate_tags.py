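#!/usr/bin/env python
"""Run the elimination hierarchy over both tag libraries.

Tags are matched in fixed order (mature miRNA exact, then ncRNA, piRNA,
rRNA/mRNA, exon, intergenic/intronic, each allowing up to 2 mismatches)
and the first matching stage wins.  Full annotation tables go to
scratch/analysis/; per-class read percentages go to
results/annotation_classes.tsv.
"""

import pandas as pd
from common import RESULTS, SCRATCH, ensure_dirs, tag_libraries

from hypoxamir import annotate


def main():
    ensure_dirs()
    ref, _, _, libs, _ = tag_libraries()
    rows = []
    for cond, lib in libs.items():
        table = annotate.eliminate_hierarchy(lib, ref)
        annotate.write_annotation_tsv(table, SCRATCH / f"annotation_{cond}.tsv")
        pct = table.class_read_percentages()
        rows.append({"condition": cond, **{c: round(p, 2) for c, p in pct.items()}})
        top = max(pct, key=pct.get)
        print(
            f"{cond}: most abundant class {top} ({pct[top]:.1f}% of reads); "
            f"miRNA-derived (mature + precursor-matching variants): "
            f"{pct['mature_miRNA'] + pct['ncRNA']:.1f}%"
        )
    pd.DataFrame(rows).to_csv(
        RESULTS / "annotation_classes.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
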