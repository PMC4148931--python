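# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic experiments do and do not
demonstrate about real data.

## Study design being modelled

A single two-condition small-RNA sequencing experiment: one cell culture
split into a normoxic and a hypoxic arm, each sequenced once (no
replicates). All inference is therefore descriptive — fold-change
thresholds rather than variance-model tests — which is why the pipeline
deliberately contains no p-values or multiple-testing control.

## Synthetic data generator

The generator is first-class code: it defines the conditions under which
the pipeline's recovery properties are demonstrated.

**Reference.** One contig (default 200 kb) hosts 30 miRNA hairpin loci:
five promoter-bearing standalone loci (alternating strands), the rest
packed into dense blocks ~1.8 kb apart — real miRNA genes are frequently
clustered, and packing keeps the toy genome small — plus one designated
three-member cluster. Any run of precursors spaced < 10 kb on one strand
is declared a genomic cluster, the same convention `derive_clusters`
implements. The bundle also carries other-ncRNA, piRNA and rRNA/mRNA
collections (random sequences of realistic lengths), exon intervals, one
intergenic hairpin with no mature annotation (the "novel" miRNA), and
RCGTG motifs planted at known offsets within 5 kb upstream of the induced
precursors. The ncRNA collection includes the precursor sequences
themselves, as real ncRNA databases do; this is what routes isomiR end
variants to the ncRNA stage instead of letting them masquerade as novel
intergenic tags.

**Hairpin design.** Precursors are mature + terminal loop +
reverse-complement arm (two substitutions), 3 nt pads. Because the folding
model is pure weight maximization with no stacking thermodynamics, an
unconstrained random hairpin often has a higher-weight alternative
structure that splits the terminal loop. The design therefore makes the
intended stem the unique optimum: a poly-C loop (4 nt; C pairs only G),
A/T-only stem positions in the 8 nt flanking the loop, G/C clamps at the
outer stem end, and arm mismatches kept ≥ 8 nt from the loop and ≥ 4 nt
from the outer end, chosen so any competing pairing strictly loses weight.
This is a property of the synthetic plant, not of the filter: the filter
itself never sees these constraints.

**Counts.** Each species' biological abundance for one experiment is a
single Gamma draw with mean m and variance `dispersion`·m² shared between
the two arms (one culture, split); each arm's read count is then Poisson
around that abundance times the arm's fold multiplier. Marginally counts
are negative binomial (var = m + d·m², d → 0 giving Poisson); critically,
the shared draw means biological variability moves both conditions
together and the planted fold is the only systematic between-condition
signal — the correct model for a split-culture design without replicates.
If instead the two arms drew independent Gamma baselines, the log-fold
noise floor would be √(2d) ≈ 0.32 at d = 0.05 and a bare 1.5-fold
threshold would miscall ~20 % of null species; no caller could do better
on that data.

**Composition.** Sequencing depth is matched between arms (depth is an
instrument setting, not biology), and the default profile gives the
differential species a small share of library mass: nulls draw baselines
of 1000–2000 expected reads, induced species 100–150, the miR-210-like
star 30. TPM is compositional — if induced species carried most of the
mass, their own induction would deflate everyone's relative abundance and
planted folds would be unrecoverable in principle. With the default
composition the hypoxic/normoxic mass ratio is ≈ 1.1, so a planted 4-fold
appears as ≈ 3.6-fold in TPM and nulls sit near 0.9.

**IsomiRs.** The representative (exact mature) takes probability 0.6; the
rest is multinomial over templated 5′ shifts {−1, 0, +1} (0.1/0.8/0.1)
and 3′ shifts {−2…+2} (0.1/0.2/0.4/0.2/0.1), with a 3′ non-templated A/T
appended at rate 0.15. Substitution errors (default 10⁻³/base) are applied
to the insert only; reads are insert + adapter truncated to 50 nt with
constant quality — quality realism, ligation bias and PCR duplicates are
out of scope.

**What passing does not show.** The generator has uniform random
backgrounds, no sequence-composition bias, no expression-dependent
ligation efficiency, exact adapter sequence, and hairpins engineered to be
clean under the weight-maximization folder. Recovery rates here are upper
bounds; on real libraries adapter heterogeneity, repeat-derived
multi-mapping and marginal hairpins will all cost accuracy.

## Pipeline decisions

**Adapter trimming.** A read position matches when the first
`min_overlap` = 8 adapter bases align there with ≤ 1 substitution; the
leftmost match wins and the prefix is the insert. Checking only the
fixed-length seed (rather than the longest available overlap) makes
trimming idempotent: any seed match inside a trimmed insert would already
have been the leftmost match. Reads with no adapter are discarded as
unligated read-through. Length filter bounds [16, 35] are inclusive and
applied after trimming.

**Annotation.** Matching is ungapped with Hamming mismatches only —
indels in 16–35 nt tags are indistinguishable from isomiR end variation.
Transcript databases are searched on the forward strand, exons and genome
on both strands. Stage order: mature (0 mm) → ncRNA → piRNA → rRNA/mRNA →
exon → intergenic/intronic, each stage allowing ≤ 2 mismatches, first
match wins; the exon stage is treated as its own sequence database
(genome slices), mirroring how such pipelines compile an exon set.
Within a stage the winner is chosen by fewest mismatches, then
lexicographic reference name, then leftmost position; all references hit
at the winning mismatch tier are recorded. Coordinates are 0-based
half-open internally, 1-based on GFF/TSV output. Exact matches are found
by plain substring search; only tags without a verbatim occurrence pay
for the vectorized sliding-window mismatch scan.

**Candidate extraction.** Only exact (0-mismatch) intergenic placements
become hairpin candidates — the candidate's mature sequence *is* the tag,
so a mismatched placement would assert a mature the genome does not
encode. Windows are tag ± 70 nt, truncated at contig ends,
reverse-complemented for minus-strand tags.

**Folding.** Nussinov-style maximum weighted matching (GC = 3, AU = 2,
GU = 1; hairpin loop ≥ 3; nested structures only), O(n³) with a
vectorized inner maximization. Traceback is deterministic: at each
interval the 5′-most base is paired with the smallest partner achieving
the optimum, else left unpaired. This replaces thermodynamic folding by
design; it preserves the stem/loop geometry decisions the downstream
filter needs, not free energies.

**Stem-placement filter.** A candidate hairpin passes when (a) weighted
pair score ≥ 25, (b) the structure has exactly one terminal loop of
3–20 nt, (c) the mature does not intersect that loop, (d) ≥ 60 % of
mature positions are paired. Applying these criteria to the raw 162-nt
window fails by construction: under maximum-weight pairing, 70 nt of
random flank always folds into additional terminal loops, so even a
perfect planted hairpin would be rejected as multi-branched. The filter
is therefore evaluated on mature-anchored subwindows: for each arm
hypothesis the window is trimmed to the mature plus a 3 nt pad on one
side and a one-sided extension on the other, stepping by 5 nt up to
mature + 20 (max loop) + pad — beyond which no subwindow can pass anyway.
Some subwindow then overshoots the true partner arm by ≤ 4 nt, too little
flank to fold a spurious loop. A candidate passes if any subwindow passes;
the best-scoring passing structure is reported. Measured on planted
hairpin windows vs dinucleotide-shuffled windows, this gives sensitivity
≈ 1.0 and specificity ≈ 0.85–0.9 at the default thresholds.

**Quantification.** TPM = count/total_clone_count × 10⁶ over the full tag
set (so ΣTPM = 10⁶ per library); RPKM = TPM/L. Differential calls use the
TPM ratio with strict > 1.5 / < 1/1.5 thresholds; equality is unchanged.
The pseudocount (1 read, added to both counts only when either is zero)
gives condition-specific species a finite fold without perturbing
abundant ones. A normalization switch for differential calling is
unnecessary: the mature length cancels in the RPKM ratio, so TPM- and
RPKM-based folds are identical.

**IsomiR grouping.** A tag joins a precursor's group when some 5′ offset
within ±3 nt of the anchor gives a maximal templated prefix whose
unmatched 3′ suffix is ≤ 2 nt and whose templated 3′ offset is within
±4 nt; among admissible placements the longest templated prefix wins
(ties to the smaller |5′ offset|). "A few nucleotides" is not quantified
in the underlying analysis style, so these bounds are configurable. A
non-templated addition that happens to equal the next templated base is
inherently indistinguishable from a templated extension; ground-truth
comparisons are therefore made at the variant-sequence level, where the
two coincide. Tags equal to another miRNA's exact mature are excluded
(exact annotation wins). Condition summaries count a species as expressed
when its count is ≥ 1 and as a singleton at exactly 1; the union row
counts species seen in either condition.

**HRE scan.** Consensus RCGTG (R = A/G) on either strand, overlapping
matches allowed, offsets negative upstream (−1 adjacent to the precursor
5′ end). The pattern is any IUPAC string, so a matrix-based scanner can
replace the consensus without interface changes. A consensus scan finds
more chance hits than a curated matrix scan would; planted-motif recall
is the property under test, not hit-count parity.

**Target consensus.** External prediction programs are inputs, not
re-implementations: named gene sets, combined by a ≥ 3-source vote. The
built-in seed matcher implements the canonical site taxonomy with
priority 8mer > 7mer-m8 > 7mer-A1 > 6mer, mutually exclusive per locus
(A1 = adenine opposite miRNA position 1 in UTR orientation). In the
pipeline's synthetic mode the external sources are emulated as noisy
views of a planted target list (85 % true-positive retention, 10 % decoy
admission), which exercises the combiner, not the external programs.

## Problem sizes

Default synthetic experiments run ~70 k reads over a 200 kb genome with
30 miRNAs; a full pipeline run takes ~10 s and the 20-seed planted-truth
evaluation about two minutes on one core. These sizes were chosen so the
whole analysis, test suite and acceptance evaluation rerun comfortably on
a laptop while keeping per-species counts large enough (nulls ≥ 1000
expected reads) that recovery rates reflect the method rather than
shot noise.

## Known limitations

- No gapped alignment or multi-mapping resolution beyond deterministic
  first-hit assignment.
- The folding DP ignores stacking energies, dangles and G-quadruplexes;
  scores are not free energies.
- Differential calling is threshold-only by design (no replicates to
  power a variance model).
- The exon stage uses exon sequence containment; junction-spanning reads
  are out of scope (no spliced alignment).
- isomiR internal (seed) variants and A-to-I editing are not modelled or
  detected.
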