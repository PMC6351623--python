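# Methods

This note documents the models and procedures implemented in `dripseq`,
the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not establish.

## Intron features

A gene model is the union of its annotated exons (GFF3 gene → mRNA →
exon/CDS; genes with several transcripts are collapsed to the exon
union with a warning, since the analysis operates on one effective
transcript per gene). Introns are the inter-exon gaps of length at
least `min_intron_length` (default 50 bp, inclusive: a 50 bp gap is
kept). Introns are numbered in transcription order, so intron 1 of a
minus-strand gene is the most 3'-in-genome gap. Coordinates are 0-based
half-open internally and converted to 1-based closed only in the GFF3
readers and writers, which round-trip exactly.

## Intersection-strict counting

For every aligned base of a read (all blocks of a spliced alignment),
take the set of features covering that base; intersect the sets. A
singleton assigns the read, an empty intersection (including any
uncovered base) is `no_feature`, two or more features are `ambiguous`.
Because every feature here is one genomic interval, this equals the set
of features containing the whole read, which is how the implementation
computes it; the test-suite checks exact equivalence with a literal
per-base oracle on randomized instances.

Two consequences drive the pipeline layout. First, a read straddling an
exon/intron boundary is never uniquely attributable to the intron: with
the gene indexed as its locus the intersection collapses onto the gene;
with exon intervals it is empty. (Note the contract itself can never
return `ambiguous` for a boundary read — "ambiguous" in the loose,
field-usage sense means "not uniquely assigned".) Second, gene and
intron counting therefore run as two separate passes over two feature
sets: genes only, and a dedicated intron-only set in which boundary
reads simply fall out as `no_feature`. Per-library tallies
(assigned/ambiguous/no_feature) always sum to the number of reads
processed, making the contract auditable.

Only primary alignments are counted; secondary and supplementary
records are skipped. Counting is unstranded by default (strand
non-specific library preparation); a stranded mode exists but is not
the default analysis path. RPK is computed from raw counts —
`count × 1000 / length_bp` — with no depth normalization, because the
low-expression filter precedes the normalization step.

## Filtering, normalization, testing

**Low-count filter.** A feature is removed when its RPK is ≤ 40 in at
least ⌈2n/3⌉ of the n libraries (10 of 15 in the reference design).
Both boundaries are inclusive on the "low" side: RPK exactly 40 counts
as low.

**Size factors.** Median-of-ratios: the per-feature reference is the
geometric mean of its counts across libraries (features positive in
every library only); s_j is the median ratio to the reference, rescaled
to geometric mean 1. If no feature is positive everywhere, the method
falls back to total-count factors with a warning.

**Dispersion.** Method of moments on normalized counts, pooling
within-group variances weighted by degrees of freedom:
α_f = max((var_pooled − mean)/mean², 10⁻⁸). Poisson-like and constant
features land on the floor. No trend fitting and no shrinkage: with
three replicates per group the estimate is noisy, which is the price of
a fully documented, deterministic procedure. The benchmarks show the
resulting test is well calibrated at moderate means and protected at
the study's stringent call thresholds.

**NB Wald test.** Per feature, a log-link NB regression with intercept
and group indicator, log size factors as offsets, fixed α_f, fitted by
IRLS (vectorized across features; 2×2 normal equations in closed form;
β clipped at ±30 on the natural-log scale to survive all-zero groups;
convergence at 10⁻¹⁰, 100 iterations max, non-converged features are
flagged and given p = 1). log2FC = β₁/ln 2; the Wald SE comes from the
inverse expected information at the fit; p is two-sided normal.
Features with all-zero counts in both groups return the null result
(log2FC 0, p 1) — no pseudocounts anywhere. Each mutant-vs-control
contrast is fitted independently; there is no joint multi-group model.

**Multiplicity and calls.** Benjamini–Hochberg adjustment (the
conventional choice where only "adjusted p-value" is specified). A
feature is `up` when log2FC ≥ +1.5 and p_adj < 0.001, `down` when
log2FC ≤ −1.5 and p_adj < 0.001; the fold-change boundary is inclusive
("higher than 1.5 in absolute value" is read as ≥, configurable), the
significance boundary strict. Both thresholds are configurable; the
relaxed |log2FC| ≥ 1 variant is a parameter, not a separate code path.

**A note on exactness.** Scaling one library's counts by c scales its
relative median-of-ratios factor by exactly c, and fold-change
estimates are invariant to such joint rescaling *in the Poisson limit*;
with NB weights the re-weighting of a deeper library leaves a small
residual (≈0.01–0.05 log2 at counts of 50–500), which the property
tests bound rather than ignore.

## Differential retention and borrowed normalization

Intron counts are a small fraction of each library. If size factors
were re-estimated from the intron sub-matrix, a genuine global
retention shift in one strain (most introns up, or down) would be
absorbed into that strain's factors and the per-intron fold changes
driven toward zero. The retention test therefore *borrows* the
median-of-ratios factors computed on the complete gene-level matrix of
the same libraries (a total-mapped-reads alternative is selectable by
config), and never re-estimates them from introns; supplying factors
that do not cover the intron libraries is a hard error. The benchmark
in which every intron of a mutant is retained 4× more while gene
expression is unchanged shows gene-derived factors recover the true
log2FC with ≈0 mean bias while subset-derived factors are biased by
almost the full shift (−2 log2 units).

The intron matrix is pre-filtered with the same RPK filter as the
genes. DR calls use exactly the gene-level criteria. The reported set
is the union of introns DR in at least one mutant; for the
"retention-specific" view an intron is kept (per mutant) only when its
host gene's DE status is `ns`. Hosts removed by the gene-level filter
cannot be certified non-DE, so their introns are excluded — the
conservative reading of an unspecified case.

## Clustering displays

The DR fold-change matrix (introns × mutants, non-significant cells
carrying their estimated fold change) is clustered on rows and columns
with Euclidean distance and complete linkage. Library clustering
discretizes the count matrix into five global quantile levels over the
nonzero entries (zeros form their own lowest level — the scheme is
unspecified upstream, and this choice keeps the all-zero row pattern
informative), runs a correspondence analysis (SVD of standardized
Pearson residuals of the discretized table; zero-inertia axes dropped),
and clusters the library principal coordinates over all retained axes
with Euclidean distance and average linkage. The COA operates on
features × libraries with libraries as columns. Rows are sorted by
label before linkage so tie-breaks are deterministic and the leaf order
is invariant under input permutation; the tested surface is orderings
and merge heights, not colors.

## Parsimony trait mapping

Gene loss is modeled as Dollo: a single origin (present at the root),
losses only. The minimal reconstruction places one loss on each edge
subtending a maximal all-absent subtree; a character absent from every
tip is reported as one loss on the root edge (with a warning). Fitch
small parsimony (set intersection/union, gains allowed) is kept as a
cross-check and can only be ≤ the Dollo count. Both are verified
against exhaustive-enumeration oracles on small trees. Input trees must
be rooted (a root with more than two children is rejected) with unique
tip labels.

The packaged fixture (`data/ejc_species_tree.nwk`,
`data/ejc_traits.tsv`) is **curated data**: a representative rooted
topology of 24 Ascomycota/Basidiomycota taxa and presence/absence calls
for the EJC core factors (MAGO, Y14) and peripheral factors (UPF3, PYM,
Aly/REF, IBP160), transcribed at clade level from published homology
screens of budding-yeast genomes. It is not an inference made by this
package, and analyses depending on within-family branching details
beyond the encoded clades should not rely on it. On this fixture the
MAGO/Y14 pattern yields exactly two losses (the Saccharomycetaceae
ancestor and the CTG + Pichiaceae ancestor) and seven Saccharomycotina
species carry both factors.

## Pfaffl quantification

E = 10^(−1/slope) from the standard-curve slope (slope must be
negative; E is validated to lie in (1, 10]). The relative ratio is
E_t^ΔCt_t / E_r^ΔCt_r with ΔCt = Ct(control) − Ct(sample); with both
efficiencies 2 this is algebraically the 2^−ΔΔCt form. Technical
replicates are averaged on the Ct scale before ΔCt; biological
replicates yield per-replicate ratios compared across groups with a
two-sided two-sample t test (identical degenerate groups return t = 0,
p = 1 by convention).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical* structure the analysis
assumes: five strains × three replicates (15 libraries), per-library
depth multipliers spanning a 1.61-fold range (the relative spread of
real per-sample totals, scaled down so the default run totals ~50–80k
reads per library and finishes in seconds), log-normal baseline
expression, NB count noise at dispersion α = 0.05, a ~30% intron
probability giving ~150 introns of ≥50 bp among 500 genes, per-strain
DE effects, and per-strain retention shifts (upf1-like up, y14-like
down, 8× by default). Baseline retention fractions ρ_i are uniform on
(0.02, 0.15) — introns are minority signals, as in real data. Reads are
single-block, placed uniformly inside their feature, so counting the
stream reproduces the count matrix exactly; an optional boundary
fraction places reads across the 5' junction to exercise the boundary
contract. Spliced (multi-block) reads appear only in counting tests.

Not emulated: sequence content, alignment error, multimapping,
positional coverage bias, correlated gene-gene structure, isoform
mixtures. Passing benchmarks therefore demonstrate that the *pipeline
logic and statistics* behave as designed under the assumed model — not
that the model captures every property of real libraries.

Two named benchmark scenarios pin the recovery claims:
`dr_benchmark_scenario` (200 intron-bearing genes, 25% with an 8×
retention shift, one mutant vs control, 3v3, expression set so tested
introns carry filter-surviving counts — the universe the DR test
actually operates on) and `shifted_mass_scenario` (every intron 4× up
in the mutant, genes unchanged) for the borrowed-normalization
contrast. On these, sensitivity at the study thresholds is ≥ 0.9,
false-call rates ≤ 0.02, direction concordance ≈ 1.0, and the Wald
type-I error on 2,000 model nulls at known α sits within [0.035,
0.065] of the nominal 0.05.

## Pipeline and determinism

One root seed drives everything; the generator stream-splits it per
stage (annotation, counts, reads use distinct derived seeds). A fixed
config yields byte-identical output tables. Each stage writes TSV
intermediates so stages can be re-run from files; counting can be
routed through the simulated SAM/assignment stage (`count_from_reads`)
or taken directly from the generator (default, exact by construction —
the equality of the two routes is itself a test). Stage failures abort
with the stage name. The headline limitations to keep in mind: no
dispersion/fold-change shrinkage (three-replicate designs with weaker
effects than the benchmarks will have less power than shrinkage-based
tools), two-group contrasts only, and single-interval features only in
the counter (exonic multi-interval gene features are representable but
gene counting here uses the locus span, matching the "complete gene
loci" convention).
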