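# Methods

## Regions and coordinates

All coordinates are 0-based half-open (BED convention); refFlat input maps
directly, BED12 blocks are expanded on read. The gene body is the transcript
span [txStart, txEnd) in transcribed orientation; the promoter is
TSS − `promoter_up` … TSS + `promoter_down` (default ±500 bp; set
`promoter_up=1000` for a −1000/+500 variant); flanks of `flank_bp` (default
5 kb) sit 5' of the TSS and 3' of the transcript end. Intervals are clipped
at position 0; a fully clipped flank becomes an *empty* region with a
warning, never a failure. Transcripts are kept per-record (no collapsing by
symbol); overlapping genes each receive every probe independently, matching
the per-gene-summary design of the analysis. CpG density is the count of
"CG" dinucleotides divided by region length and scaled to counts per kb; it
is strand-independent because CpG is self-complementary.

## Probe handling

A probe belongs to a region when its midpoint `floor((start+end)/2)` lies in
the region (an any-overlap mode exists behind `membership="overlap"`).
Midpoint membership avoids double-counting probes that straddle region or
bin boundaries, which matters because all summaries are *unweighted probe
means* — tiling probes are near-uniform in length, so length weighting would
change nothing but the arithmetic. A region with fewer than `min_probes`
probes (default 1; 5 for correlation analyses) yields a *missing* summary,
never zero, and missing genes are excluded from any classification
denominator. Duplicate identical probe intervals are collapsed by mean with
a warning; unsorted input is sorted silently.

## Coverage classification and statistics

A probe is positive when its log2 ratio is **strictly** greater than
`theta_pos` (default 1.0; a probe exactly at the threshold is not positive).
A gene is marked when its positive-probe fraction is **at or above**
`theta_cov` (default 0.20). Coverage is defined over probes rather than
base pairs; on a uniform probe grid the two definitions coincide.

Co-occupancy of two marks is a 2×2 cross-classification over the genes with
defined coverage for both. The chi-square test is Pearson's without
continuity correction, df = (r−1)(c−1); a zero margin is an error that
points to the Fisher exact test, and a warning recommends Fisher whenever an
expected cell is below 5. The Fisher test is two-tailed by the
probability-mass rule (sum of same-margin tables whose hypergeometric
probability does not exceed the observed table's); other two-tailed
conventions can differ in the third decimal. Pearson correlations drop
incomplete pairs, require n ≥ 3 and non-constant vectors, and take p from
the two-sided t distribution with n − 2 df. Group comparisons of per-gene
summaries use all pairwise two-sided Mann–Whitney U tests with Bonferroni
correction over the number of pairs; the choice of Mann–Whitney + Bonferroni
is this package's decision for an otherwise unspecified multiple-comparison
step.

## Metagene profiles

Each gene yields a 40-bin oriented vector: 10 flank bins × 5 kb upstream,
20 body bins, 10 flank bins downstream, index 0 always 5'-most. With body
length L, the first (L mod 20) bins from the 5' end get one extra base, so
bins tile the body exactly; flank bins use the same rule (5000/10 divides
evenly). Minus-strand genes are computed in genomic space and
orientation-reversed, which is identical to binning in transcript space.
Empty bins are missing, not zero; composite profiles average each bin over
the genes that have a value there and report per-bin n and SEM, so a
composite of a group equals the n-weighted merge of composites of any
partition of the group.

Heatmap matrices concatenate the per-mark bin vectors; rows are ordered by
agglomerative hierarchical clustering (average linkage, Euclidean distance)
computed jointly across all marks, with missing bins imputed as column means
for the distance computation only and rows pre-sorted by gene id as the
deterministic tie-break. The display transform (centering each mark at its
chromosome-wide mean probe signal, saturating at ±2 log2 units) never feeds
statistics. Average linkage was chosen for determinism; the linkage and
metric are configurable.

## Exon-level and differential analysis

Exon strata use order-statistic (type-1) quantiles: with n exons and
quantile q (default 0.15), the k = ⌈qn⌉ lowest/highest intensities form the
low/high strata, ties at the threshold included; if the two thresholds
collapse (e.g. all intensities equal) the assignment is flagged degenerate
and no extremes are set. First/last exons and first/last coding exons are
transcriptional (strand-aware); coding exons are exons intersected with the
CDS, and genes need at least two (coding) exons for first/last rows. Introns
are the gaps between consecutive exons. Differential status between two
conditions is threshold-only: Δ = log2(b) − log2(a), up iff Δ ≥ 0.5, down
iff Δ ≤ −0.5 (inclusive), because the exon-array inputs carry no replicate
structure to support variance moderation. Boxplot exports carry
{min, Q1, median, Q3, max, n}.

## Synthetic data: what it emulates and what it does not

The generator plants the study conditions directly: four gene classes in a
55/20/15/10 mix —

| class | body CpG/kb (mean±sd) | body marks planted | promoter | expression log2 |
| --- | --- | --- | --- | --- |
| METH_ACTIVE | 25 ± 5 | MIRA, H3K36me3 (amp 2.0) | CpG island, UMC+, MIRA−, H3ac+ | 8.0 ± 1.0 |
| ZNF_LIKE | 6 ± 2 | H3K9me3, H3K36me3 (amp 2.0) | methylated (MIRA+) | 5.0 ± 0.8 |
| POLYCOMB | 20 ± 5 | H3K27me3 (2.0), UMC (2.0), MIRA 0.3 | CpG island, UMC+ | 4.0 ± 0.8 |
| INERT | 10 ± 3 | none | baseline | 5.5 ± 1.0 |

Probes sit on a uniform 100-bp grid (50-bp probes); each probe's value is
the sum of the per-gene piecewise-constant role amplitudes covering its
midpoint (promoter overrides the gene's own body amplitude near the TSS)
plus Gaussian noise (default SD 0.5 log2 units, homoscedastic). UMC is
constructed anticorrelated with MIRA at promoters. H3K36me3 body amplitude
is coupled to gene expression (0.3 log2 of signal per log2 of expression
around the class mean), the elongation-mark behaviour that plants the
exon-stratum contrast. The knockout ("DKO") condition sets promoter MIRA to
baseline, scales body MIRA by 0.4, scales ZNF-body H3K9me3 by 0.3, and
shifts ZNF expression by +0.8 log2 with per-condition expression noise SD
0.1. With amplitude 2.0 and noise 0.5 a single probe is miscalled with
probability Φ(−2) ≈ 0.023, so the ≥20% coverage rule recovers the planted
mark set of essentially every gene (each gene has ≥ 60 body probes); the
POLYCOMB "partial methylation" amplitude of 0.3 was chosen low enough that
it never crosses the positivity threshold in aggregate.

Generator design choices: genes are assigned to classes by exact
largest-remainder allocation with a seeded shuffle rather than multinomial
sampling, so planted proportions hold exactly and recovered proportions
measure classification error, not assignment noise. Gene lengths (uniform
6–16 kb) are rounded down to a multiple of 20 so default body bins have
equal sizes in either orientation, making strand reversal an exact symmetry
on the fixture. Sequences are random ACGT with all accidental CG
dinucleotides broken, then exact CpG budgets placed per region (islands
80/kb over promoters of island classes, per-gene body targets, 8/kb
intergenic), so realised body densities track their targets within a few
percent. Everything derives from one integer seed via stage-tagged
generators; identical config + seed gives a byte-identical bundle.

Not modelled: array heteroscedasticity and dye effects, masked repeats and
gaps in the probe grid, realistic nucleotide composition beyond CpG control,
alternative promoters, and read-level noise. Passing tests on this generator
demonstrate that the analysis code implements its contracts and recovers
planted structure; they do not certify performance on real arrays, where
probe response is non-uniform and classes are not cleanly separable.

## Numerical choices and scale

Default problem sizes: the flagship fixture uses 1000 genes (~16 Mb
chromosome, ~160k probes × 7 marks × 2 conditions), which the full test
suite and the acceptance script process in well under a minute each; unit
tests use 30–120-gene datasets. Oracles in the test suite are independent
re-implementations: per-base bin lookup tables for binning, brute-force
midpoint scans for probe assignment, closed-form Pearson chi-square and full
hypergeometric enumeration for the 2×2 tests (all tables with margins ≤ 12,
tolerances 1e−9 and 1e−7). The statistical primitives themselves are
delegated to scipy (`chi2_contingency(correction=False)`, `fisher_exact`,
`pearsonr`, `mannwhitneyu`, `cluster.hierarchy`); the coverage
classification, binning geometry, region derivation, CpG accounting and the
generator are implemented here.

## Known limitations

Per-transcript (not per-symbol) reporting can double-count genes with
multiple isoforms when annotation input contains them. The pipeline is
single-threaded; stage results are independent of evaluation order by
construction. No genome-wide multiple-testing is applied across arbitrary
mark pairs, no peak calling, no CpG-island calling (density only), no
liftover, and differential expression has no significance model beyond the
|Δlog2| threshold.
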