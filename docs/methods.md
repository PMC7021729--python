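# Methods

This note documents the models behind each analysis stage, the synthetic
data they are validated on, the parameters that matter, and the numerical
choices made where the design was genuinely open.

## The scenario

The package models a young allotetraploid grass genome: one diploid
ancestor whose descendant lineages (the future A and B subgenomes) diverge
`t_divergence` years before present (default 5.0 Myr), evolve
independently, and merge into a single tetraploid nucleus `t_merger` years
ago (default 1.1 Myr). After the merger the two subgenomes coexist with
little structural interaction: limited gene loss, no homoeologous exchange
by default, and a mild expression bias toward one subgenome.

## Synthetic data generator (`polysub.simulate`)

**Mutation process.** All sequence evolution is Jukes–Cantor-like: a site
differs from its ancestor after time *t* with probability
`¾(1 − e^(−4μt/3))`, and a substituted site takes one of the three
alternative bases uniformly. These marginals compose correctly over
lineages, so the Jukes–Cantor correction applied downstream is the exact
inverse of the generating process in expectation.

**Coding sequences.** Genes are built from fourfold-degenerate codon
families (Ala GCN, Gly GGN, Pro CCN, Thr ACN, Val GTN) plus a fixed
ATG/TAA. Third codon positions then carry exactly one synonymous site per
codon and first/second positions are nonsynonymous, so the generator's
site bookkeeping coincides with NG86 site counting without approximation:
third positions substitute at `mu_neutral`, first/second at
`mu_neutral × ka_ks_true` (default ω = 0.2), and substitutions that would
create a stop codon are redirected. This is a deliberate idealization —
real codon usage mixes degeneracy classes — chosen so that closed-form
expectations (E[Ks] = 2·μ·t) are exact test oracles rather than
approximations. A small fraction of codons drifts out of the fourfold
families via nonsynonymous changes; at ω = 0.2 the effect on recovered Ks
is ≲2%.

**Gene complement.** Per subgenome, each gene is lost with probability
`fractionation_rate_{A,B}` (default 0.02); a lost gene leaves a pseudogene
remnant (frameshift deletion + extra substitutions) with probability
`pseudogene_fraction` (default 0.5). Retained genes seed tandem arrays with
probability `tandem_rate` (sizes uniform on 2..15); segmental inversions
reverse gene order and strand. Truth tables record status, homoeolog
partner, and array membership for every gene.

**LTR retrotransposons.** Each family has a subgenome restriction (A, B, or
shared) and an activity window; element ages are drawn uniformly in the
window (the real age distribution within a family is unknown — this is a
config knob). An element's two terminal repeats start identical and each
accumulates substitutions at `mu_ltr` for the element's age, giving
E[K] = 2·μ·age. The packaged landscape has six specific families (five A,
one B) whose windows end at the merger, plus four shared families, three
active after the merger — the qualitative structure of the published teff
landscape at reduced scale (10 families, 360 elements vs 65 families).
Default LTR length 500 bp.

**Satellites.** Two monomer lineages are derived from one random 159 bp
monomer at `satellite_clade_divergence` (default 10%, i.e. 5% per lineage);
each chromosome receives one array of its subgenome's monomer, copy number
uniform on 22–824 (the published range), each copy independently mutated at
`satellite_copy_noise` (default 2%).

**Expression atlas.** Per homoeolog pair, a log-normal baseline mean
(natural-log sd 1.0, median ≈ 80 counts) shared by both homoeologs, with a
per-tissue log-normal factor (sd 0.2) and per-sample library factors
uniform on 0.7–1.3 (exercising normalization). A fraction `frac_biased`
(default 0.30, matching per-tissue significant shares of ~26–36% in
published atlases) of pairs receives a `effect_size_log2` (default 1) shift
on one homoeolog — toward B with probability `prob_bias_toward_B` (default
0.56) — in all tissues; `frac_consistent_across_tissues` (default 0.869) of
biased pairs keep the direction everywhere, the rest flip it in 1..5
tissues. Counts are negative binomial (gamma–Poisson) with NB2 dispersion
`atlas.dispersion` (default 0.05, a typical well-replicated bulk RNA-seq
value).

**What the generator does not emulate.** Read-level artifacts (mapping
bias, multi-mapping between homoeologs), indel evolution in genes,
transposition bursts nested inside arrays, GC-content heterogeneity,
dispersion–mean trends, and correlated expression across tissues. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated generative model, not robustness to every artifact of real data.

**Determinism.** One `numpy` Generator seeded from `SimConfig.seed` drives
stage 1; stages 2–4 use children derived via `SeedSequence([seed, k])`.
Identical configs give byte-identical output files.

## Satellite phasing (`polysub.satellites`)

Array detection scores each lag p in 20–400 bp by the fraction of positions
matching at offset p (vectorized autocorrelation) in 3 kb windows; any two
copies of a noisy monomer agree equally in expectation, so every multiple
of the true period scores alike and the period is the smallest lag within
0.02 of the window maximum (threshold 0.5 against a ~0.25 random
background). Merged window runs are refined on the per-position match
profile (smoothed over one period, kept while ≥ 0.5) and the consensus is
the column-majority over the chopped copies after circular register
alignment (minimum-Hamming rotation, ties to the smallest offset;
majority ties break A<C<G<T).

Phasing registers all consensus monomers to the lexicographically smallest
chromosome's, computes pairwise p-distances, builds a neighbour-joining
tree (scikit-bio), and evaluates every internal bipartition with ≥2 tips
per side by its between/within mean-distance ratio; the best split defines
the clades. The clade containing the smallest chromosome id is labelled A
(the tree is unrooted — no outgroup exists for a repeat phylogeny — so the
best-ratio split plays the role of the root, and the result records
support rather than a rooting). Support is the fraction of 100
column-bootstrap replicates reproducing the same bipartition. Phasing
refuses (raises) when consensuses are identical, when the between-clade
distance does not exceed the within-clade distance, or with fewer than
four chromosomes.

## LTR dating (`polysub.ltr`)

K between an element's repeats is the raw p-distance over non-gap columns
of a global alignment (match 1, mismatch −1, gap open −4, extend −1) — raw
rather than JC-corrected because insertion-time work conventionally uses
percent identity; `jc_correct=True` is available for sensitivity analysis.
Intactness requires the aligned non-gap span to cover ≥ 50% of the longer
repeat (both repeats recovered). Families report only with ≥ 5 intact
members (`min_copies`), and a family is subgenome-specific when all intact
members carry one subgenome label.

**Polyploidy bracket.** The target quantity is the youngest time at which
any subgenome-specific family was still active — an upper bound on the
merger age. Each element's date carries binomial error
`sd ≈ sqrt(K(1−K)/L)/(2μ)` (≈ 0.28 Myr for 500 bp repeats at K ≈ 0.03), so
the strict minimum over hundreds of elements is downward-biased by several
hundred kyr and is not a usable floor. Instead the floor is estimated by
single-parameter maximum likelihood under the convolved-edge model: near a
sharp boundary F with locally constant age density, the observed
(noise-convolved) density is ∝ Φ((x−F)/σ), and conditioning on the lower
40% of the sample cancels the density constant. σ comes from the
per-element binomial errors of the youngest quartile. The estimator
degenerates to the strict minimum when σ = 0 or fewer than 20 elements are
available, and approaches linear quantile extrapolation when σ is small
relative to the window; on the packaged landscape it recovers the merger
with sd ≈ 0.09 Myr and no detectable bias. `floor_quantile` forces a fixed
pooled quantile instead (0 = strict minimum).

## Synteny and fractionation (`polysub.synteny`)

Homology candidates share ≥ 15 13-mers (k-mers hitting > 100 genes are
skipped as repeats); candidates are scored by global alignment and filtered
by C-score ≥ 0.99, which keeps near-reciprocal-best (recent homoeolog)
pairs and discards paralogs from older whole-genome duplications. Chaining
extracts, per chromosome pair, the best strictly monotone anchor chain
(either orientation; consecutive anchors ≤ `max_gap` = 25 ranks apart in
both dimensions — the published tooling leaves this implicit, so it is an
explicit config here) by O(n²) dynamic programming, repeatedly until no
chain of ≥ `min_block` = 5 anchors remains; each anchor is used once. 1:1
resolution keeps the highest-scoring anchor per gene (ties to the smaller
partner rank). Tandem gene arrays are single-linkage clusters of
within-chromosome hits at rank distance ≤ 10. Retention classes are
pair / gene+pseudogene / single, with pseudogene partners supplied as
annotations (the package does not call pseudogenes). Biased fractionation
is an exact two-sided binomial test on the per-subgenome loss counts
(null 0.5). Syntenic depth counts block spans covering each reference gene
rank — 2:1 from a diploid reference's view of a tetraploid.

## Ka/Ks and the exchange scan (`polysub.molevol`)

NG86 is used instead of ML codon models: transparent, dependency-free, and
adequate at Ks ≈ 0.15 (divergences well below saturation). Site counts are
fractional per codon (mutations to stops counted nonsynonymous); difference
counts average over all orderings of the differing positions, excluding
pathways through stops unless all are blocked; transitions and
transversions weigh equally (no κ). ps/pn ≥ 0.75 flags saturation (rates
NaN); ω is reported missing when Ks = 0. Codon-aware alignment is a global
BLOSUM62 protein alignment (open −10, extend −0.5) back-threaded onto
codons; gap columns are excluded and pairs with > 50% gaps or internal
stops are skipped. Pairs need ≥ 30 ungapped codon columns.

`ks_distribution` reports the median, a histogram, and the number of
kernel-density peaks (Silverman bandwidth, peaks with prominence ≥ 5% of
the density maximum). `scan_homoeologous_exchange` slides windows of 50
pairs (step 25) along each chromosome and flags windows whose median Ks
falls below 0.5× the genome-wide median — a recent segmental replacement
resets divergence to ~0, so flagged windows mark candidate homoeologous
exchanges. Window, step, and threshold are config (no published standard
exists for them).

## Expression bias (`polysub.expression`)

Counts are normalized by median-of-ratios size factors over the full
matrix. HEB = log₂((Ā+pc)/(B̄+pc)) with pseudocount 1 (the sign convention:
positive = A-dominant). Significance is a Wald test on the log mean
difference under NB2: variance of the log mean per side is
`1/(n·m) + α/n` by the delta method. The dispersion α is the larger of the
pair's pooled moment estimate and a matrix-wide estimate — the mean of
unclipped per-gene moment estimates over well-expressed genes, inflated by
n/(n−1) because the raw moment estimator is downward-biased at small n
(sample mean and variance are positively correlated for counts). The
statistic is referred to the standard normal; the dispersion floor and
inflation keep the empirical type-I error at or below the nominal 0.05
across dispersions 0.01–1 with three replicates, which the test suite
checks directly. BH correction is applied within tissue by default
(`bh_scope="global"` switches to one family); pairs with both normalized
means below 1.0 are `not_expressed` and excluded from testing.

Dominance: a pair significant in ≥ 1 tissue is consistent if all its
significant tissues share one direction, reversing otherwise. Detection
misses inflate the consistent share slightly (a reversal in an
undetected tissue is invisible); at the packaged power (~0.5–0.7) the
inflation is 1–3 points. Per-chromosome tallies carry a sign test
(binomial on A vs B counts) and a Wilcoxon signed-rank test of significant
HEB values against zero. The Ka/Ks comparison stratifies pairs into
never-biased / biased-in-all-tissues / intermediate and compares ω between
the extremes by two-sided Mann–Whitney (strata under 10 pairs are
skipped).

## Pipeline sizes

The bundled end-to-end runs and recovery tests use reduced problem sizes
chosen to keep the full suite fast while leaving comfortable statistical
margins: 1,000 homoeolog pairs of 300 codons for Ks recovery (Monte-Carlo
sd of the median ≈ 0.002), 360 LTR elements in 10 families for the
polyploidy bracket, 20 chromosomes with 60–250 satellite copies for
phasing, and 5,000 pairs × 10 tissues × 3 replicates for the expression
atlas. These are the package's standard demonstration conditions; all sizes
are config fields.

## Known limitations

- NG86 underestimates Ks relative to ML codon models at high divergence or
  strong codon bias; within the simulated regime (Ks ≈ 0.15) the two agree
  within a few percent.
- The homology search is k-mer seeded and tuned for ≥ ~85% identity
  homoeologs; it is not a general-purpose aligner and will miss very
  diverged or heavily rearranged orthologs.
- The satellite detector assumes monomer length within the scanned period
  range and arrays long enough to fill a window; higher-order repeat
  structure (dimers scoring as the fundamental) is resolved toward the
  smallest near-maximal period.
- The NB Wald test omits dispersion shrinkage across genes (trend
  fitting); it is deliberately conservative instead, at some cost in power
  versus shrinkage-based testing.
- The polyploidy bracket assumes specific-family activity windows end at
  (not before) the merger when interpreting the floor as the merger date;
  if all specific families stopped amplifying earlier, the bracket is only
  an upper bound.
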