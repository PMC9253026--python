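# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic communities do and do not
emulate, and the numerical decisions taken where the design was open.
Coordinates are 0-based half-open internally; every file written (SAM,
GFF3, TSV) is 1-based per its format convention.

## Read filtering and pileups

A read is retained iff (i) its mate maps to the same scaffold, (ii) its
identity — 1 − NM/aligned-length, recomputed against the reference when
the NM tag is absent — is ≥ `min_identity` (default 0.96, with a 0.98
"ANI sensitivity" re-run supported via `FilterConfig.ani_mode` /
`min_identity` override), and (iii) mapping quality is strictly > 1.
Each dropped read is attributed to exactly one reason, checked in the
order missing-mate → other-scaffold → identity → mapq, so filter reports
partition the input. Pileups count bases with quality ≥ 20. Where mates
of one fragment overlap, the shared positions are counted **once**, the
higher-quality base winning (first mate on ties); whether original
strain-analysis pipelines count such bases once or twice differs between
tools, so `count_overlap_once=False` restores per-read counting. Only
gapless (all-M) alignments are supported; indel-aware pileups are out of
scope.

## SNP calling

On a (possibly population-pooled) pileup, a site is called when the
second-most-frequent allele has frequency strictly > 5% of the top-two
allele count *and* a one-sided binomial test rejects sequencing error:
P(X ≥ k | n, ε) < α with ε = 10⁻³ and α = 10⁻⁶. With 10⁶–10⁹ tested
sites this bounds the expected number of false segregating sites at order
one — the validation suite verifies 0 calls on an error-only megabase at
100×. Sites are reduced to their top two alleles; third-allele counts are
excluded from frequency denominators because all downstream statistics
(LD, F_ST) are biallelic. A 20× minimum coverage gate is applied at call
time, matching the coverage floor used for π and F_ST. Both ε and α are
configuration, since the error model of any given sequencing run differs.

Coding effects substitute the minor allele into the reference codon
(reverse-complemented for −-strand genes) and translate both with the
bacterial code (NCBI table 11); genes whose length is not a multiple of 3
are flagged partial and excluded from N/S tallies. Codons containing a
second SNP are classified against the reference codon — a deliberate
simplification that avoids phasing; at the simulated densities double-hit
codons are rare. A SNP inside overlapping genes is classified once per
gene occurrence and tagged (`n_genes`).

## Nucleotide diversity

π at a site is the without-replacement pair probability
Σ_{b≠b′} n_b n_{b′}/(n(n−1)), not 1 − Σf²: the n/(n−1) form is unbiased
under coverage subsampling, which `subsample_pi` checks directly
(depth-20 subsamples of depth-100 columns agree with the full column
within Monte-Carlo error at 200 reps). Only positions with ≥ 20× qualify.
Per-gene π averages per-site π over **all** qualifying positions of the
gene body, monomorphic positions contributing zero (a `snp_sites_only`
switch restores segregating-sites-only averaging, since published
pipelines vary here); genes with no qualifying position report missing.
Category and genome summaries are unweighted means over genes, so the
overall mean equals the gene-count-weighted mean of category means.
Group comparisons use Welch t tests with Bonferroni adjustment across the
family of comparisons.

## Linkage disequilibrium

Haplotypes are observed only on sequenced fragments: a fragment (read or
mate pair) observes a SNP when either mate reports a ≥ Q20 base there;
mates disagreeing at a site void that site for the fragment. For each SNP
pair spanned by ≥ 30 such fragments (`min_span`, switchable), the four
haplotype counts give D = p_AB − p_A p_B, r² = D²/(p_Aq_Ap_Bq_B) and
D′ = |D|/D_max with D_max = min(p_Aq_B, q_Ap_B) for D > 0 and
min(p_Ap_B, q_Aq_B) for D < 0. D′ is reported unsigned because its use
here is the recombination indicator D′ < 1 (all four haplotypes present).
Fragments carrying a non-major/minor allele at either site are discarded
for that pair. Distances are reference distances between SNP positions;
pairs are restricted to one scaffold and (by default) ≤ 1 kb, which also
bounds the quadratic pair enumeration. Summaries report the distance-
binned decay profile, mean r² and D′, the fraction of pairs with D′
strictly < 1, and r²_N/r²_S — the mean r² over nonsynonymous–nonsynonymous
pairs divided by that over synonymous–synonymous pairs (missing when a
class is empty). Note r² ≤ D′ does **not** hold in general; only the
[0, 1] range bounds are invariants.

## Differentiation and sweeps

Per site, Hudson components with sample-size correction:
num = (p₁−p₂)² − p₁q₁/(n₁−1) − p₂q₂/(n₂−1), den = p₁q₂ + p₂q₁, computed
at the union of sites called segregating in either population, with both
populations ≥ 20× (the two alleles are the top two by combined count).
Gene and genome F_ST are ratios of averages Σnum/Σden — never averages of
ratios, which are downward-biased. Negative values are preserved, not
clamped. Genes whose mean coverage exceeds the across-gene mean + 2 SD
are excluded (mismapping/copy-number guard; low coverage is already gated
at 20×).

The sweep scan computes, per bin and pair, a threshold
T = mean + 1.5 SD over the non-missing gene-F_ST series, slides a 5-gene
window (step 1, missing-F_ST genes skipped, scaffold boundaries never
crossed), seeds a region at every window with mean > T and merges
overlapping qualifying windows — equivalently, a region ends where the
running window mean drops below T. SD uses ddof = 1; a constant series
therefore yields no regions. Regions are *confirmed* sweeps only when
member-gene π is significantly below all other genes (one-sided Welch,
lower) **and** member-pair r² is significantly above background pairs
(one-sided Welch, higher), both at α = 0.05; regions with fewer than two
member genes or pairs on either side stay `high_fst` with the reason
recorded. Region reports tally member N/S counts, since sweeps driven by
beneficial nonsynonymous variants show elevated N/S.

## Replication index

Mean coverage in 5 kb windows sliding by 100 bp (published convention for
this estimator family) is sorted ascending; the lowest and highest 5% are
trimmed, remaining zero windows dropped and counted, and log2 coverage is
regressed on rank fraction over the **full** [0, 1] range, so trimming
does not shrink the estimate. Because the centres of n sliding windows
span only step·(n−1) of the step·(n−1)+window bp they summarise, the raw
slope is scaled by (step·(n−1)+window)/(step·(n−1)); without this the
origin/terminus ratio is systematically understated by window/L. iRep =
2^slope; uniform windows give exactly 1.0, and multiplying all coverages
by a constant leaves the estimate unchanged to machine precision. The
replicating fraction is clamp(iRep − 1, 0, 1): 2.0 means the whole
population replicating, 1.25 a quarter. Caveat: sampling noise in the
sorted quantiles puts a floor under the estimate — on a 30 kb bin at 50×
a non-replicating population reads ≈ 1.1, not 1.0; estimates on short
low-coverage bins carry a `low_coverage`/`poor_fit` flag and values below
≈ 1.1 should be treated as "no detectable gradient". No GC-bias
correction is applied (the synthetic communities have none); a
user-supplied per-window correction can be applied to the coverage track
before windowing.

## Synthetic communities

The generator emulates the data regime the pipeline targets: a few genome
bins, 150 bp paired-end alignments (insert 350 ± 40 bp), per-base error
10⁻³ at constant Q37, depth ~50×, populations sampled along a gradient.
Defaults are genome-wide π = 0.01 and background F = 0.05 — the high-
microdiversity, weak-background-differentiation regime typical of dense
environmental populations.

**Frequencies.** Segregating sites are uniform over the genome; their
count is set so the expected genome-wide per-site heterozygosity of the
realized haplotype pool equals `within_diversity` (the calculation
includes the (1−F) within-population factor and the 1−1/n_hap finite-pool
factor). Ancestral frequencies follow a configurable law (default
U(0.05, 0.95)); per-population frequencies are Balding–Nichols
Beta(p(1−F)/F, (1−p)(1−F)/F) draws, F = 0 degenerating to exactly p. F
may be scalar or per-population; pairwise F_ST between populations with
parameters F_a, F_b is (F_a+F_b)/2 in expectation, which is how the
gradient experiment encodes a monotone differentiation series.

**Haplotypes and reads.** Each population carries n_hap = 24 haplotypes;
each haplotype holds the alternate allele independently per site with the
population frequency. Fragments copy one haplotype with
Poisson(`crossover_rate`) template switches at uniform positions — higher
crossover rates decay LD faster, and with no crossovers LD reflects the
finite pool (baseline r² ≈ 1/n_hap from chance associations, plus ≈
1/n_span sampling inflation). Read pairs are placed uniformly (or under a
log-linear origin→terminus density when `coverage_ratio` > 1) and emitted
directly as coordinate-correct sorted SAM with exact NM tags — no
external aligner, so filter behaviour is exactly testable; a FASTQ
emitter exists for end-to-end runs with a real aligner.

**Planted sweeps.** Sites in a sweep interval are drawn at the elevated
`f_high`; in every population one dominant haplotype — all-alternate in
population 0, all-reference elsewhere, so populations diverge — receives
fragment weight 1 − `diversity_factor`, and crossover donors inside the
interval are drawn from the same weights (a recombination donor in a
swept population is itself usually the dominant lineage; without this the
sweep signature is badly diluted). Any fragment whose span intersects the
interval uses the sweep weights, avoiding edge dilution over the first
insert length. With `diversity_factor` = 0.1 this reduces within-
population heterozygosity in the interval to roughly a third of
background (the residual comes from the 10% escape mass carrying the
Balding–Nichols field) and drives member-pair r² to several times
background — the two signals the confirmation test requires.

**Determinism.** All randomness derives from one seed through keyed
`SeedSequence` substreams per (stage, bin, population, sample), so
identical configs give bit-identical outputs and per-bin output is stable
under unrelated config edits.

**What is not emulated** — and hence what passing tests cannot vouch for
on real data: indels and structural variants, chimeric/duplicate reads,
GC–coverage bias, quality-score variation, mapping ambiguity between
related bins (reads are emitted at their true coordinates, so identity
filtering is exercised but mismapping is not), and any realistic
demographic history — Balding–Nichols is a variance model chosen for
testability, not a claim about real population history.

## Validation experiment sizes

The standardised experiments in `strainpop.validation` use: F_ST recovery
at 5000 sites × 50 reads (frequency-level, recovering F = 0.1 within
±0.02 — read-level recovery additionally carries the finite-pool
inflation ≈ 1/n_hap in (p₁−p₂)², visible in the gradient experiment's
absolute values and not removed by the read-depth correction); caller
specificity on 1 Mb at 100×; sweep recovery on a ~100-gene 100 kb genome
(genes 720–900 bp, two samples per population at 50×) with the planted
window at genes 45–49; null-scan specificity on 200 sweep-free 38 kb
genomes (~100 genes of 270–330 bp, one 50× sample per population); and
replication calibration on 150 kb at 100× with 10 kb windows. Longer
genes are used for sweep recovery because per-gene π variance scales
inversely with segregating sites per gene, and the site density itself is
capped by the 96% identity filter: a fully diverged sweep haplotype must
stay under ~4% divergence per 150 bp read or its reads are filtered out —
a real limitation of identity-filtered strain analysis that the
simulations respect.
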