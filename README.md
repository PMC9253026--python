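# strainpop

Strain-resolved population genetics for metagenome-assembled genomes
(MAGs). Given per-sample read alignments against a set of genome bins and
their gene calls, `strainpop` computes the statistics used to compare
microbial populations sampled along an environmental gradient (for
example the salinity gradient of a hypersaline sabkha mudflat):

- **SNPs** from filtered pileups: a site is biallelic-segregating when the
  minor allele frequency exceeds 5% *and* a binomial error model rejects
  sequencing error, P(X ≥ k | n, ε) < 10⁻⁶ with ε = 10⁻³;
- **nucleotide diversity** π = Σ_{b≠b′} n_b n_{b′} / (n(n−1)) per site
  (the probability two reads differ), averaged over ≥20× positions per
  gene, with coverage-subsampling bias checks and synonymous /
  nonsynonymous classification of SNPs on gene calls;
- **linkage disequilibrium** from read-spanning fragments: for SNP pairs
  covered by ≥30 fragments, D = p_AB − p_A p_B,
  r² = D²/(p_A q_A p_B q_B), and D′ = |D|/D_max — D′ < 1 (all four
  haplotypes observed) is direct evidence of homologous recombination;
- **Hudson F_ST** between sample sites with sample-size correction,
  num = (p₁−p₂)² − p₁q₁/(n₁−1) − p₂q₂/(n₂−1), den = p₁q₂ + p₂q₁,
  aggregated per gene as the ratio of averages Σnum/Σden;
- **selective-sweep candidates**: 5-gene sliding windows with mean F_ST
  above mean + 1.5 SD of the genome background, confirmed as sweeps only
  when member genes also show significantly reduced π *and* significantly
  elevated r² (one-sided Welch t tests);
- **replication index (iRep-style)**: the sorted log2-coverage gradient
  across a bin, 2^slope, where 2 means the whole population is
  replicating and iRep − 1 approximates the replicating fraction.

A first-class **synthetic community generator** produces reference bins,
gene models, Balding–Nichols allele-frequency fields with a target F_ST,
haplotype pools with recombination, planted sweeps, and coordinate-correct
paired-end alignments (SAM) together with ground-truth tables — so every
stage is testable without any external sequencing data.

## Worked example

Simulate a two-population community (two 30 kb bins, 50×, 150 bp pairs)
with a selective sweep planted across genes 20–24 of bin 0, then run the
full pipeline:

```bash
strainpop simulate --seed 7 --out demo/data --genome-length 30000 \
    --depth 50 --samples-per-population 1 --sweep 0:20:25
strainpop run-all run.yaml   # config pointing at demo/data, pairing inner vs outer
```

`demo/out/report.md` then contains (actual output):

```
## Pairwise genome-wide Fst
pop_b     inner     outer
inner       NaN  0.149767
outer  0.149767       NaN

## Sweep regions — inner_vs_outer
  bin  start_gene_index  stop_gene_index  ...  window_fst  threshold          status     p_pi         p_ld
bin_0                19               26  ...    0.630707   0.600043 confirmed_sweep 0.014135 8.264974e-08

## LD — inner: mean r2=0.0677 mean D'=0.4846 frac D'<1=0.854 n=2611
```

Reading this: the planted high-differentiation window is recovered (the
region covers genes 19–25 ⊇ 20–24) with window F_ST 0.63 far above the
scan threshold 0.60; it is *confirmed* as a sweep because member-gene π is
significantly below the genome background (p = 0.014) and member-pair r²
significantly above it (p = 8×10⁻⁸). 85% of SNP pairs have D′ < 1,
reflecting the recombination built into the simulated haplotypes. The
per-category π table and per-bin replication indices are written
alongside (`pi_by_category_*.tsv`, `irep.tsv`); with the flat coverage
simulated here iRep sits at its short-bin noise floor of ≈ 1.1.

Every stage is also callable as a library function
(`strainpop.filtering`, `.variants`, `.diversity`, `.linkage`,
`.differentiation`, `.replication`) on pysam-loadable SAM/BAM input.

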