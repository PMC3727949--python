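# bgscan

Constraint-versus-diversity analyses for population variant data: windowed
minor-allele-frequency (MAF) meta-profiles around genes and non-coding sites
stratified by GERP evolutionary constraint, a depth-of-depression statistic
for background selection, and per-individual mutation-load profiling with
pairwise nonparametric tests — plus a seeded synthetic-data generator that
reproduces the statistical structure these analyses assume.

It is written for population geneticists who have a multi-sample VCF, a
per-base constraint track (bedGraph), gene annotations (BED), and optional
consequence/ancestral-allele tables, and who want to ask: *how strongly does
linked purifying selection depress diversity around constrained sequence,
how does that vary across populations, and do individuals differ in the
constraint load they carry?*

## The statistics

**Meta-profile.** For a set of anchor features (gene coding spans, or single
distal non-coding SNPs), the folded MAF of segregating biallelic SNVs is
averaged in non-overlapping windows of width *w* on each flank (100 × 10 kb
per side for genes, 100 × 100 bp for SNP anchors). Offsets run outward from
the span boundaries; sites inside the focal anchor are excluded, and a site
contributes once to every anchor whose flank contains it.

**Depth of depression.** A profile is summarized as

```
depth = mean( window MAF, 0.5–1 Mb both flanks ) − min( window MAF, ±50 kb )
```

Under background selection the depth grows with the constraint of the
anchoring genes (bin-level Pearson correlation with mean gene GERP) and,
around the most constrained genes, is larger in populations with smaller
effective size.

**Individual load.** An individual's load distribution is the multiset of
GERP scores at nonsynonymous sites where they carry the within-population
minor allele — twice per homozygous site (additive model). All pairs within
a population are compared with two-sided Mann–Whitney U and two-sample
Kolmogorov–Smirnov tests (exact small-sample nulls, Bonferroni-corrected),
and populations are summarized by per-individual counts of heterozygous,
homozygous-derived, and singleton alleles in unit-width positive GERP bins.

## Worked example

Generate a small synthetic dataset (40 genes with a conservation gradient,
three populations of 20) and run the gene-profile analysis:

```
$ cat sim.yaml
n_genes: 40
seed: 7
$ bgscan simulate --config sim.yaml --out demo --seed 7
wrote 7 files to demo (26246 sites)

$ cat an.yaml
vcf: demo/sites.vcf
genes: demo/genes.bed
gerp: demo/gerp.bedgraph
panel: demo/panel.tsv
consequences: demo/consequences.tsv
ancestral: demo/ancestral.tsv
outdir: demo_out
n_bins: 4
$ bgscan profile-genes --config an.yaml
$ cat demo_out/depression.tsv
bin  n_genes  mean_avg_gerp  distal_mean_maf  central_min_maf  depth         population
0    10       0.8368065064   0.04788710413    0.03843899336    0.009448110769 ALL
1    10       2.401126929    0.04779703877    0.02130657835    0.02649046042  ALL
2    10       3.784359316    0.04784637313    0.02609106649    0.02175530664  ALL
3    10       5.415618734    0.04797165851    0.0183346663     0.02963699221  ALL
```

Read this as: the distal flanks of all four quartiles level off at the same
baseline MAF (~0.048), while the central minimum drops from 0.038 around
the least conserved genes to 0.018 around the most conserved — the depth
rises from 0.009 to 0.030 with gene constraint. At this desk scale the
quartile-level correlation (`demo_out/correlations.tsv`: r = 0.82, n = 4
bins) is noisy; at the analysis scale used by the acceptance script
(500 genes, 10 bins, ~250k flank SNPs) it recovers the injected gradient
with r ≈ 0.97.

The other subcommands follow the same pattern: `bgscan profile-noncoding`
(GERP-quartile profiles around distal non-coding SNPs with a
proximal-vs-distal Mann–Whitney contrast), `bgscan individual-tests`
(pairwise load tests in a table of individual_1 / individual_2 /
population / mwu_p / ks_p), and `bgscan population-summary` (per-bin means
with 95% CIs and group contrasts).

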