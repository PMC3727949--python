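# Methods

## Scientific setting

Purifying selection at functionally constrained sites removes linked neutral
variation — background selection — so the minor allele frequency (MAF) of
polymorphisms near constrained sequence is depressed relative to distant
sequence. `bgscan` quantifies this with three connected analyses:

1. **Constraint-stratified meta-profiles.** Genes are scored by the mean
   GERP constraint of their coding bases and split into rank bins
   (quartiles or deciles). For each bin, the folded MAF of segregating
   SNVs is averaged in non-overlapping windows on each flank of each gene
   (offsets measured outward from the coding span boundaries, gene-body
   sites excluded, one contribution per anchor whose flank contains the
   site). The same construction applies at single-nucleotide anchors for
   distal non-coding sites, at 100 bp instead of 10 kb resolution.
2. **Depth of depression.** One profile is summarized as
   `depth = mean(distal windows) − min(central windows)`, where distal
   windows lie wholly within 0.5–1 Mb of the anchor on either flank and
   central windows within ±50 kb. The depth is compared across constraint
   bins (deeper near more constrained genes) and, for the most constrained
   genes, across populations (deeper in lower-diversity populations,
   the effective-population-size signal).
3. **Individual mutation load.** Each individual's load distribution is
   the multiset of GERP scores at nonsynonymous sites where they carry the
   within-population minor allele, counted twice when homozygous
   (additive fitness). All pairs within a population are compared by
   two-sided Mann–Whitney U and two-sample Kolmogorov–Smirnov tests under
   Bonferroni control; populations are summarized by per-individual counts
   (heterozygous, homozygous-derived, singleton) and proportions in
   unit-width bins over the positive GERP range, with 95% normal CIs
   across individuals.

## Conventions and numerical choices

- Coordinates are 0-based half-open internally; VCF/TSV inputs are 1-based
  and converted on read; report tables are 1-based offsets in bp.
- MAF is folded to [0, 0.5] and computed over non-missing alleles only;
  missing genotypes are excluded from denominators, never imputed.
  A site with alt frequency exactly 1/2 is a recorded tie; per-individual
  analyses deterministically treat alt as the minor allele at ties.
- Only biallelic SNVs on autosomes enter by default; multiallelic
  records, indels, and malformed genotypes are skipped and counted.
- A GERP track query outside coverage is *absent*, never 0: a score of
  exactly 0 means too few aligned species. Absent scores pass the
  neutrality GERP threshold filter; the exactly-0 exclusion applies only
  to analyses that compare per-site GERP with MAF, never to gene averages
  (which keep 0-scored coding bases — they are real scores there).
- Gene-average GERP: mean over all coding bases with a track score; bases
  without coverage leave both numerator and denominator.
- Quantile bins are rank-based with sizes differing by at most one
  (lower bins take the remainder); ties break by stable (value, id) order.
- Empty windows propagate as absent means and are skipped in distal
  averages; a profile whose distal flank or central region is entirely
  empty is an error rather than a silent zero.
- Mann–Whitney U: exact null for pooled n ≤ 16 (count recursion without
  ties, full label enumeration with ties); otherwise normal approximation
  with tie and continuity corrections. The two-sided p is the probability
  of a U at least as far from its mean as observed.
- Kolmogorov–Smirnov: D is the ECDF sup-distance; exact label enumeration
  (tie-safe) for pooled n ≤ 12, else the asymptotic Kolmogorov law at
  `sqrt(nm/(n+m))·D` (slightly conservative at moderate n).
- Hardy–Weinberg: conditional exact test summing heterozygote counts no
  more probable than observed, computed with exact integer weights;
  monomorphic sites return p = 1.
- Pearson correlations report two-sided p from the t reference on n−2 df,
  clamped into (0, 1].
- Bonferroni family for pairwise load tests: all C(n, 2) pairs within one
  population, separately per test type (the pipeline default). When one
  analysis spans several populations, the pooled family (sum of all
  within-population pairs) is available via `family_size`; the acceptance
  spike analysis uses it because that analysis performs all those tests.
- 95% CIs in population summaries are mean ± 1.96·sd/√n across
  individuals by default; a bootstrap percentile option exists. The
  equal-size singleton comparison redraws samples deterministically from
  the seed and re-evaluates singleton status within the subsample.

## The synthetic-data generator

The generator emulates the structure these analyses assume, not any real
genome. Genes with a linear conservation gradient g ∈ [0.3, 6] are placed
with ≥ 2.2 Mb inter-gene gaps (flank windows never overlap two genes at
the default scale). Per-base constraint is realized as a bedGraph track:
exon intervals jittered around g, sparse conserved non-coding elements
(score 2–6), near-zero background strips (a quarter exactly 0, to
exercise the informative-score exclusion), and 1-bp intervals at
polymorphic coding sites so a site's GERP always equals the track query.

Expected MAF at distance d from the nearest gene edge is

    m(d, g, pop) = mu_eff(pop) · (1 − A(g) e^(−d/λ)) · (1 − A_e e^(−d_e/λ_e))

with A(g) = a_max·g/g_max (defaults a_max = 0.5, λ = 100 kb; elements use
λ_e = 1 kb). Each population has a baseline mean MAF mu0 (default 0.08)
and an SFS-shape grade θ ∈ [0, 1] — the effective-population-size
analogue. θ mixes a rare baseline (mu_rare = 0.01) into the expected MAF
(`mu_eff = (1−θ)·mu0 + θ·mu_rare`): higher-diversity populations carry an
excess of rare variants and therefore a lower mean MAF and a shallower
absolute depression, reproducing the direction of the depth-versus-Ne
relationship. Realized frequencies add Beta noise (concentration 80)
around m; genotypes are binomial (HWE) draws with a 2% missing rate.

Coding polymorphism uses a separate SFS model: a site segregates in a
population with probability π = π0·h(θ) and, if it does, its derived
frequency follows a rare-skewed Beta (shape 0.3) with mean ν = ν0/h(θ),
where h = 0.3 + 0.7θ. The expected derived-allele mass π·ν is constant
across populations, so lower-diversity populations concentrate the same
mass into fewer, higher-frequency variants: heterozygous counts rise and
homozygous-derived counts fall with θ, the two directions the population
load summaries test. Ancestral alleles equal the reference except for a
5% polarization flip. Spiked individuals receive private heterozygous
singletons at new coding positions whose scores are drawn from the
coding score distribution shifted by +δ, so singleton semantics are exact
by construction.

Everything is driven by one `numpy` Generator; identical (config, seed)
pairs produce byte-identical output files.

### Frozen study conditions (presets)

Scales were chosen once, from power considerations, and then frozen:

- `profile_gradient_config`: 500 genes, flank SNP density 1.8e-4/bp
  (~250k sites), 3 populations × 20 — the constraint-gradient recovery
  condition (decile depths vs injected conservation, Pearson r ≥ 0.9).
- `ne_gradient_config`: 100 genes, density 2e-3/bp, 4 populations × 30
  with θ ∈ {0.1, 0.4, 0.7, 1.0}. Denser SNPs than the gradient preset
  because the central-window minimum is an order statistic: with only a
  handful of SNPs per window its noise would swamp the between-population
  depth differences. 2e-3/bp is still several-fold sparser than real
  human polymorphism density.
- `load_comparison_config`: 120 genes, coding-only, sized to give ≈50
  nonsynonymous singletons per individual (the order observed in real
  exomes), 3 exchangeable populations × 20 — null calibration and spike
  detection conditions.
- `theta_graded_load_config`: 100 coding-rich genes, 4 θ-graded
  populations × 20 — the population load-direction condition.

### What the generator does not emulate

No linkage disequilibrium or recombination structure, no coalescent
genealogy, no admixture, no sequencing error model, and depression acts
on expected MAF rather than SNP density (deliberately: the MAF statistic
is the one robust to mutation-rate variation). Passing tests therefore
demonstrate that the estimators recover the assumed structure at desk
scale — not that real data satisfy that structure.

## Known limitations

- The depth statistic's central minimum is biased by sampling noise when
  windows hold few SNPs; compare depths only between profiles of similar
  site density.
- The KS asymptotic p is the limiting distribution, not a finite-n
  approximation; for pooled n below ~30 treat borderline KS calls with
  care (the U test is exact-or-corrected in that regime).
- The HWE exact filter is O(minor-allele count) per site with exact
  integer arithmetic; enabling it on very large cohorts is noticeably
  slower than the default filters.
- Population-scoped profiles condition on segregation within that
  population, so populations rich in rare variants lose more sites near
  the detection floor; this attenuation is part of the measured signal,
  as it is in real low-coverage data.
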