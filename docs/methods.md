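# Methods

This note documents the statistical models, estimators, numerical choices
and known limitations of `molqtl`. It is written for users deciding whether
the package's behavior matches their data, and for maintainers deciding
whether a change is safe.

## The measurement model

All phenotypes are log2-scale and zero-centered per feature. Transcripts
are measured per strain in up to three biological replicates; the
strain-level summary used everywhere downstream is the arithmetic mean of
replicates. Peptides are measured once per strain as log2 sample/reference
ratios, plus technical replicate runs of one designated reference strain;
those runs estimate the technical (plus residual non-genetic) variance of
each peptide.

## Quality filters

* **Basic peptide rules.** Missingness strictly below 50% of the strain
  panel ("less than 50%" is a strict inequality, so exactly half missing is
  rejected); no lysine or arginine anywhere except the final residue (the
  tryptic C-terminus is exempt; the KP/RP trypsin exception is deliberately
  NOT applied — the filter implements the literal rule); exactly one
  annotated gene. The rejection log records every (peptide, failed rule)
  pair.
* **Signal-to-noise.** `S = var_population / var_technical`, both unbiased
  (n−1) sample variances over non-missing values; a peptide passes iff
  `S > cutoff` (default 2). Zero technical variance with positive panel
  variance is best-case, not an error: it passes with an infinite sentinel
  ratio. S is invariant under scaling of the peptide's values.
* **Heritability ANOVA.** One-way fixed-effect ANOVA with strain as the
  grouping factor, unbalanced designs allowed. Two statistics are reported:
  `h2 = SS_strain/SS_total` — the conventional broad-sense heritability
  summary for panel data — and `h2_vc`, the variance-component (intraclass
  correlation) estimate `σ̂²_s/(σ̂²_s+σ̂²_w)` with
  `σ̂²_s = (MS_strain − MS_within)/r̄` and `r̄` the standard effective
  replicate number for unbalanced designs. The distinction matters: the
  SS-ratio is biased upward at small replicate numbers (its null
  expectation is `(s−1)/(sr−1)`, about 0.33 at 100 strains × 3 replicates),
  so it cannot be used to check recovery of a planted variance fraction;
  `h2_vc` is the consistent estimator and is what recovery tests and the
  acceptance script report. Filtering uses the strain-term F-test p-value
  (p < 0.05), which is identical under either parameterization. Features
  with all-identical values get h2 = 0, p = 1.
* **Probe masking.** A 25-mer probe is masked iff at least one SNP position
  falls inside its 1-based inclusive interval; a probeset is excluded iff
  its masked-probe count is ≥ 8.
* **Eigenpeptide normalization.** Missing cells are mean-imputed for the
  SVD only; the top `n_trends` right-singular vectors of the centered
  feature × strain matrix are projected out of every feature row, and
  missing cells are restored. `n_trends = 0` is the identity. This removes
  batch-like systematic trends; it does not test trend significance.

## Biweight midcorrelation

For each variable, deviations from the median are weighted by the Tukey
biweight `w = (1−u²)²·1[|u|<1]` with `u = (x−median)/(9·MAD)`, MAD taken
raw (consistency constant 1). The correlation is the inner product of
weighted deviations normalized by the two weighted norms, clamped to
[−1, 1]. A variable with MAD = 0 (more than half its values tied) falls
back to Pearson-style deviations for that variable only. Missing data are
handled by pairwise-complete deletion; fewer than 3 complete pairs is an
error, as is zero variance under both weighting schemes. Significance uses
the Student-t transform `t = r·sqrt((n−2)/(1−r²))` on n−2 degrees of
freedom, two-sided.

## Group bootstrap test

The observed statistic for a term is the mean correlation p-value of its
member entries in the pool (per-pair or per-gene — the pool definition is
the caller's choice and both are supported, since either convention is
defensible). The null is built from draws, without replacement, of
equal-size subsets of the pool; the two-tailed empirical p is
`(2·min(#null ≤ obs, #null ≥ obs) + 1)/(n_draws + 1)`, capped at 1 — the
+1 correction avoids zero p-values. Groups are first restricted to the
measured-gene universe (annotation terms routinely list unmeasured genes);
a group whose declared size exceeds the pool is an error. An exhaustive
mode enumerates all subsets for small pools and is used as the test
oracle. Under a null pool the empirical p is uniform (checked by KS test
over 500 random groups).

## Mixed-model association

Per phenotype the model is `y = μ + xβ + u + e`, `Var(u) = σ²_g K`,
`Var(e) = σ²_e I`, with K the identity-by-state kinship: the fraction of
jointly observed SNPs at which two strains carry the same allele. Missing
genotypes are mean-imputed per SNP for testing; kinship uses observed
pairs only; K gets a 1e-6 diagonal ridge if numerically non-PSD.

REML estimates `δ = σ²_e/σ²_g` by maximizing the restricted likelihood on
the spectrum of the projected kinship `S K S` (S the residual-maker of the
fixed effects): a 100-interval grid over `ln δ ∈ [−10, 10]`, derivative
root-refinement in every sign-change interval, and the global optimum over
all candidates. Ties are broken toward the **largest** δ: with K = I the
restricted likelihood is exactly flat in δ (only `σ²_g + σ²_e` is
identifiable) and the largest-δ convention makes the fit degenerate to
ordinary least squares, which is the behavior one wants from an
uninformative kinship.

Variance components are estimated once per phenotype under the null and
reused for every SNP (`per_snp_reml=True` re-estimates per SNP; the
default is the standard fast approximation and the two agree under an
identity kinship). Each SNP is tested by rotating phenotype and design
into the eigenbasis of K, scaling by `1/sqrt(λ_i + δ)`, and running an
F-test of β = 0 with denominator degrees of freedom `n − 2` (intercept +
SNP). Variance explained is `1 − var(y − β̂x)/var(y)`, clamped to [0, 1].

Two properties define correctness here and are enforced by tests: with
K = I every p-value equals the ordinary F-test p to relative 1e-6, and on
a family-structured null panel the type-I error at α = 0.05 stays within
[0.035, 0.065] while the no-kinship scan inflates severely (~0.19 at the
default structure).

A note on δ recovery: the REML estimator is exact, but how well δ is
*identified* depends on the eigenvalue spread of K. A nearly
block-constant IBS similarity matrix concentrates its information in a
handful of family contrasts and leaves δ weakly identified (median
estimates drift upward); a standardized genetic-relationship matrix from
approximately independent SNPs identifies δ well (median ≈ 1.0 when
σ²_g = σ²_e). The recovery test therefore uses the latter.

## FDR

Storey q-values: `π₀` is estimated by a cubic least-squares fit of
`π₀(λ) = #{p>λ}/(m(1−λ))` over `λ ∈ {0, 0.05, …, 0.90}`, evaluated at
λ = 0.90 and clipped to (0, 1] (the same estimator family as the standard
smoother, without a spline-smoothing parameter). With `π₀ = 1` the q-values
equal Benjamini–Hochberg exactly. For very large p-value collections a
subsample mode computes q on random subsets and averages per test, which
reproduces the standard large-scale approximation at configurable size.
q-values computed separately per dataset give each dataset its own
significance scale — the basis of the matched-FDR eQTL/pQTL comparison.

## LD pruning, blocks, windows, overlap

Pruning is greedy per phenotype: the most significant unpruned SNP becomes
a peak and removes all significant SNPs with genotype `r² ≥ 0.5` against
it ("0.5 or larger", boundary inclusive). Ties in p break toward the
smaller genomic coordinate, making output independent of input order.
Haplotype blocks use the complementary strict rule: a block extends while
adjacent r² is strictly above 0.5. Locality: a peak is local iff on the
gene's chromosome within `[min(TSS,TES) − 2 Mb, max(TSS,TES) + 2 Mb]`,
boundaries inclusive; the rule is translation-invariant. Hotspot windows
are 2 Mb advancing by 50 kb, half-open `[start, end)` so a call is never
double-counted at a boundary; counts are also reported as fractions of
each dataset's total. Overlap matches local QTL only within the same gene
and distant QTL anywhere on the same chromosome, peak-to-peak distance
≤ 2 Mb, one-to-one nearest-first (a symmetric rule); identical peak SNPs
are counted separately.

## The synthetic panel generator

What it emulates, and the defaults chosen (one per line, with the
reasoning where the choice was open):

* 97 strains, 3 transcript replicates, 10 technical replicate runs of one
  reference strain — the study design of this kind of panel.
* Genotypes: homozygous {0,1} calls (an inbred panel has no
  heterozygotes); SNPs in contiguous LD blocks of exponential length,
  mean 0.73 Mb (the empirical mean block size in such panels); within a
  block each SNP is a noisy copy (flip rate 0.03) of the block founder;
  MAF floor 0.10 enforced by redraw. Five strain families with 40% of
  blocks segregating along family lines give the panel its genome-wide
  population structure (classic + recombinant-inbred composition); without
  it a kinship correction has nothing to correct.
* Genetic architecture is gene-centric: each gene (or isoform cluster) has
  one standardized genetic profile built from planted QTL effects plus a
  polygenic remainder, rescaled to unit realized variance so that variance
  bookkeeping is exact. Features mix their gene's profile at their own
  heritability `t` (uniform over 0.07–0.95 by default, the span seen for
  transcript heritabilities) with feature-level noise of variance `1−t`.
  Because a gene's transcripts and peptides share the profile, realistic
  transcript–protein concordance emerges rather than being painted on.
* Local QTLs are planted on SNPs that segregate within families. Effects
  on family-aligned SNPs are absorbed by the kinship correction and their
  apparent peaks migrate to correlated structure SNPs elsewhere in the
  genome — they are not locally identifiable by the design of mixed-model
  mapping. Recovery tests measure the mapping machinery, so planted local
  effects must be identifiable ones; this is a property of the simulation
  design, not a tuning of any threshold.
* Peptide technical noise: per-peptide σ drawn lognormally (median 0.3,
  log-sd 0.75) around the study-scale technical variance, which produces
  the broad signal-to-noise spectrum the SNR filter exists for; peptide
  missingness 10% at random.
* Traits: linear combinations of 1–3 standardized driver strain-mean
  profiles with coefficients ±U(0.5, 1.5) and residual sd 0.5.
* Determinism: a single global seed is fanned out to per-stage child seeds
  (a small string hash), so any stage can be regenerated independently and
  identical configs give byte-identical outputs.

What it does **not** emulate: raw spectra or probe-level intensities,
linkage maps or outbred genetics, non-Gaussian phenotype tails, missing
data that is informative rather than random, shared batch structure
between transcripts and peptides, or realistic gene length/density
distributions. Passing recovery tests on this generator therefore
demonstrates the correctness and calibration of the estimators under the
stated statistical structure — not robustness to every pathology of real
panel data.

## Problem sizes

The test suite and the acceptance script run desk-scale versions of each
analysis: calibration on 100 strains × 2,000 SNPs × 200 phenotypes,
heritability recovery on 200 features per planted value, concordance on an
80-strain panel with 450 peptides, recovery on 100 strains × 1,000 SNPs ×
60 transcripts. These sizes were chosen so each check has comfortable
statistical resolution for its tolerance; all scale linearly if increased.

## Known limitations

* The SS-ratio heritability is reported because it is the field's summary
  statistic, but it is not a consistent estimator of the variance fraction
  at r = 3; use `h2_vc` for quantitative statements.
* The bootstrap test treats pool entries as exchangeable; correlated
  entries (several pairs from one gene) make the null slightly
  conservative for per-pair pools.
* One-to-one nearest-first overlap matching is one defensible convention;
  greedy matching can differ from optimal assignment when peaks are dense.
* The per-SNP REML flag is exact but quadratic in cost; the default
  null-based approximation is standard and matches it wherever both were
  compared here.
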