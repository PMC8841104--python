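# Methods

## Pure two-locus penetrance models

A pair of biallelic loci is modelled by a 3×3 penetrance table
`f[i, j] = P(case | gA = i, gB = j)` over minor-allele counts. With HWE
genotype frequencies `p = [(1−q)², 2q(1−q), q²]` at allele frequency `q`,
prevalence is `K = Σ p_i p_j f_ij` and heritability
`h² = Σ p_i p_j (f_ij − K)² / (K(1−K))`. A model is *pure* (strictly
epistatic) when every single-locus marginal penetrance equals `K`, so no
locus carries a main effect; χ²-style single-SNP tests are then blind to the
pair by construction, which is the property the whole package exists to
exercise.

`gen_penetrance_model(maf, h2_target, K, seed)` builds such tables exactly
rather than by search: the six purity conditions form a rank-5 linear system
on the deviations `d = f − K`, leaving a 4-dimensional null space. A random
(seeded) direction in that null space is scaled by the unique positive factor
that makes the heritability equal `h2_target` to machine precision, and the
draw is rejected if any penetrance leaves [0, 1] (cap: 10,000 draws).
Residuals of the purity constraints are at numerical zero (~1e−16).

**Prevalence default.** `K` trades off against attainable heritability:
vertex enumeration of the purity polytope at MAF 0.2 shows the maximum
attainable h² is ≈0.34 at K = 0.25 and ≈0.46 at K = 0.35. The default is
K = 0.35, the value at which the target h² = 0.4 is comfortably feasible
(rejection-sampler acceptance ≈6%); it is exposed everywhere.

## Combining several pairs

The reference architecture holds four pairs (MAF 0.2, h² 0.4 each, shared
K) plus 1000 no-effect SNPs, sampled for 405 cases and 405 controls. Two
combination rules are provided:

* `combine="fraction"` (default): each individual's disease status is
  governed by one pair drawn uniformly, so each of M equally weighted pairs
  drives status for 1/M of the population at its full heritability. This is
  the multi-model dataset semantics of GAMETES-style simulators, and the
  reading of "each pair contributes one-fourth of the effect" adopted here.
* `combine="mean"`: penetrance is the mean of the pair penetrances, which
  scales every pair's deviations by 1/M and hence its detectable
  heritability by 1/M² (0.025 per pair for M = 4) — far below what any
  neighbourhood-based scorer can recover at n = 810, p = 1008.

Both rules keep every single-locus marginal penetrance exactly at K, so the
combined architecture stays free of main effects; this was verified both
analytically and by the empirical-MAF checks below. An unclipped additive
sum of deviations that would preserve more per-pair signal is not an option:
it leaves [0, 1] for essentially all feasible model quadruples, and clipping
it back introduces marginal effects (~0.01) that a χ² scan detects at
n = 810.

No-effect SNPs are independent HWE draws with per-SNP MAF ~ Uniform(0.05,
0.5), the plausible post-QC spectrum of an imputed array panel; a
`noise_template` mode resamples columns of a supplied real dataset instead.
Simulated SNPs are mutually unlinked, so LD pruning is an identity on this
data (it is exercised on correlated toy data in the unit tests).

## Relief-based scoring

Distances between individuals are mismatch proportions over jointly
non-missing SNPs. For each target, neighbors with distance below μ − σ/2
(mean/SD of the target's distance distribution, ddof = 0) are *near*;
above μ + σ/2, *far*. MultiSURF accumulates, per feature, the mean 0/1
genotype mismatch against near misses minus near hits; MultiSURF* adds the
far-neighbor terms with inverted sign, which cancels univariate signal and
retains interaction signal. Sums are divided by n (2n for MultiSURF*, whose
per-instance near and far contributions are each bounded by 1), giving the
[−1, 1] range; the constant is a package choice since only the range, not
the normaliser, is standard. Missing genotypes contribute no evidence
(diff = 0). A `continuous=True` flag switches the scoring diff to
|a − b| / 2. Both scorers are verified feature-for-feature against an
exhaustive O(n²p) oracle.

Cross-validation averaging (`cv_average_scores`, default 10 stratified
folds) scores each fold's training portion and averages the k score
vectors; scoring the held-out tenth is available via `score_holdout=True`.

χ² scoring builds per-SNP 2×3 genotype (default) or 2×2 allele tables and
returns the Pearson statistic as a ranking score; no multiple-testing
correction is applied because the statistic is used only to rank.

## Gene scores and enrichment

SNPs map to genes on the same chromosome whose BED interval, widened by
10 kb on each side, contains the SNP's 0-based position (half-open test);
a SNP may hit several genes. A gene's summary score is the maximum over its
SNPs (negative Relief scores are kept); ties in the ranked list break
lexicographically for determinism.

The enrichment score of a set against a ranked list is the signed maximal
deviation of the weighted running sum (hits add |s|ᵖ/N_R with p = 1 by
default, misses subtract 1/(N − N_H)); if all hit weights are zero the walk
falls back to p = 0 with a warning. The permutation null draws same-size
gene sets uniformly without replacement from the universe (`n_perm` = 1000
default; nominal p floored at 1/(n_perm+1)). NES divides ES by the mean
same-sign null magnitude; FDR q is the pooled same-sign ratio
`P(null NES ≥ |NES|) / P(observed NES ≥ |NES|)`, clipped to [0, 1] and made
monotone non-increasing in |NES| by a step-up (suffix-minimum) pass within
each sign. Null p-values were checked for uniformity by KS test on 200
random sets. Leading-edge genes are the set members at or before the
running-sum peak (at or after it, for negative ES); the cross-analysis
summary restricts each analysis to its top-n sets by |NES| (ties: smaller
q, then name) and reports the gene × set occurrence matrix, per-set
leading-edge fraction, and the genes replicated on a leading edge in every
analysis.

## What the simulation does and does not show

The generator reproduces the statistical core of the study design — pure
interaction signal invisible to marginal tests, at realistic sample size —
but not LD structure, covariates, population stratification, gene-size
variation (one synthetic gene per SNP), or real GO topology (random gene
sets plus one functional set). Green tests therefore demonstrate that
interaction signal survives the score → gene → enrichment chain where
univariate ranking fails, not that any particular real pathway would be
recovered.

At the reference scale the contrast is reproducible but partial: Relief
rankings place several of the eight functional loci near the top of 1008
SNPs, their nominal enrichment beats χ² in essentially every seed, the
χ² ranking never reaches FDR significance for the functional set, and the
between-method rank-correlation ordering
ρ(MultiSURF, MultiSURF*) > ρ(χ², MultiSURF*) holds seed after seed. The
8-member functional set itself, however, does not reach FDR q < 0.05
against 150 random sets: with four pairs sharing the effect, no pure and
penetrance-valid combination gives each pair enough signal to put all eight
genes at the extreme top, and an 8-gene set needs essentially that to beat
a pooled permutation FDR. Pathway-level FDR significance of this kind is
expected for larger (20–200 member) sets that contain the functional genes
among many null members, not for the bare 8-gene set.

## Numerical and design choices

* Seeds: every stochastic routine takes an explicit seed; the pipeline
  derives per-stage seeds from one master seed by fixed offsets (mod 2³¹).
* LD pruning keeps the earlier SNP of a violating pair (PLINK-like), treats
  pairs with <3 complete observations as uncorrelated, and never lets
  windows span chromosomes.
* Pseudo-controls: `father + mother − child`; Mendelian-inconsistent cells
  become missing with a logged warning rather than aborting, since residual
  inconsistencies survive upstream QC in real trio data; all-missing trios
  are dropped.
* Genotype tables are tab-delimited with header `sample_id, rsIDs…,
  phenotype` and missing token `NA`; SNP positions are 1-based, gene
  intervals 0-based half-open (BED).
* Degenerate inputs: monomorphic SNPs score 0 (not NaN) under χ²; constant
  features score exactly 0 under Relief; gene sets equal to, or disjoint
  from, the ranked universe are rejected; sets with no same-sign null ES
  get NES/q = NaN and are excluded from FDR pools.
* Problem sizes in the shipped checks (e.g. 25,000 individuals for the
  marginal-purity check, 5 seeds × n_perm = 1000 for the reference
  comparison, n ≤ 30 for oracle equivalence) were chosen as the smallest
  scales at which the corresponding statistics are stable.

## Known limitations

Relief scoring is O(n²p) and intended for post-pruning panels (~10⁵ SNPs)
rather than raw imputed data; no TuRF-style iterative wrapper is included.
The enrichment module implements gene-set permutation only (phenotype
permutation requires per-sample recomputation of the ranking) and
competitive testing only. Gene-size bias of max-score aggregation is not
corrected.
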