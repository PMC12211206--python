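# Methods

## Scope and model of the data

`mitonuc` analyzes three layers of evidence about the same set of
individuals: biallelic SNP genotypes (dosage 0/1/2 with missingness, plus
per-site Phred quality and per-genotype read depth), a raw expression
count matrix over a subset of those individuals, and sample metadata that
groups the expression subset three ways — station, mitotype and nuclear
type.  Two cohorts coexist: a larger genotype cohort (default 27
individuals) used for population structure, and the expression subset
(default 15 samples) used for differential expression.  The pipeline
identifies the expression subset as the columns of the counts matrix;
metadata rows form its superset.

## Filter cascade

The cascade applies, in a fixed order: (1) site Phred quality — strictly
below `min_qual` (default 30) is removed; (2) stage-1 site filter — call
rate ≥ 0.5 and minor allele count ≥ 3; (3) individual filter — missing
fraction strictly above 0.27 removes the individual; (4) depth masking —
genotypes with depth < 10 become missing, loci are kept; (5) stage-2 site
filter — call rate ≥ 0.95, minor allele frequency ≥ 0.05, at most two
alleles.  These follow VCFtools flag semantics (`max-missing` is the
required genotyped fraction; `minDP` masks genotypes rather than dropping
sites).  Boundary conventions: quality and individual-missingness cutoffs
are strict, call-rate/MAC/MAF cutoffs inclusive.  MAC and MAF are
computed over non-missing genotypes; the minor allele is the less
frequent one, so an exact tie yields MAF 0.5.  Depth masking is placed
inside the second filtering step, immediately before the stage-2 site
predicates: stage-1 statistics therefore see unmasked genotypes, and
stage-2 missingness sees masked cells.  The cascade is monotone per
stage and, on realistic depth distributions (masking rare relative to the
stage-2 call-rate margin), idempotent on its own output.  Multi-allelic
records are carried with their allele count, dosage measured against the
first ALT, until the `max-alleles` predicate removes them; with default
parameters none survive.

Loci on contigs labelled mitochondrial in the compartment table go to the
mitochondrial partition; all other loci — including contigs absent from
the table — are nuclear, mirroring a "no database hit means nuclear"
assignment rule.

## Population structure

AMOVA uses squared Euclidean dosage distances; for a pair of individuals
the sum over jointly called loci is rescaled by (total loci / shared
loci), which is unbiased when missingness is independent of the locus
effect.  Variance components follow the classical two-level partition
(among groups vs within groups); σ²_among may be negative and is reported
as-is, with Φ_ST computed from it — percentages are floored at zero only
in the report layer.  Significance comes from permuting individual labels
(default 1,000 permutations) with the +1-corrected p-value
(1 + #{Φ_perm ≥ Φ_obs})/(n_perm + 1), which is slightly conservative and
never zero.  A fully degenerate matrix (all distances zero) is defined to
have Φ = 0 and 0% among-group variance.

PCA is covariance PCA (no unit-variance scaling of loci) on per-locus
mean-imputed, column-centered dosages, computed by SVD; explained
percentages are eigenvalue shares of total variance.

G′_ST for a pair of groups uses unweighted mean allele frequencies:
H_S = (2p_A(1−p_A) + 2p_B(1−p_B))/2, H_T = 2p̄(1−p̄) with p̄ = (p_A+p_B)/2,
G_ST = (H_T − H_S)/H_T and G′_ST = G_ST(k−1+H_S)/((k−1)(1−H_S)), k = 2.
Equal weights are deliberate: group sizes here are small and unequal, and
the unweighted form makes the hand-computable oracle exact.  Loci with
H_T = 0, or with no called genotype in either group, are excluded from
the per-locus vector and the mean.  The estimator is computed from sample
frequencies and reported unclamped; on parametric frequencies it lies in
[0, 1].

## Differential expression

The NB Wald test is intentionally simple and fully self-contained:

- Size factors: median-of-ratios over genes positive in every sample.
  If no such gene exists the computation refuses rather than silently
  switching reference.
- Dispersion: per-gene method of moments on normalized counts — pooled
  within-group variance v, grand mean μ̂, α̂ = (v − μ̂·mean(1/s))/μ̂²,
  clipped to [1e−8, 10].  No empirical-Bayes shrinkage: the validation
  layer of this pipeline is calibration-based (the randomized-grouping
  null), so exact agreement with any particular published tool is not
  claimed, only correct error rates under the null.
- Test: delta-method variance of ln of the group mean,
  normal-approximation two-sided p.  Groups with zero mean receive the
  continuity substitute 0.5/Σ_{j∈g}s_j so the log ratio stays finite;
  genes with zero counts in both groups are untested and excluded from
  the BH denominator.
- Multiplicity: Benjamini–Hochberg within each pairwise contrast
  separately (m = tested genes of that contrast).
- DEG: p_adj ≤ 0.01 and |log2FC| ≥ 1, both inclusive.  The per-grouping
  analysis statistic is the size of the union of DEG sets over all
  unordered group pairs.

When a whole grouping is analyzed, size factors are computed once on the
full matrix and dispersion once per grouping (pooled over all its
groups); a standalone pairwise call estimates dispersion from the
two-group design restricted to those samples.  Under a pure NB null with
10-vs-10 samples the raw p-values are mildly anticonservative (the
normal approximation with estimated dispersion behaves like a t with ~18
degrees of freedom), which the calibration tests bound explicitly.

## Randomized-grouping null

For a grouping with size conformation (n₁,…,n_G), each of `n_iter`
(default 1,000) iterations draws a uniformly random partition of the same
samples into groups of exactly those sizes (sampling with replacement
across iterations — the partition space at 15 samples is far larger than
any n_iter) and records the union DEG count.  Gamma, lognormal, Weibull
and normal are fitted by maximum likelihood (gamma via Newton iteration
on the shape; positive-support families on values shifted by +0.5 when
zeros are present, with quantiles shifted back and floored at 0; a
candidate whose support cannot hold the sample, or whose likelihood is
non-finite, is dropped) and the minimal-AIC candidate is selected.  The
exceedance verdict is strict: observed > Q0.95 of the selected fit.  An
empirical permutation p-value, (1 + #{null ≥ observed})/(n_iter + 1), is
reported alongside.

The Q0.95 confidence interval is a parametric bootstrap percentile
interval: resample n_iter values from the fitted distribution, refit
within the same family, take the central `conf_level` interval of the
refitted quantiles.  The verdict depends only on Q0.95, not on the CI.

Degenerate null samples — all counts equal, typically all zero on small
effect-free data — admit no ML fit; `fit_null` raises, and the pipeline's
verdict layer falls back to the empirical 0.95 quantile with the same
strict rule (reported with method = "empirical").  This keeps type-I
behavior honest instead of manufacturing a parametric fit.

## Synthetic data generator

The generator emulates the study conditions the pipeline assumes:

- **Design**: 15 samples; station (5,5,5), mitotype (2 h1h1, 7 h2h2,
  3 h1h3, 3 h2h3), nuclear type (10, 5); label-to-sample assignment is
  shuffled independently per grouping so groupings are not confounded by
  construction.  The genotype cohort adds 12 genotype-only individuals
  (stations and homoplasmic mitotypes cycled) for 27 in total.
- **Counts**: gene baselines log-normal (meanlog 4, sdlog 1 on the count
  scale — chosen as a typical right-skewed transcript-abundance profile;
  exposed in the config), library sizes log-uniform on [0.5, 2], NB
  dispersion α = 0.2 (a moderate invertebrate-tissue overdispersion).
  One planted contrast per grouping — first station vs rest, heteroplasmic
  vs homoplasmic, first nuclear type vs second — with disjoint planted
  gene sets (default 5% of 2,000 genes per contrast) at |log2FC| = 2 and
  random sign.
- **Genotypes**: nuclear loci use the Balding–Nichols model (station
  frequencies Beta-distributed around a uniform ancestral frequency at
  F_ST = 0.03, matching weak spatial structure); mitochondrial loci are
  clonal — 80% of the 145 sites are fixed between the h1- and h2-carrier
  clusters (written as homozygous diploid calls), and heteroplasmic
  individuals carry intermediate dosage at 30% of those sites to mimic
  minor-haplotype admixture.  Site quality is uniform on [20, 60], so the
  Phred ≥ 30 filter removes a predictable ~25% of sites; depth is
  Poisson(30) per genotype; genotypes go missing at rate 0.02.
- All randomness flows from one integer seed through fixed, named
  substreams, so identical configs produce byte-identical fixtures.

What the generator does **not** emulate: read-level noise and mapping
artifacts, linkage between loci, GC/length biases in counts,
gene-specific dispersion profiles, and correlated missingness.  Passing
tests therefore demonstrate the correctness and calibration of the
statistical machinery under its stated model, not robustness to every
real-data pathology.

## Problem sizes in tests and the acceptance script

The test suite exercises calibration at 200 replicates (AMOVA permutation
and exceedance type-I error), power at 50 replicates across the three
study conformations, and bootstrap coverage at 200 trials, using 200
randomization iterations and 500–2,000 genes per replicate; these sizes
give binomial Monte-Carlo noise comfortably inside the asserted bands.
The acceptance script runs the full default conditions (2,000 genes,
1,000 null iterations, 1,000 AMOVA permutations).

## Known limitations

- The Wald test's normal approximation is anticonservative at very small
  group sizes (n = 2–3 groups exist in the mitotype design); the
  randomized null inherits and thereby neutralizes this bias, but raw
  per-pair p-values should not be read as exact.
- The AMOVA is strictly two-level; nested designs are out of scope.
- AIC comparison mixes shifted (positive-support) and unshifted (normal)
  likelihoods when zeros force a shift; the 0.5 location shift perturbs
  log-likelihoods marginally and never changes the verdict mechanism,
  which depends only on the selected fit's quantile.
- G′_ST is defined here for two groups (k = 2) only, as used in pairwise
  comparisons.
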