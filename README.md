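# mitonuc

Does where a marine bivalve lives, or which mitochondrial genome it
carries, leave a larger footprint on its gene expression?  `mitonuc` is a
reusable pipeline for answering that class of question in non-model
systems where individuals can be grouped three ways over the same
transcriptome — by sampling station (habitat), by mitotype (mitochondrial
genotype class, including heteroplasmic individuals that carry two
divergent mitochondrial haplotypes at once), and by nuclear genotype
cluster.  It covers four stages:

1. **SNP hard-filter cascade** (VCFtools-style semantics): Phred site
   quality ≥ 30 → call rate ≥ 0.5 and minor allele count ≥ 3 → drop
   individuals with > 27% missing genotypes → mask genotypes with depth
   < 10 → call rate ≥ 0.95, minor allele frequency ≥ 0.05, at most 2
   alleles — with a logged per-stage funnel, and a mitochondrial/nuclear
   partition of the surviving loci by contig.
2. **Population structure**: two-level distance-based AMOVA
   (between stations vs within individuals) with a label-permutation test,
   covariance PCA of dosages with per-locus mean imputation, and pairwise
   Hedrick's G′<sub>ST</sub> per locus.
3. **Differential expression**: a self-contained negative-binomial Wald
   test with median-of-ratios size factors, method-of-moments dispersion,
   Benjamini–Hochberg FDR per pairwise contrast, and DEG calling at
   p<sub>adj</sub> ≤ 0.01 and |log2FC| ≥ 1.
4. **Randomized-grouping null**: the observed union DEG count of a
   grouping is validated against DEG counts from many random
   re-partitions of the same samples into groups of the original sizes
   (the *size conformation*, e.g. 5/5/5).  Candidate distributions
   (gamma, lognormal, Weibull, normal) are fitted by maximum likelihood,
   selected by AIC, and the verdict is whether the observed count exceeds
   the fitted Q<sub>0.95</sub> (with a parametric-bootstrap confidence
   interval).

A synthetic-data module generates study-shaped fixtures (NB counts with
planted effects, Balding–Nichols nuclear genotypes, clonal mitochondrial
haplotype clusters), so the whole pipeline is testable without any
sequencing data.

## The statistics in brief

Counts follow NB(μ, α) with Var = μ + αμ².  For groups A, B the test
statistic is

```
λ = ln μ̂_B − ln μ̂_A,   Var(ln μ̂_g) = Σ_j (μ̂_g/s_j + α μ̂_g²) / (n_g μ̂_g)²,
z = λ / √(Var_A + Var_B),   p = 2(1 − Φ(|z|)),
```

with s_j the median-of-ratios size factors.  AMOVA partitions squared
Euclidean dosage distances: SS_total = (1/N)Σ_{i<j} d²,
SS_within = Σ_g (1/n_g)Σ_{i<j∈g} d², σ²_within = SS_within/(N−G),
σ²_among = (MS_among − σ²_within)/n̄, Φ_ST = σ²_among/(σ²_among+σ²_within).
Hedrick's standardized differentiation for two groups is
G′_ST = G_ST (k−1+H_S)/((k−1)(1−H_S)) with k = 2.

## Worked example

```python
from mitonuc.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=5, n_iter_null=100, n_perm_amova=100, n_boot_ci=100)
report = run_pipeline(cfg)
for grouping, block in report["de"].items():
    v = block["verdict"]
    print(grouping, v["observed"], round(v["q95"], 1), v["exceeds"])
```

prints

```
station 92 12.8 True
mitotype 108 23.9 True
nuclear_type 85 4.5 True
```

i.e. on the default synthetic conditions each grouping's observed union
DEG count (92, 108, 85) lies far above the 0.95 quantile of its
randomized-grouping null (12.8, 23.9, 4.5): the group structure, not
chance assignment of the 15 samples, drives the expression differences.
The same report carries the filter funnel, AMOVA (here: no station
structure in mitochondrial SNPs, a small but significant percentage
between stations in nuclear SNPs), PCA explained variances (the
h1-vs-h2 mitotype split dominates mitochondrial PC1 with ~81% explained,
while nuclear PC1 explains only ~6%), and per-pair G′_ST means.

The same run is available from the shell:

```bash
mitonuc run-all --outdir runs/demo --seed 5
mitonuc simulate --outdir fixtures --seed 3
mitonuc filter-variants --vcf fixtures/genotypes.vcf --out filtered
mitonuc de --counts fixtures/counts.tsv --meta fixtures/metadata.tsv --group-by mitotype
mitonuc null --counts fixtures/counts.tsv --meta fixtures/metadata.tsv --group-by station
```

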