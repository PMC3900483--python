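# Methods

`famblock` implements region-level family-based association tests for binary
traits — rbPDT and rbFBAT — together with the simulation machinery needed to
study their operating characteristics.

## The tests

### Per-SNV, per-pedigree statistics

For pedigree *i* and SNV *j*, two flavours of a statistic `T_ij` with
conditional null mean 0 are available.

**PDT flavour.** The pedigree disequilibrium test extracts two kinds of
informative units from a pedigree: parent–affected-child trios, scored as
`d = (# minor alleles transmitted) − (# not transmitted) = 2·X_child − X_f −
X_m`, and discordant sibpairs (one affected, one unaffected full sib), scored
as the affected-minus-unaffected minor-allele count.  `T_ij` averages the
unit scores over the pedigree's `n_T + n_S` units (a sum is available).

Its conditional null variance is computed exactly: given parental genotypes,
every unit score is *linear* in offspring genotypes, so
`Var(T_ij) = Σ_c w_c² v_c / n²` where `v_c` is the Mendelian transmission
variance of child *c* (¼ per heterozygous parent) and `w_c` the child's
accumulated weight over units.  This correctly handles a trio and a DSP that
share an affected child — treating the units as independent (available as
`variance="unit"`) underestimates the variance there, which would bias the
region test anticonservatively.  DSPs whose parents are not genotyped at the
SNV fall back to the affection-label-swap variance `d²` and are treated as
independent of other units (an approximation, exact for DSP-only pedigrees).

**FBAT flavour.** `T_ij = Σ_offspring (y − offset)·(X − E[X | parents])`,
with `E` and `Var` from Mendelian transmission conditional on parental
genotypes and `Var(T_ij) = Σ (y − offset)² Var(X | parents)`.  With the
binary-trait default `offset = 0` only affected offspring contribute.
Offspring of distinct transmissions are conditionally independent, so this
variance is exact; families missing a parental genotype at a SNV contribute
nothing at that SNV (no sufficient-statistic reconstruction for missing
parents).

The classic single-SNV tests are included for validation:
PDT `z = Σ_i D_i / √(Σ_i D_i²)` (empirical variance) and FBAT
`z = Σ_i U_i / √(Σ_i Var(U_i))`, both standard normal under the null.

### Blocking

A gene's SNVs are partitioned into blocks assumed mutually independent;
within-block dependence is absorbed empirically.  Schemes:

* **Option 1** — fixed-width bp windows, half-open `[start, start+w)` from
  the smallest SNV position; a SNV on a boundary joins the right window;
  gene span ≤ window gives one block; empty windows are dropped.
* **Option 2** — the gene span cut into a fixed number of equal bp
  intervals; empty intervals are dropped, so the realized count can fall
  short of the request.
* **Option 3** — consecutive groups of a fixed number of position-ordered
  SNVs; the final block keeps the remainder, so `B = ceil(m/w)`.
* **Option 4** — a fixed number of consecutive groups with sizes as equal
  as possible (earlier blocks take the remainder); a gene with fewer SNVs
  than requested blocks gets singleton blocks, `B = min(request, m)`.
* **one-block** — no blocking (the whole gene in a single block).
* **adaptive** — contiguity-constrained average-linkage clustering on the
  distance `1 − |r|` between SNVs, with `r` the founder-genotype
  correlation.  Perfect-LD merges are always applied; the tree is cut
  before the largest jump between consecutive merge heights, provided the
  jump reaches `cut_gap = 0.1` (distances of thresholded rare-allele data
  are bounded away from zero, so an elbow must be sized in absolute terms);
  a gapless dendrogram leaves SNVs as singletons.  The constrained
  agglomeration is hand-written because standard hierarchical-clustering
  routines do not preserve positional contiguity.

### The region statistic

Within block *b*: `X_ib = Σ_{j∈b} T_ij²` with conditional null mean
`μ_ib = Σ_{j∈b} Var(T_ij)`.  Squaring stops risk and protective variants
from cancelling, so no assumption on effect directions is needed, and no
MAF threshold is imposed — rare and common SNVs are analysed jointly.

Across the `N_used` pedigrees that are informative anywhere in the gene:

    Z_b = Σ_i (X_ib − μ_ib) / sqrt( Σ_i (X_ib − μ_ib)² )

i.e. the deviation sum standardized by the pooled (known-mean) empirical
variance — the same device the classic PDT uses in its denominator.  The
pooling is what absorbs within-block LD: no model for the correlation among
the `T_ij²` within a block is ever needed.  Using instead the sample
variance of the raw `X_ib` would also absorb the across-pedigree spread of
`μ_ib` and visibly deflate `Z_b` (we measured one-block type I error of 0.0
at α = 0.01 under that variant), which is why the deviation form is used.

Assuming blocks are independent, `S = Σ_b Z_b²` is referred to a χ² with
`df` = number of non-degenerate blocks.  A block whose pooled variance is
zero carries no information and is excluded with a matching df reduction
(contributing 0 with full df would deflate type I error).  `N_used` counts
pedigrees informative anywhere in the gene, so all blocks share one
pedigree set; `N_used < 2` or zero usable blocks raise an
"uninformative gene" error.

`S` and the p-value are exactly invariant under relabeling the minor/major
allele at any subset of SNVs (the classic z statistics negate).

## The simulator

The generator reproduces a controlled validity design:

* **Founder haplotypes** by the threshold-multivariate-normal construction:
  draw `Z ~ N(0, R)` and set allele `j` to 1 iff `Z_j < Φ⁻¹(MAF_j)`, with
  `R` block-diagonal and AR within blocks (`R_jk = ρ^|j−k|` inside a block,
  0 across blocks).  Marginals match the target MAFs; the latent ρ maps to
  a weaker phi coefficient between rare alleles, as in real data.
* **Gene dropping**: each non-founder inherits one complete haplotype from
  each parent, uniformly and without recombination; fully vectorized across
  replicated families.
* **Trait**: affection drawn per individual from
  `logit P(Y=1) = β₀ + Σ_c β_c X_c`.

Defaults (the package's stated world, used by `scripts/acceptance.py` and
the acceptance tests):

| parameter | default | rationale |
|---|---|---|
| pedigree template | synthetic 4-generation, 90-member extended family (22 founders, 68 non-founders) | emulates the scale and founder fraction of extended-family reference panels; real structures are not redistributable, and a PED-file template can be substituted |
| number of pedigrees | 1000 | large enough that the χ² tail approximation of `S` holds (measured Option-4 type I ≈ 0.012–0.015 at α = 0.01; at 200–300 families it is visibly anticonservative) |
| gene | 20 SNVs, five position clusters of 4, width 14.02 kb | an LPL-like resequenced gene |
| MAFs | fixed vector, median ≈ 0.02, range 0.0025–0.11 | mostly rare plus a few low-frequency/common variants, analysed jointly without a threshold |
| LD | 5 independent blocks of 4 SNVs, within-block AR ρ = 0.9 | strong local LD, zero distant LD; Option 4 with 5 blocks is then the partition matching the truth |
| β₀ | logit(0.1) | 10% baseline prevalence |
| causal SNVs | 3, drawn among SNVs with 0.005 ≤ MAF ≤ 0.05 | rare but polymorphic, as in the gene the design emulates |
| effect sizes | per-allele OR 2 ("smaller") / OR 4 ("larger"), same-direction (+,+,+) or mixed (+,+,−) | field-typical rare-variant simulation magnitudes |
| nominal α | 0.01 | the level at which the validity study is evaluated |
| replicates | 1000 per scenario | resolves type I error near 0.01 to ±0.008 (99% binomial) |

Randomness: one root seed; every replicate stream derives from
`(seed, replicate_id)` so replicates are independently reproducible
bit-for-bit, and scenario configs get distinct sub-seeds.

An optional ascertainment filter resamples families until each has at least
one affected non-founder (off by default; no ascertainment is modelled in
the validity design).

### What the generator does and does not emulate

It reproduces family-enriched rare variation (a rare founder allele is
common among that founder's descendants), local LD with distant
independence, and Mendelian-consistent pedigree genotypes.  It does **not**
model recombination, mutation, population admixture or stratification,
genotyping error, missingness, or quantitative traits.  A green simulation
test therefore establishes calibration and power behaviour under clean,
correctly-specified family data — not robustness to the messiness of real
cohorts (though the tests' conditioning on parental genotypes confers the
usual family-design robustness to stratification, which the simulator does
not exercise).

## Evaluation

Empirical type I error and power are rejection proportions over replicate
streams; power is additionally reported at a critical value calibrated as
the empirical `(1−α)` quantile of the null statistic sample, which puts
methods with different finite-sample size on an equal-type-I footing.
Gene-level TPR/FPR are swept over thresholds to form ROC curves with
trapezoid AUC.

### Measured operating characteristics (desk scale)

All numbers below are recomputed by `scripts/acceptance.py` / the acceptance
tests at run time; representative values from a seed-1 run of the stated
world: Option-4 type I error ≈ 0.012 (rbPDT) and ≈ 0.015 (rbFBAT) at
α = 0.01; the one-block (unblocked) rbFBAT shows no material inflation
(≈ 0.009 in the same run).  We note explicitly: a *correctly centered* one-block
statistic absorbs all within-region LD in its pooled variance, so the large
single-block type-I inflation sometimes reported for unblocked region
statistics does not occur here; blocking's benefit in this implementation is
power (df economy and variance reduction), not rescue from a broken
one-block null.

## Numerical choices and degenerate inputs

* Minor alleles are determined from founders only; an exact 0.5 frequency
  tie goes to the lexicographically smaller allele label.
* Affection: PED 1/2 is remapped to 0/1 when any `2` is present, else 0/1
  is read directly; 0 (in 1/2 mode) and −9 are missing; individuals with
  missing affection join no informative unit.
* Missing genotypes: a unit (or FBAT offspring) missing any required
  genotype at SNV *j* is skipped at SNV *j* only; complete-data inputs use
  a vectorized path that is tested to agree exactly with the per-pedigree
  path.
* Half-sibs are not discordant sibpairs (both parents must be shared).
* Zero-variance SNVs in adaptive blocking are attached to their positional
  neighbour with a warning.
* Monomorphic SNVs/blocks contribute 0/0 and, if a whole block is
  uninformative, it is dropped with a df reduction.

## Known limitations

* Pedigrees with missing *parental* genotypes lose those families' FBAT
  (and trio) information at the affected SNVs; no Rabinowitz–Laird
  sufficient-statistic reconstruction is attempted.
* `Z_b` is asymptotic in the number of pedigrees; with only a few hundred
  small families the block statistics carry visible skew and the χ² tail
  is mildly anticonservative.  The per-block deviations `X_ib − μ_ib` are
  bounded-skew averages only when pedigrees are numerous.
* Between-block independence is an assumption, not an estimate: partitions
  that split strong LD across blocks can misbehave; the adaptive scheme
  exists to choose block boundaries from the data.
* X chromosome, multiallelic sites, imputation and quantitative traits are
  out of scope.
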