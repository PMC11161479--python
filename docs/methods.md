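# Methods

## The model

`wssgwas` implements weighted single-step GWAS for growth traits in a
livestock population where many animals are phenotyped over generations
but only a small, recent subset is genotyped. One trait is analysed at a
time with the maternal-effects animal model

    y = X b + Z a + W p + S m + e

where `b` are categorical fixed effects (sex, birth type, herd, birth
year, dam age class; dummy-coded with an intercept and the first sorted
level of each effect dropped), `a ~ N(0, K σ²_a)` the direct additive
genetic effects, `m ~ N(0, K σ²_m)` the maternal genetic effects of the
dams, `p ~ N(0, I σ²_p)` the maternal permanent-environment effects and
`e ~ N(0, I σ²_e)` the residual. The direct–maternal genetic covariance
σ_am is fixed at zero; the model statement carries four independent
variance structures and no covariance term. Weaning weights are
pre-adjusted to 90 days as `((WW − BW)/age) × 90`.

`K` is `A` (pedigree numerator relationships) for pedigree BLUP and REML,
or the single-step hybrid `H` when genotypes enter. The inverse used in
the mixed-model equations is

    H⁻¹ = A⁻¹ + [0 0; 0 G_ω⁻¹ − A₂₂⁻¹]

with `G_ω = α G + β A₂₂` (defaults α = 0.95, β = 0.05) and
`G = Z D Z′ / Σ 2 p_i (1 − p_i)` the weighted VanRaden genomic matrix
over the centered gene content `Z = counts − 2p`. Genotyped animals may
sit anywhere in the pedigree ordering; the genotyped block is updated by
scatter-add on their index set.

## The weighting iteration

Starting from equal SNP weights `D = I`, each iteration t:

1. builds `G(t) = λ Z D(t) Z′` (λ = 1/Σ2p(1−p)), blends with `A₂₂`,
   assembles `H⁻¹` and solves the MME for GEBVs;
2. converts genotyped GEBVs to SNP effects,
   `û(t) = λ D(t) Z′ G_ω(t)⁻¹ â_g`, separately for the direct (from â)
   and maternal (from m̂) effects;
3. re-weights each SNP with the nonlinearA rule
   `d_i = CT^(|û_i|/sd(û) − 2)`, CT = 1.125, with the exponent capped at
   5 so the largest weight is CT⁵ ≈ 1.802;
4. rescales the new weights so their sum (the trace of D) is unchanged,
   keeping the total genetic variance constant, and loops.

Three iterations are run by default. The weight update is driven by the
direct-effect û only (`weight_source` switches this): the procedure
defines a single D and a single loop, and maintaining separate weights
per effect type would imply a different G per effect. Back-solving uses
the blended `G_ω⁻¹` — the same matrix whose inverse enters `H⁻¹`. The raw
`λZDZ′` is singular whenever m ≫ n, and also whenever Z is centered at
the observed panel frequencies (each column of Z then sums to zero, so
the 1-vector is a null vector). The exact conversion identity
`Z û = â_g` therefore only holds with α = 1, external centering
frequencies (`run_wssgwas(..., freqs=...)`, the equivalent of a
frequency file) and m ≥ n; it is preserved as a test configuration.

## Window decomposition

Each genetic effect's variance is decomposed over fixed, non-overlapping
1-Mb bins anchored at bp 1 (bin k covers [(k−1)·10⁶ + 1, k·10⁶]; all
coordinates 1-based inclusive, PLINK convention). For each non-empty bin
the window genetic value `g_w = Σ_{j∈w} Z_j û_j` is computed per
genotyped individual and the table reports `100 · var(g_w) / σ²`, with
σ² = σ²_a for the direct effect and σ²_m for the maternal effect and
var(·) the sample variance (ddof = 1) across genotyped individuals. The
first/last SNP position and SNP count per bin are recorded; the top-k
ranking (default 10) breaks ties by genome order.

## Pedigree algebra

`A` is built with the tabular method (row-vectorised; O(n²) memory,
adequate to a few thousand animals). `A⁻¹` uses Henderson's rules with
exact Mendelian-sampling variances from parental inbreeding
(`d_i = 0.5 − 0.25(F_s + F_d)`), with F taken from the tabular diagonal,
so inbreeding is always accounted for. Unknown parents are unrelated,
non-inbred founders; genetic groups are not modelled. `A·A⁻¹ = I` holds
to 1e-8 at 500 animals, and A matches the empirical relationships of a
gene-dropping simulation within Monte-Carlo error.

## Genotype QC and imputation

Filters run in PLINK's conventional order: (1) unmapped or
non-autosomal SNPs, (2) individual call rate ≥ 0.95, (3) SNP call rate
≥ 0.95, (4) MAF ≥ 0.05, (5) Hardy-Weinberg exact test p ≥ 1e-6
(Wigginton-style conditional enumeration, validated against brute-force
enumeration). The per-step removal counts are reported and the battery
is idempotent. Missing calls surviving QC are imputed by a
Hardy-Weinberg draw at the SNP's observed frequency — at a small recent
panel with low missingness, haplotype-based imputation would change
little while adding an external phasing dependency. Centering and the G
denominator use the counted-allele frequency (mean count / 2): G is
invariant to which allele is counted under 0−2p coding, so this
coincides with MAF-based centering up to relabelling.

## REML

Variance components are estimated from pedigree and records. The MME are
assembled sparse; every factorization uses SuperLU in symmetric mode
(fill-reducing symmetric ordering, diagonal pivoting), which for these
SPD systems yields `P′ L D L′ P`. The EM updates

    σ²_a ← (â′K⁻¹â + σ²_e tr(K⁻¹ C_aa)) / q        (likewise σ²_m)
    σ²_p ← (p̂′p̂ + σ²_e tr(C_pp)) / n_dams
    σ²_e ← (y′y − θ̂′r) / (n − rank X)

need entries of `C = M⁻¹` only on the sparsity pattern of M, so the
traces are computed exactly with the Takahashi recurrence on the factor
(selected inverse; numba-compiled, validated against dense inverses) at
a small fraction of the cost of a full inverse. EM is monotone in the
restricted likelihood — the log-likelihood, evaluated from the factor's
log-determinant, is checked non-decreasing — but its convergence tail is
very slow for maternal models. `method="ai"` therefore takes
average-information Newton steps from the exact REML gradient (the same
selected-inverse traces give `tr(P V_i)` in closed form; the AI matrix
needs only four extra MME solves), falling back to an EM sweep whenever
a step fails or leaves the parameter space; both methods share their
stationary points, which the tests verify by confirming the AI solution
is an EM fixed point. Components drifting to zero are pinned at a floor
of 1e-8 × var(y); non-convergence warns and returns the last iterate.

Identifiability: σ²_m and σ²_p are both dam-level variances, separated
only by the genetic covariance among related dams and across
generations. At ~1,500 records their REML split is close to
unidentifiable (corner solutions); at ~3,000 records on ~600 repeatedly
recorded dams the split is well behaved. The statistical tests therefore
run at that scale (see below).

## The synthetic generator

`wssgwas.simulate` emulates the target data structure: discrete
generations, random sire × dam pairing without selfing, many phenotyped
but few genotyped (a random subset of the last generation is released,
with calls masked at 2% missingness). Founder alleles are drawn per SNP
at Uniform(0.05, 0.5) frequency and transmitted by gene dropping; SNPs
are unlinked with uniform bp positions on 5 chromosomes of 100 Mb —
window analysis needs only coordinates, and no use is made of LD, so
linkage realism is deliberately out of scope. Breeding values are a QTL
part (5 direct + 5 maternal QTL, jointly 50% of their component's
variance, effects scaled against the realized count variance) plus an
infinitesimal part bred down the pedigree with inbreeding-adjusted
Mendelian sampling. Default variance components are
(σ²_a, σ²_m, σ²_p, σ²_e) = (2, 1, 0.5, 4) kg², a trait mean of 4 kg and
small fixed effects — birth-weight-like numbers. Each dam produces 4
offspring (a ewe's lambs across parities), which is what makes σ²_p
estimable at all.

Two standard scales are used:

* **pipeline preset** (`SimConfig()` defaults): 400 founders + 4
  generations of 400 (2,000 animals, 1,600 records), 5,000 SNPs, 300
  genotyped — fast end-to-end demonstration;
* **study conditions** (statistical tests, acceptance script): 400
  founders + 4 generations of ~750 (~3,400 animals, ~3,000 records,
  ~570 dams), 300 genotyped, where both REML recovery and QTL window
  localization are statistically comfortable at desk runtimes
  (a few seconds per replicate).

What passing tests show — and what they do not: the generator matches
the model's own assumptions (no LD, no selection, random mating,
homogeneous residuals, categorical effects assigned at random), so the
tests demonstrate correctness of the algebra and estimators under those
assumptions, not robustness to the selection, assortative mating,
heterogeneous recording and LD structure of real station data.

## Numerical choices

* Blending defaults α/β = 0.95/0.05; no rescaling of G toward A₂₂ means
  beyond blending. G and H⁻¹ are symmetrized (½(M + M′)) after assembly.
* Dense Cholesky for G_ω⁻¹ and A₂₂⁻¹ (panel sizes ≈ hundreds); sparse
  symmetric factorization for every MME solve, with one iterative
  refinement step if the relative residual exceeds 1e-8.
* MME block order is (fixed, direct, permanent-environment, maternal);
  solutions are returned keyed by original animal labels.
* Degenerate inputs raise informative errors: pedigree cycles name an
  animal on the cycle, monomorphic SNPs in G point to QC, singular G_ω
  advises blending, a record with an unknown dam rejects the maternal
  model fit.
* Ties in the top-k window ranking resolve by (chromosome, start);
  `sd(û) = 0` in the weight update warns and returns equal weights.
* All stochastic steps (simulation, imputation) take explicit seeds;
  deterministic paths are bit-stable for identical input order, and the
  CLI `full` run is byte-reproducible given config + seed.

## Known limitations

* Single trait, one record per animal; no σ_am covariance (config
  switch reserved), no unknown-parent groups or metafounders, no
  dominance/epistasis.
* The tabular A is dense O(n²): fine to ~5,000 animals, not for a
  100k-animal national evaluation (a Meuwissen–Luo F computation without
  the full A would be the first upgrade).
* Naive Hardy-Weinberg imputation ignores haplotype information; at
  >10% missingness a proper imputation tool should replace it.
* Window percentages are reported without significance measures;
  bootstrap or permutation inference is out of scope.
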