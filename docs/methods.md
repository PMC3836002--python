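# Methods

## Model and statistic

The package tests association between a biallelic marker and a disease in
mixed data: `N` case-parent trios (an affected offspring with both
parents genotyped) plus `M` unrelated controls. Genotypes are counts of
the "1" allele (conventionally the minor allele; the choice only flips
signs and leaves two-sided p-values unchanged).

Two standard components are combined:

* **Trend statistic** `P = (R̄ − S̄)/sqrt(σ²(1/N + 1/M))`, the difference
  in mean allele counts between cases and controls standardized by its
  null standard error. With `σ² = 2p(1−p)` this is the classic pooled
  two-sample z-test of allele proportions, and `P²` is the
  Cochran–Armitage trend χ² under HWE.
* **Transmission (Wald) statistic** `F = (ΣT − H/2)/sqrt(H/4)`, where `H`
  counts heterozygous parents and `ΣT` the "1" alleles they transmitted
  to their affected children. `F²` is exactly the TDT χ²
  `(b−c)²/(b+c)`; the implementation verifies this identity exhaustively.
  Transmissions are counted without phasing: each homozygous "1/1" parent
  transmits exactly one "1" allele, so `T_i = child − #(parents with
  genotype 2)` per trio, and any triple for which this count falls outside
  `[0, h]` is Mendelian-inconsistent (dropped with a warning by default,
  fatal under `strict`).

Both components are asymptotically N(0,1) under the null but share the
case genotypes. Conditional on parental genotypes, a case genotype
decomposes into the deterministic contribution of its homozygous parents
plus the Bernoulli(½) transmissions from its heterozygous parents — the
very transmissions `F` counts — so `Cov(ΣR, ΣT | parents) = H/4`, and
after standardization

```
τ = sqrt(H) / (2N · sqrt(σ²(1/N + 1/M))).
```

The combined statistic `z = [wP + (1−w)F]/sqrt(w² + (1−w)² + 2w(1−w)τ)`
is then standard normal under the null. Replacing `H` by its null
expectation `2Nσ²` (per-parent heterozygosity equals `σ²` under HWE)
shows `τ → ½` when `N = M`, a value the test suite confirms against the
empirical null correlation of `(P, F)` over 10⁵ Monte-Carlo replicates at
five `(N, M, MAF)` settings.

Because the observed `H` and estimated `σ̂²` are plugged in, `τ` can
marginally exceed 1 in small samples with rare alleles; it is clipped at
1 (a covariance of two unit-variance statistics cannot exceed it).

## Parameters and defaults

* `weight_mode="half"` fixes `w = ½`, appropriate when the components
  have comparable power (balanced `N ≈ M`); `"sample_size"` uses
  `w = A/(A+H)`, `A = NM/(N+M)` (half the harmonic mean), which moves
  weight toward the trend test when few parents are informative.
* `variance_mode="hwe"` uses `σ² = 2p̂(1−p̂)`; `"mom"` uses the
  method-of-moments genotype variance `[4g₂ + g₁ − nḡ²]/n`, robust to
  HWE departures (applied to the pooled sample when `maf_source=
  "pooled"`, otherwise to the controls, since untransmitted alleles do
  not form genotypes).
* `maf_source="untransmitted"` (default) estimates `p` from the control
  alleles plus the `2N` parental alleles *not* transmitted to the
  affected offspring (`father + mother − child` per trio). Under random
  mating the untransmitted alleles are unbiased population draws even
  under case ascertainment, so the estimate is valid under both the null
  and the alternative; pooling them with the controls halves the
  estimator's noise relative to controls alone, which measurably reduces
  the small positive mean (≈ +0.02 → +0.009 at MAF 0.09, N=M=200) that
  `P` otherwise acquires through the correlation between its numerator
  and a control-only `σ̂`. `"controls"` and `"pooled"` are provided for
  comparison; the pooled estimate is inflated by the ascertained cases
  under an alternative and costs several points of power at rare MAFs.
* `H = 0` (no informative parent): the family component carries no
  information and the test degrades gracefully to the trend statistic
  (`w = 1, τ = 0`). If the population-frequency sample is monomorphic,
  the variance falls back to the pooled sample; a marker monomorphic
  everywhere is reported as a flagged row by the scan rather than
  aborting it.
* P-values are two-sided normal tails throughout.

## Simulator

The generator realizes the validating study's conditions. A disease
locus (risk allele frequency `daf`, penetrances `f0, f1, f2`) and a
marker (MAF equal to `daf` by default) are linked through haplotype
frequencies with `D = D′·Dmax`, `Dmax = min(p_m(1−p_d), (1−p_m)p_d)`,
the "1" allele coupled positively to the risk allele (the sign is
irrelevant to two-sided tests). Trios are drawn by rejection: two
haplotypes per parent i.i.d. under random mating, one transmitted per
parent uniformly, acceptance with probability equal to the offspring's
penetrance — so the acceptance rate equals the population prevalence
`K = f0(1−p)² + 2f1 p(1−p) + f2 p²`. Controls are population draws by
default (`mode="unaffected"` additionally rejects affected individuals;
with `K = 5%` the difference is small but not nil at rare MAFs). Null
data involve no disease locus at all: HWE parents, Mendelian
transmission, HWE controls.

The six built-in scenarios span risk-allele frequencies 0.03–0.30 with
penetrances tuned to `K = 5%` and a 4.5% phenocopy rate (`f0 = 0.045`),
deliberately neither additive, dominant, multiplicative nor recessive;
`D′ = 0.80` throughout. The exact conditional distribution of accepted
trio genotypes is computable by enumerating the parental haplotype
space, and the test suite holds the sampler to it within Monte-Carlo
error.

What the generator does *not* emulate: population stratification or
admixture, genotyping error, missingness, linked markers/haplotypes
beyond the single tagged locus, extended pedigrees, and covariates.
Passing tests therefore demonstrate correctness of the statistic and its
calibration under a homogeneous, cleanly-typed population — not
robustness to those real-data complications.

## Study machinery and problem sizes

`run_type1` / `run_power` estimate rejection rates at 200 trios + 200
controls; replicate `r` is seeded `base_seed + r`, so results are
identical regardless of execution order. The test suite reproduces the
validation numbers at 1000 replicates per scenario (matching the original
study design) and checks type-I error on 10⁴ null replicates; the
acceptance script uses 10⁴ replicates per scenario to report power with
~0.5-point Monte-Carlo error. Monte-Carlo standard errors
`sqrt(p(1−p)/n)` accompany every estimate.

## Known limitations

* **Null distribution is near-normal, not exactly normal.** The
  statistic lives on a fine lattice (integer allele counts) and uses
  plug-in `σ̂²` and `τ̂`; at `N = M = 200` its null law differs from
  N(0,1) by a sup-distance of roughly 0.006 at MAF 0.09–0.30. Rejection
  rates at the 5% and 1% levels are correct to within Monte-Carlo error,
  but a Kolmogorov–Smirnov test at n = 10⁴ sits on its own rejection
  boundary: across repeated draws it rejects at the 1% level in roughly
  3–13% of runs (more often at rarer MAFs). Two parametrizations of the
  KS acceptance test are red at the suite's fixed seed for exactly this
  reason; the operational calibration checks pass.
* At MAFs below ~0.09 with these sample sizes, asymptotics degrade
  further (the trend test's rejection rate can drift ~1 point above
  nominal); exact or permutation p-values would be preferable for very
  rare variants.
* The sample-size weight `w = A/(A+H)` is exposed but the power study
  fixes `w = ½`; no attempt is made to estimate an optimal weight from
  data.
* Large families are handled only by decomposition into trios with both
  parents genotyped; no extended-pedigree component statistic (e.g.
  GDT/PDT-style) is provided, and no stratification-robust variant of
  the trend component is implemented.
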