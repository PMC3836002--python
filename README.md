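# popfam

Combined population- and family-based testing of genetic association for
*mixed* study designs: case-parent trios analysed together with unrelated
controls, where the affected offspring serve simultaneously as the cases
of a case-control comparison and as the children of a transmission
comparison.

Case-control (trend) tests detect allele-frequency differences but ignore
the preferential transmission of risk alleles from heterozygous parents;
the transmission disequilibrium test (TDT) does the opposite. Because both
tests use the genotypes of the same affected individuals they are
positively correlated under the null, so naively adding them miscalibrates
the type I error. This package combines them with an explicit closed-form
null covariance, yielding a single nonparametric statistic that is
standard normal under no association and more powerful than either
component alone.

## The statistic

At a biallelic marker, for `N` case-parent trios and `M` controls, let
`R_j` and `S_k` count the "1" alleles of case `j` and control `k`, let `H`
be the number of heterozygous parents across trios and `ΣT_i` the number
of "1" alleles they transmitted to their affected offspring. The two
components are

```
P = (R̄ − S̄) / sqrt(σ²(1/N + 1/M)),        σ² = 2p(1−p) under HWE
F = (ΣT − H/2) / sqrt(H/4)                  (F² is the TDT χ²)
```

and the combined statistic, for a weight `w ∈ [0, 1]`,

```
z = [ wP + (1−w)F ] / sqrt( w² + (1−w)² + 2w(1−w)·τ )
```

where `τ = Cov(P, F)` under the null. Conditional on parental genotypes
each case genotype is the deterministic contribution of its homozygous
parents plus the Bernoulli(½) transmissions counted by `F`, giving
`Cov(ΣR, ΣT) = H/4` and hence the closed form

```
τ = sqrt(H) / ( 2N · sqrt(σ²(1/N + 1/M)) ).
```

By default the allele frequency `p` in `σ²` is estimated from the controls
*plus the parental alleles not transmitted to the affected offspring* —
both are draws from the population that are unbiased even under case
ascertainment. A method-of-moments genotype variance (`variance_mode=
"mom"`) is available when HWE is doubtful, and `w` can be fixed at ½ (the
default, appropriate for balanced designs) or computed from sample sizes
as `w = A/(A+H)` with `A = NM/(N+M)`.

The package also ships the conditional genotype simulator used to
validate the test — a two-locus penetrance model (disease locus + marker
in LD `D′`) with rejection sampling on offspring affection status — and
the type-I-error / power study machinery built on it.

## Worked example

Simulate one marker under scenario S1 (risk-allele frequency 0.03, strong
heterozygote effect, 5% prevalence, marker in LD `D′ = 0.8`) and test it:

```python
import numpy as np
from popfam import SCENARIOS, simulate_alt_dataset, popfam_test

ds = simulate_alt_dataset(SCENARIOS["S1"], 200, 200, np.random.default_rng(7))
r = popfam_test(ds)
print(f"P={r.P_stat:.3f} F={r.F_stat:.3f} tau={r.tau:.3f} "
      f"z={r.z:.3f} p={r.p_value:.4g} H={r.H}")
```

prints

```
P=3.328 F=2.160 tau=0.634 z=3.036 p=0.0024 H=42
```

The case-control component alone gives `P = 3.33`; 42 parents were
heterozygous and over-transmitted the tagging allele (`F = 2.16`); the two
pieces of evidence, combined with their null correlation `τ = 0.63`,
give `z = 3.04` (two-sided p = 0.0024).

The same analysis from the shell, via PED/MAP files:

```
popfam simulate --scenario S1 --trios 200 --controls 200 --seed 7 --out s1demo
popfam assoc s1demo.ped s1demo.map
popfam power --reps 1000 --seed 42          # full six-scenario power table
```

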