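# mshtc

Maximum-likelihood estimation of **first coalescent times** for individual
variant copies — including singletons — in phased population haplotype
data, from **maximum shared haplotype (msh)** lengths.

## The problem

The age of an allele, relative to its frequency, carries information about
selection and demography: functional alleles under directional selection
are younger than neutral alleles at the same frequency. Classical
allele-age estimators use variation *among* the copies of an allele and so
cannot touch the rarest variants. `mshtc` instead estimates, for each copy
of a variant on a focal chromosome, the time `t_c` (in generations) at
which that chromosome's lineage first coalesces with a lineage *not*
carrying the variant. The mutation creating a derived allele occurred
somewhere on that branch, so `t_c` upper-bounds the allele's age (a
neutral singleton has expected age `t_c / 2`), and the estimator works for
every copy individually — singletons included.

## The model

Looking 5′ or 3′ from a focal base, the distance to the first observable
difference between the focal chromosome and its closest relative (the
*sister*) is approximately exponential: mutations arrive at rate `μ` per
bp per generation along the focal branch (length `t_c`) and the sister
branch (length `φ ≤ t_c`), and recombination at the local map rate `ρ`
acts as an additional tract terminator. The observable is the **msh**: the
longest identity tract flanking the focal base against *any* non-carrier,
measured separately in each direction and extracted in linear time with
the positional Burrows–Wheeler transform (PBWT). Tract lengths fold into a
composite event statistic

```
χ = μ·(msh₅′ + msh₃′) + c₅′ + c₃′        β = (μ + ρ₅′)(μ + ρ₃′)
```

with `c` the Morgans spanned by each tract and `ρ` the per-base rates at
the tract ends. The per-copy likelihood marginalizes the unobserved sister
branch length `φ` over its coalescent density (for a constant diploid
population of size `N` and sample of `n` chromosomes: density
`n/(4N + n·t_c)` on `[0, t_c)` plus a point mass at `φ = t_c`):

```
p(χ | t_c) = ∫₀^tc p(φ) β (t_c+φ)² e^{−χ(t_c+φ)} dφ
             + p(φ = t_c) β (2t_c)² e^{−2χ·t_c}
```

with a single-event kernel when one direction is truncated at the end of
the chromosome. The product over the `k` copies of an allele (times the
derived-allele factor `1 − e^{−μ t_c}`) is a composite likelihood,
maximized over `log10(t_c)` by bounded Brent search. The same machinery
phases heterozygous singletons: the variant is assigned to the chromosome
of the diploid with the larger estimated `t_c`, correct with probability
`t_c / (t_c + t_c*)`.

## Worked example

Estimate `t_c` for every variant of a phased VCF under a uniform
recombination map, and re-phase singletons first:

```
mshtc estimate sample.vcf --rho 1e-8 --mu 1e-8 --rephase-singletons -o out.tsv
```

Equivalent library use, on simulated data with known truth:

```python
from mshtc import (EstimationParams, GeneticMap, estimate_all, evaluate,
                   simulate_sample)

sim = simulate_sample(demography="constant", n=100, L_bp=2_000_000,
                      mu=1e-8, rho=1e-8, seed=1)
params = EstimationParams(mu=1e-8, gmap=GeneticMap.uniform(1e-8), n=100)
est = estimate_all(sim.matrix, sim.records, params)
pairs = est.merge(sim.truth[["site", "tc_true"]], on="site")
print(pairs[["pos", "k", "msh5_bp", "msh3_bp", "tc_hat", "tc_true"]].head(3))
report = evaluate(pairs["tc_hat"], pairs["tc_true"])
print(f"RMSE {report.rmse:.3f}  bias {report.bias:+.3f}  r {report.r:.3f}")
```

prints (seed 1):

```
   pos   k  msh5_bp  msh3_bp        tc_hat       tc_true
0   50   7     49.0  14367.0   4464.202250   3812.476157
1  580  45    579.0    619.0  32420.171254  53053.813560
2  592  11    591.0  13879.0   2366.498619   8926.585895
RMSE 0.519  bias -0.222  r 0.776
```

Each row is one variant: its derived-allele count `k`, the 5′/3′ msh
tracts of its first copy in bp, the pooled maximum-likelihood `t_c` in
generations, and the true first coalescent time read from the simulated
genealogy. The summary line says estimates are typically within a factor
`10^0.52 ≈ 3.3` of the truth at this configuration, with the method's
characteristic mild underestimation.

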