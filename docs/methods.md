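# Methods

## Model and estimand

For a focal base on a focal chromosome sampled from a population, let
`t_c` be the number of generations back to the first coalescence of that
chromosome's lineage with any other sampled lineage at that base — for a
variant copy, with any lineage *outside the set of carriers*. `t_c` is the
estimand throughout. It upper-bounds the age of a derived allele on the
focal branch; a neutral singleton has expected age `t_c/2` (documented,
not asserted anywhere in code).

The observable is the maximum shared haplotype: in each direction from the
focal base, the longest tract of sequence identity between the focal
chromosome and any chromosome not carrying the focal variant. Under a
Poisson model, mutation (rate `μ`/bp/generation) and recombination (local
map rate) terminate the tract of identity with the true sister lineage at
distance ~ Exponential with rate proportional to `t_c + φ`, where `φ` is
the length of the sister branch. The two directions are conditionally
independent given `(t_c, φ)`. Tract endpoints are converted to the
composite statistic `χ = μ(msh₅′+msh₃′) + c₅′ + c₃′` (Morgans from the
genetic map) with rate product `β = (μ+ρ₅′)(μ+ρ₃′)`; a tract that runs to
the end of the assayed region contributes only a no-event factor (the
`χ_eoc`, `β_eoc = μ+ρ` forms). When both directions are truncated the
likelihood degenerates to a pure no-event term and the estimate is flagged
low-information.

Key approximations inherited by design, and their known consequences:

* the density of the msh is approximated by the density of the distance to
  the nearest event on the focal or sister branch (`x_AS`). Because the
  msh maximizes over all non-carriers, it can exceed `x_AS` when the
  nearest event lies on the sister branch and a non-sister happens to
  share further (at `n = 100`, `ρ = 0` we measure `msh = x_AS` for ~79% of
  singleton tract ends and `msh > x_AS` for ~18%). The surplus tract
  length produces the estimator's characteristic negative bias, strongest
  for common variants (many non-carriers to maximize over).
* recombination is treated as a terminator like mutation; at map rates
  well above `μ` this degrades estimates and flips the bias positive.
* the `k` copies of an allele are treated as independent (composite
  likelihood), though they share the genealogy.

## Sister-branch density and the constant-N closed form

The number of lineages ancestral to a sample of `n` chromosomes `t`
generations ago is approximated by `n(t) = n / (1 + (n/2) τ(t))` with
`τ(t) = ∫₀ᵗ dt'/(2N(t'))`. Writing the sister branch length `φ` forward
from the coalescence at `t_c`, the per-branch coalescence hazard is
`λ(φ) = n / (2 N(t_c−φ)(2 + n τ(t_c−φ)))`, and the survivor function has
the closed form `n(t_c)/n(t_c−φ)`, so the density needs no inner
quadrature; any leftover mass sits at `φ = t_c` (single sister). For
constant `N` this collapses to density `n/(4N + n t_c)` on `[0, t_c)` and
point mass `4N/(4N + n t_c)` — the form used by default.

Substituting the constant-N density into the per-copy likelihood and
integrating gives closed forms. They are evaluated in log space through
the auxiliary integrals `E_m(t) = ∫₀¹ sᵐ e^{−ts} ds` (`t = χ·t_c`;
`m ≤ 2`), computed by an 18-term alternating series below `t = 0.1` and
`expm1`-based expressions above. The naive expanded polynomial-times-
exponential form cancels catastrophically as `χ·t_c → 0` (relative error
above 10⁶ at `χ·t_c ~ 10⁻⁷` in double precision); the `E_m` form agrees
with adaptive quadrature of the defining integral to better than 10⁻⁹
across `t_c ∈ [10, 10⁵]`, `χ` over six decades. Quadrature remains
available (`use_quadrature=True`) and is the estimation path for
tabulated, non-constant `N(t)`.

## msh extraction

Prefix (`a`) and divergence (`d`) arrays are built per Durbin's PBWT
algorithm 2, one forward and one reverse pass, in O(rows × sites). At the
focal column, the best match between the focal row and any allowed row is
found by scanning outward from the focal row's sorted position, keeping a
running maximum of `d` until the first allowed row in each scan direction;
the smaller of the two running maxima is the match start. Conventions:

* the focal variant's own column never terminates a tract (the mutation
  being dated is not evidence against identity); estimates at arbitrary
  non-variant bases use the same rule via virtual column lookup.
* msh length is, by default, the bp distance from the focal base to the
  first mismatching *site* (the first base observably not identical); an
  alternative ``match`` convention measures one SNP interval shorter, to
  the farthest matching site as read directly off the divergence array.
  The true terminating event is interval-censored between the two; the
  choice only matters when tracts shrink toward the inter-SNP spacing
  (measured head-to-head, the default gives lower RMSE and slightly more
  negative bias). Zero-length tracts are valid observations.
* ties among equally long matches report the lowest row index
  (determinism only; `χ` ignores the partner identity).
* a tract with no mismatch before the first/last assayed site is
  truncated; end-of-chromosome distances run to the contig bounds when a
  contig length is declared and to the outermost variant otherwise (no
  mismatch is observable beyond it in either case).

A brute-force O(rows × sites) scan is kept as an independent oracle; the
two paths agree exactly on randomized matrices (asserted in the suite).

## Estimation

The composite log likelihood (sum over copies, plus `log(1 − e^{−μ t_c})`
once per derived allele) is maximized over `log10(t_c) ∈ [0, 7]` with
bounded Brent search, absolute tolerance 10⁻⁴ on the log scale; `t_c`
spans decades, so the log parameterization keeps the search
well-conditioned. Non-convergence falls back to a 2000-point log-spaced
grid and is flagged. The profile is unimodal on all tested observation
sets. Estimates are weak functions of the reference size `N₀` (log10
estimates at `N₀ = 10⁴` vs `10⁵` correlate above 0.99), which is why a
constant-`N = 10⁴` default is adequate in practice.

Defaults: `μ = 10⁻⁸`/bp/generation, `N₀ = 10⁴` (diploid), `n` = number of
chromosomes in the input, uniform map `ρ = μ` unless a map file is given.

## Site filtering

CpG/TpG transitions (C→T with reference G at +1; G→A with reference C at
−1) carry elevated and heterogeneous mutation rates and can be masked
given a reference FASTA. The default policy removes masked sites from the
matrix entirely — they neither receive estimates nor terminate tracts,
which is the consistent choice under a constant-`μ` model; a `terminator`
policy retains them as tract-ending mismatches only. Missing genotypes
are a hard error by default; the alternative drops the whole individual
for the chromosome, because dropping single sites would lengthen msh
tracts artificially.

## Singleton phasing

For a diploid heterozygous at a singleton site, both placements are
evaluated: all singleton columns are masked (their phase is exactly what
is unknown), `t_c` is estimated for each of the individual's two
chromosomes at the focal position, and the variant goes to the chromosome
with the larger estimate — equivalently the shorter msh tracts — with
confidence `t_c/(t_c + t_c*)`. Decisions are made independently against
the masked matrix and committed together, so results are order-invariant
and re-phasing is idempotent. Ties (|Δlog10 t_c| < 10⁻³, below optimizer
tolerance) go to the first chromosome and are flagged; for ties the
estimate is insensitive to the assignment. Re-extracting msh values after
committing assignments is left to the caller (assignments cluster
singletons onto fewer chromosomes and lengthen tracts).

## Synthetic data and what the tests show

`mshtc.simulate` generates samples with `msprime` under three demographies
used for validation: constant `N = 10⁴`; exponential growth from 10⁴ to
5×10⁵ over the 200 generations before sampling; and the Gutenkunst et al.
(2009) out-of-Africa model (sampling the European deme; parameters
hard-coded from that source at 25 years/generation). Mutations use a
binary 0/1 model on a discrete genome; sites hit more than once are
dropped so every variant has a single origin, which makes the truth exact:
all `k` copies share `t_c` = the time of the parent node of the mutation's
edge, read directly from the tree sequence, and `φ` is the sister edge
length below it. Default validation scale is 2 Mb × `n = 100` × 3 seeds
(about 4000 variants per seed), which reproduces the method's accuracy
profile at desk scale; metrics are RMSE and mean signed error of
log10(t_c) and Pearson's r of true vs estimated log10 values, overall and
by frequency stratum.

The generator emulates neutral, uniformly mutating, uniformly recombining
sequence with perfect genotypes and known ancestral states. It does not
emulate sequencing error, low-coverage dropout of rare variants (which
lengthens msh tracts and deflates estimates), mutation-rate
heterogeneity (beyond the CpG mask), gene conversion, or selection — so
passing tests certify the estimator under its own model assumptions, not
robustness to those artifacts.

At the default validation conditions (`μ = ρ = 10⁻⁸`, known phase) the
suite observes RMSE ≈ 0.5 over all variant frequencies — dominated by
common variants, whose many non-carriers inflate the msh maximum — with
rare-variant strata near 0.4 and overall bias ≈ −0.22; the favorable
configuration (`n = 1000`, `ρ = 0.1μ`) reaches r > 0.9. The idealized
frequency-based comparator `τ_k` (per-frequency mean of true log10 `t_c`,
the least-squares optimum for any frequency-only estimator) explains zero
within-frequency-class variance by construction, which is the contrast
that motivates a per-copy estimator for rare alleles.

## Numerical and degenerate cases

* `χ = 0` (no observable events) is handled by the same log-space forms.
* Underflow is impossible by construction: all likelihood terms are
  assembled as logs and combined with `logaddexp`.
* Monomorphic columns are excluded at ingestion; a variant carried by
  every chromosome has no non-carrier and is rejected.
* Genetic maps interpolate linearly in cumulative Morgans and extrapolate
  at the terminal interval's rate; the local rate at an interior anchor is
  the right-hand interval's slope (deterministic tie-break, negligible
  effect).

## Limitations

Composite-likelihood pooling understates uncertainty for `k > 1`; no
standard errors are reported. The arbitrary-map likelihood assumes the
map is correct at msh-tract scale. The estimator assumes known ancestral
alleles (REF = ancestral). Very high recombination (`ρ ≫ μ`) shortens
tracts toward the inter-SNP spacing and degrades estimates with a
positive bias, as the validation harness can demonstrate.
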