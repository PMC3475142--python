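# Methods

## Scope and model

`linkpower` is a simulation study of two-point linkage statistics at a
single autosomal marker, asking how pedigree structure and the true mode
of inheritance affect the power to detect a complex-disease locus, and
how the null distributions of the statistics depend on structure.

**Trait model.** A diallelic trait locus with disease allele frequency
`p` and penetrances `f0 <= f1 <= f2` (probability of affection given
0/1/2 disease alleles). Phenocopies enter through `f0 > 0`; reduced
penetrance through `f2 < 1`. Three generating models (MOIs) are fixed
constants, calibrated upstream for roughly 80% power with 500 affected
sib pairs:

| MOI | f0 | f1 | f2 | p |
|---|---|---|---|---|
| dominant | 0.04 | 0.20 | 0.20 | 0.05 |
| additive | 0.03 | 0.13 | 0.23 | 0.10 |
| recessive | 0.04 | 0.04 | 0.20 | 0.20 |

Parametric analysis deliberately uses *different* parameters (AMOIs):
`f0 = 0.003`, `f2 = 0.5`, `f1 in {0.5, 0.25, 0.05}` for
dominant/additive/recessive, all with `p = 0.25`. The mismatch mimics
real complex-trait analysis where the generating model is unknown; a
high assumed `p` buffers penetrance misspecification.

**Marker.** One marker with 8 equifrequent alleles (high polymorphism
information content), in linkage equilibrium with the trait locus. All
members are genotyped.

**Pedigree structures.** Nuclear families with two genotyped,
phenotypically unknown parents and 2–4 children: ASP/AST/ASQ (2/3/4
affected sibs), DST/DSQ (2 affected + 1/2 unaffected sibs). Two
three-generation structures (A3G/D3G) with six members: grandparents
(unknown phenotype), one of their children plus a married-in founder
spouse, and two grandchildren. The extracted source text does not pin
down the three-generation affection placement, so the builder is
parameterized; defaults are all four descendants affected (A3G) and,
for D3G, the two grandchildren affected with their parents unaffected —
chosen so the affected pair is a sibship with variable allele sharing
(an affected parent–child pair shares exactly one allele always, which
would make the sharing statistics degenerate). Homogeneous samples use
500 pedigrees; the mixed sample is 100 AST + 100 ASQ + 100 DST +
100 DSQ (400 pedigrees, as specified — not 500).

## Simulation

Each non-founder receives one allele per parent; the transmission
choices form an inheritance vector `v` with one bit per meiosis (m bits,
uniform prior `2^-m`).

*Null (H0):* founder marker alleles i.i.d. from the allele frequencies,
`v` uniform — marker independent of the trait, affection pattern fixed.

*Alternative (H1, complete linkage):* a phased trait-locus
configuration — founder-haplotype disease indicators `a` plus inheritance
vector `v` — is drawn from its exact posterior given the affection
pattern, `P(a, v | Phi) ∝ p^|a| (1-p)^(2F-|a|) 2^-m Π_i P(Phi_i |
count_i(a, v))`, enumerated over all `2^(2F) × 2^m` configurations.
Marker alleles are assigned i.i.d. to founder haplotypes and transmitted
along exactly the same meioses (recombination fraction 0), so marker IBD
equals trait IBD bitwise. Exact enumeration replaces rejection sampling
because multi-sib affection patterns can have acceptance probabilities
near 1e-5, hopeless at millions of pedigrees.

## Statistics

All statistics are computed from the marker data and affection pattern
only.

**IBD posterior.** `P(v | M) ∝ P(M | v) 2^-m`, with `P(M | v)` summed
over heterozygote phases and founder-allele assignments consistent with
the observed (unordered) genotypes.

**NPL.** Pairs scoring: `S(v)` is the total IBD allele count over
unordered pairs of affected members. Per pedigree
`z = (E[S | M] - mu) / sigma` with `mu`, `sigma` the moments of `S`
under the uniform prior ("perfect-data" standardization — the classical
choice; with a near-fully-informative 8-allele marker it differs from
exact-variance normalization only marginally and errs conservative).
Sample NPL is `sum(z_i)/sqrt(n)` with equal weights.

**KC-LOD.** One-parameter linear allele-sharing model: maximize
`sum_i log10(1 + delta * gamma_i * z_i)` over `delta >= 0`,
`gamma_i = 1/sqrt(n)`. The objective is concave; `sum(z) <= 0` pins
`delta = 0` (score 0). The upper bound keeps every observed term
positive; if no observed `z` is negative the bound derived from the
smallest *achievable* `z` per structure is used (always finite).
Maximization is bounded Brent to `xatol = 1e-8`, validated against a
100,001-point grid.

**LOD.** Two-point parametric likelihood ratio. Per pedigree,
`LR(theta) = sum_S qhat_S rhat_S (1 - 2 theta)^|S|` over meiosis subsets
`S`, where `qhat`/`rhat` are Walsh–Hadamard transforms of the
marker-side posterior and the (normalized) trait-side vector
`P(Phi | v)`. This closed form follows from the eigendecomposition of
the per-meiosis recombination coupling and makes the whole theta curve a
degree-m polynomial in `(1 - 2 theta)`. The statistic maximizes the
sample LOD over the grid theta = 0, 0.02, …, 0.48 (ties toward smaller
theta).

Two independent likelihood engines exist: the inheritance-vector
factorization above (default up to 12 meioses) and a two-locus
genotype-elimination (Elston–Stewart) peeling over ordered joint
genotypes, for larger pedigrees. They agree to 1e-10 relative tolerance
on all seven structures, and both match a brute-force
transmission-enumeration oracle on small test pedigrees.

**MOD.** `max` of the max-LOD over a trait-model grid, one shared model
for the whole sample. Default grid: penetrance triples from
{0, 0.003, 0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 1} with
`f0 <= f1 <= f2`, `f0 < f2` (flat models score identically zero),
crossed with `p in {0.01, 0.05, 0.1, 0.2, 0.25, 0.3, 0.4, 0.5}` — 1,248
models; 0.25 is included so the grid contains all three AMOI parameter
points, making `MOD >= LOD` an exact invariant. Optional local
refinement (coordinate search with step halving, terminating below 1e-3
score gain) adds at most ~0.05 over the grid in practice; studies use
the grid alone. Per-pedigree maximization is deliberately not offered.

## Thresholds and power

Significance levels are the genome-wide pointwise levels 0.0017
(suggestive), 0.0001 (LOD-3) and 0.000049 (significant). Asymptotic
critical values: upper-alpha normal quantile for NPL;
`z_alpha^2 / (2 ln 10)` for KC-LOD and LOD (inverting the half-chi2(1) +
half point mass law of `2 ln(10) LOD`). Empirical critical values use
the `floor(N alpha)`-th largest null score, so the threshold's own
empirical P-value is at most alpha. Power is `#{T >= Z}/N`, ties
counting as exceedances.

The MOD null distribution depends on pedigree structure, so its power
thresholds are structure-specific simulation-based constants from a
10^6-replicate reference study (ASP 3.61, DST 4.20, DSQ 4.36, mixture
4.01); empirical re-estimation is available at reduced precision. Our
own 5,000-replicate null runs of the grid-MOD land on the theoretical
chi-square-mixture quantiles for affected sib pairs
(`2 ln(10) MOD ~ 1/4 chi2(2) + 1/2 chi2(1) + 1/4 delta_0`, 0.0017
quantile ≈ 2.33) — noticeably below those published constants at the
suggestive level, which is why the constants are treated as documented
inputs rather than re-derived: the reference software's maximization
internals are not reproducible from its description, and an 11x denser
grid moves our quantile by < 0.06. Power computed *at* the published
constants reproduces the reference power values.

## Performance design

Studies evaluate millions of pedigrees of a few fixed structures. With
an equifrequent marker every statistic depends on the genotypes only
through the inheritance-vector posterior, which is invariant under
allele relabeling. Simulated genotype configurations are therefore
canonicalized (pairs sorted, alleles renumbered by first appearance,
two passes) and all per-class quantities — z score, log10-LR curves for
the three AMOIs and for all 1,248 grid models × 25 thetas — are cached
per canonical class. A replicate statistic is then a sparse
count-matrix product over class tables; an ASP has only a few hundred
classes, an ASQ a few thousand. Canonicalization is not a perfect
normal form; imperfection can only duplicate cache entries, never
change values (tested). Within-process engines are shared across runs.

Replicates are simulated in vectorized batches from one generator per
run, so a run is exactly reproducible from (configuration, seed);
per-replicate re-simulation in isolation is traded away for vectorized
throughput. Replicates are independent and order does not matter;
outputs are indexed by replicate.

Numerics: likelihood ratios are clamped at 1e-300 before logs
(Mendelian-impossible model/data pairs under theta = 0 yield large
negative, finite log-LRs); class tables are stored float32 (absolute
LOD error after summing 500 pedigrees < 1e-3, far inside all
tolerances); the theta coupling is applied as per-bit nonnegative 2x2
maps in the reference engines to avoid cancellation.

## Problem sizes used

Reported runs use 500–2,000 power replicates and 5,000 null replicates
of 500-pedigree samples (the original study used 5,000 and 100,000).
Binomial standard errors at these sizes are ~1–2 percentage points for
power; the 0.0017 null quantile from 5,000 replicates carries a
Monte-Carlo spread of roughly ±0.1–0.2.

## What the generator does and does not emulate

It reproduces the stated study conditions exactly: fixed structures and
affection patterns, one highly informative marker, complete linkage,
full genotyping. It does not model genotyping error, missing data,
marker maps or multipoint information, locus heterogeneity across
pedigrees, ascertainment beyond the fixed affection pattern, or
sex-specific recombination — so passing tests demonstrate statistical
properties of the methods under these idealized conditions, not
robustness to real-data artifacts.

## Known limitations

- Single marker, two-point analysis only; multipoint behaves
  differently for the parametric LOD and is out of scope.
- The batch engine requires an equifrequent marker (the per-pedigree
  API supports arbitrary allele frequencies).
- Exact conditional simulation enumerates `2^(2F) × 2^m` configurations
  and is intended for the small fixed structures (≤ ~12 members).
- Pedigrees with marriage loops, half-sibs or X-linkage are not
  supported; the peeling engine additionally assumes each individual
  parents at most one sibship and married-in spouses are founders.
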