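# Methods

`divaxes` implements an integrated divergence analysis between two
groups of populations — typically two subspecies along an environmental
gradient — on three axes: climatic niche, morphology and multilocus
sequence variation.  Every statistic is exercised end-to-end on bundled
synthetic generators, including a two-deme isolation-with-migration
(IM) coalescent simulator, so the whole pipeline is testable without
external data downloads.

## Niche divergence

Occurrence-site climate tables (site, group, variables) are reduced by a
**correlation-matrix PCA**: each variable is centred and scaled to unit
variance (ddof = 1) before the SVD.  The correlation matrix is used
because bioclim-style predictor sets mix units (°C, mm); a covariance
PCA would be dominated by precipitation magnitudes.  Eigenvector sign is
arbitrary, so each loading vector is flipped to make its
largest-magnitude element positive — a fixed convention that makes runs
reproducible (signed Di values from other software may differ by sign).

Divergence on axis *i* is the **Di statistic**, the difference of group
mean scores.  Its null distribution comes from reshuffling group labels
over the pooled sites without replacement (a permutation preserving
group sizes; 9999 reshuffles by default).  Two details are deliberately
configurable:

* **Tail policy.**  The literal one-sided count
  `#(Di_null ≥ Di_obs)/N` returns p ≈ 1 for any strongly negative
  observed Di even when divergence is extreme, so the default is
  two-sided on |Di|; the one-sided count is available via
  `tail="greater"`.
* **Denominator.**  The plain `count/N` ratio is the default (it can
  legitimately report p = 0); the `(count+1)/(N+1)` estimator is
  available via `plus_one=True`.  An `exact=True` mode enumerates all
  C(n, n₁) allocations for small samples.

A two-group MANOVA confirms the multivariate signal: Wilks'
Λ = det(E)/det(E+H) from within- and between-group cross-product
matrices with Rao's F approximation (exact for two groups).  A
statsmodels MANOVA serves as an independent cross-check in the tests.

## Morphology

Traits (mass g, wing mm, tarsus mm) are log10-transformed.  Structural
body size is the pooled-sample OLS residual of log wing on log tarsus.
Geography and sex effects are tested with a factorial ANOVA
(geography × sex); sums of squares are Type II by default (the common
choice when main effects are reported alongside a non-significant
interaction), with Type I/III behind a flag, and sites with fewer than
three individuals are dropped from site-structured analyses.

The climate–morphology relationship is assessed with four OLS models
per trait — linear and quadratic in each of the two leading climate
axes, with site-level scores broadcast to the site's individuals — and
ranked by AICc:

    AIC  = n·ln(RSS/n) + 2k
    AICc = AIC + 2k(k+1)/(n−k−1)

where k counts intercept, slopes and the residual variance (k = 3
linear, k = 4 quadratic).  Akaike weights are
exp(−Δᵢ/2)/Σⱼ exp(−Δⱼ/2).  RSS = 0 (a perfect fit) and n ≤ k+1 are
rejected rather than silently propagated.

## Sequence statistics

All statistics operate on **analyzed sites**: by default every
alignment column containing `-` or `N` is excluded (complete deletion,
the DnaSP-style convention), so L is the gap-free length.  Diploid
individuals contribute each phased allele as an independent sequence
(mtDNA 1 per individual, autosomes 2, Z-linked 2 for males / 1 for
females, males being the homogametic sex in birds).

* **S** — columns with ≥ 2 distinct bases.
* **Hd** — n(1 − Σpᵢ²)/(n−1) over distinct haplotypes.
* **π** — mean pairwise differences per site, computed per column from
  the allele-frequency spectrum (equal to the O(n²L) pairwise count,
  which the tests verify).
* **Watterson θ̂** — S/(a₁L) per site with
  SE = √(a₁θ̂ₗ + a₂θ̂ₗ²)/(a₁L), θ̂ₗ = S/a₁, from the neutral sampling
  variance Var(S) = a₁θ + a₂θ².
* **Tajima's D** — (πₗ − S/a₁)/√(e₁S + e₂S(S−1)) with the standard
  constants.  D is undefined (returned as `None`) when S = 0 and also
  at n = 3, where both variance constants collapse to zero.
* **Kst** — 1 − Ks/Kt with Ks the size-weighted (w_j = n_j/n; an
  (n_j−1)-based weighting is a flag) mean within-population pairwise
  difference and Kt the pooled mean; significance from permuting
  sequence→population labels with the (count+1)/(N+1) upper-tail
  estimate (999 permutations by default).
* **Fixed differences / Dxy** — sites whose between-population base
  sets are disjoint; raw Dxy as a percentage of analyzed sites (net
  divergence, Dxy − mean within-π, behind a flag).
* **AMOVA** — pairwise difference counts partitioned into among-group
  (σ²ₐ), among-population-within-group (σ²_b) and within-population
  (σ²_c) components via sums of squared deviations and expected mean
  squares with unequal-size coefficients.  F_CT = σ²ₐ/σ²_T,
  F_SC = σ²_b/(σ²_b+σ²_c), F_ST = (σ²ₐ+σ²_b)/σ²_T.  Negative
  components are reported unclamped with a warning so percentages stay
  interpretable.  Permutation schemes: whole populations among groups
  (F_CT), sequences among populations within groups (F_SC), sequences
  among all populations (F_ST).  Note that with very few populations
  the F_CT null has only a handful of distinct rearrangements, so its
  permutation p is coarse by construction; F_ST's p is the fine-grained
  one in small designs.
* **Amino-acid profiles** — sequences translated with the vertebrate
  mitochondrial code; codon positions with ≥ 2 amino acids present are
  listed, and positions whose amino-acid sets are disjoint between the
  two groups count as diagnostic.  Internal stop codons produce a
  warning with the codon position rather than an error, as mtDNA
  alignments commonly include incomplete-stop quirks.

## The IM simulator

The genealogy simulator follows the structured coalescent for two demes
exchanging migrants until the split time (backwards in time), one
ancestral deme thereafter.  Conventions (ms-style): time in units of
4N_ref generations; pair-coalescence rate 2/x in a deme of relative
size x; `mig_12` is the scaled backwards rate (4N·m) at which a lineage
in deme 1 traces into deme 2.  Mutations are Poisson with mean
θ × (total branch length in 4N units) — equivalently θ/2 per unit of
length on the 2N scale — giving the standard neutral expectation
E[S] = θ·a₁, which the calibration tests check to 5%.  The infinite
sites model maps each mutation to a distinct column; if the Poisson
draw exceeds the locus length the simulator raises an error (asking for
a longer locus or smaller θ) instead of silently recycling sites, so
S always equals the number of segregating mutations.

The **inheritance scalar** (1.0 autosomal, 0.75 Z-linked, 0.25 mtDNA)
multiplies the effective θ and both migration rates, shrinking the
marker's effective population size; split time stays in reference
units.  The relative ancestral deme size is exposed as a parameter
(default 1, i.e. equal to the daughter demes), since this quantity is
rarely identifiable and must be a modelling choice.

Multilocus datasets simulate each locus independently (free
recombination between loci, none within — the no-intralocus-
recombination assumption mirrors data screened clean of breakpoints)
under a shared demography, with per-locus seeds spawned
deterministically from the master seed so outputs are byte-identical
under a fixed seed.

## Synthetic data: what it does and does not emulate

* **Climate**: a latent-factor model — observed variables are linear
  combinations of a few latent axes plus independent noise, with group
  2's latent means offset by a shift vector.  This reproduces the
  strong collinearity of bioclim sets with a controllable, known truth
  (the default three factors with scales 3:2:1.2 put roughly half the
  standardized variance on the leading axis, comparable to real
  predictor sets).  It does not emulate spatial autocorrelation or
  non-Gaussian marginals of real climate layers, so passing tests show
  calibration under exchangeability, not robustness to spatial
  structure.
* **Morphology**: log-scale linear model with a sex effect, site
  structure via the climate axis, and an optional quadratic term;
  defaults are scrub-robin-sized (≈31 g, 84 mm wing, 28 mm tarsus,
  males a few percent larger, residual SD 0.008–0.015 log10 units).
  Site sex counts are drawn binomially but clamped so both sexes occur
  at every site, because the factorial interaction term requires
  non-empty cells.  Measurement error structure and allometric
  covariance beyond the single size index are not modelled.
* **Sequences**: neutral, non-recombining, infinite-sites loci.  No
  selection, no recombination, no sequencing/phasing error.

## Calibration experiments (scripts/acceptance.py)

The acceptance script recomputes, from scratch at the standard problem
sizes: the neutral mean S (2000 replicates, n=10, θ=5; expectation
θ·a₁ = 14.14) and mean Tajima's D (1000 replicates, n=20, θ=5;
expectation ≈ 0); the Di test's empirical type-I error at α = 0.05
(500 null datasets of 14+14 sites, 999 permutations); the Di p-value
and Wilks' Λ on a shifted 28+8-site dataset; the Akaike weight of the
quadratic model on quadratic-truth morphology (n = 80); and the
deep-split divergence recovery rate (100 replicates, θ=5, 10+10
sequences, no migration: Kst > 0.5 with permutation p ≤ 0.01 and
AMOVA F_CT > 0.5).  These sizes keep the full run around half a minute
on one core while leaving Monte-Carlo error well inside the tolerance
bands.

## Known limitations

* The Gillespie-style simulator is pure Python and is intended for
  desk-scale sample sizes (tens of sequences), not genome-scale work.
* AMOVA distances are plain difference counts; no substitution-model
  correction is applied.
* Tajima's D significance stars are not computed by default; the
  statistic is reported and its neutral calibration is demonstrated by
  simulation instead.
* The IM *inference* problem (estimating migration rates and split
  times from data) is out of scope; the model is generative only, and
  mutation-scaled times are converted to years by the documented
  `t/μ × generation-time` rule.
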