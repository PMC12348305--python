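# Methods

## Scope and model

`coexistkit` implements three statistically independent probes of niche
overlap for a small pool of plant species. Each probe is a standard
community-ecology procedure; the package's contribution is a tested,
reproducible implementation of all three plus the synthetic generators
needed to validate them jointly.

### 1. Checkerboard co-occurrence under fixed–fixed nulls

The unit of analysis is a binary site × species occupancy matrix (sites
in rows). For each species pair, checkerboard units are
`C_ij = (r_i − X_ij)(r_j − X_ij)` with `r` the species' total occurrence
counts and `X_ij` the number of shared sites (the Stone–Roberts
convention). An alternative reading — counting only occurrences
*without* the partner before the subtraction, which discounts
co-occurrence twice — is exposed as `exclusive_counts=True` but is not
the default: the standard convention is what reproduces the canonical
perfect-checkerboard value C = 1 for `[[1,0],[0,1]]` and what reference
implementations compute. The normalized score divides the summed units
by the number of species pairs and site pairs.

The null model holds both row and column sums fixed ("fixed–fixed"),
the most conservative standard randomization for co-occurrence tests.
Two samplers:

* **Trial swap** — a Markov chain whose step draws a random 2×2
  submatrix and flips it only if it is a checkerboard; because failed
  draws still advance the chain, its stationary distribution is uniform
  over admissible matrices. Burn-in and thinning control serial
  dependence.
* **Quasiswap** — one independent sample per draw: a random integer
  contingency table with the target margins (constructed by pairing a
  shuffled multiset of row labels with column labels, i.e. the two-way
  hypergeometric distribution), repaired to a 0/1 matrix by moves that
  never increase the sum of squared entries, then mixed with `thin`
  trial swaps. The mixing step is essential, not cosmetic: the bare
  fill-and-repair output is measurably non-uniform on enumerable state
  spaces (chi-square p ≈ 1e−19 over the 90 matrices of a 4×4 test
  margin set), and a few hundred trailing swaps restore uniformity
  (p ≈ 0.4–0.8). Infeasible margins are rejected up front via the
  Gale–Ryser condition.

The standardized effect size is `z = (Cn − μ)/σ` with μ, σ the null
sample mean and standard deviation (sample, n−1 denominator); the
primary p-value is the two-tailed normal tail mass, with an add-one
empirical rank p (mirrored about the null mean) reported alongside. A
null with σ = 0 raises an error rather than returning an infinite z —
with few species this happens legitimately, because fixed margins pin
the total co-occurrence `ΣX_ij = Σ_sites (richness choose 2)` and can
pin the C-score itself.

Defaults follow the standard field protocol: 1000 null matrices, 30,000
burn-in, 30,000 swaps per sample. Tests and the acceptance script use
far smaller values (100–200 nulls, 200–600 mixing swaps) scaled to the
small matrices they randomize; mixing adequacy at those sizes is
checked directly by the uniformity tests.

### 2. Diversity–productivity slopes

Productivity observations (leaf litter mass, wood BAI, root in-growth
mass) are modelled as

```
value ~ richness * density [* year]   + (1 | block) + (1 | unit-in-block)
```

with richness continuous, density (and year, for repeatedly measured
tissues) categorical under sum-to-zero contrasts. The mixed model is
fit by REML (statsmodels MixedLM); the unit variance component is
included only when units actually have repeated measures, since it is
otherwise unidentifiable. Type-III tests are joint Wald F statistics on
each term's coefficient block — equivalent to type-III sums of squares
under sum coding in balanced designs. Denominator degrees of freedom
use the residual-df approximation and the result carries
`df_method="residual"` to flag that Satterthwaite df were not computed;
in the balanced, well-replicated designs generated here the two differ
little. If the mixed fit fails to converge or is singular, the model is
automatically refit as OLS with block as a fixed (sum-coded) term and
flagged `model_kind="fixed-fallback"` — mirroring the common fate of
single-year root analyses.

Wood BAI is computed pith-outward: cumulative radius from annual ring
widths (initial radius 0 unless supplied, bark excluded), annulus area
per year. Per-stratum diversity slopes (one OLS slope per density ×
year cell) are reported with 95% CIs, and `slope_vs_zero` flags which
CIs contain zero. The response is fit on the raw scale by default with
a `log10_response` option, since the transformed axis in typical DP
figures is a display choice rather than a model statement.

### 3. Trait space

Trait records are averaged per (species, source) so that no single
prolific source dominates; own-plot measurements enter as simply one
more source label. Gaps are completed by iterative PCA: columns
standardized, missing cells initialized at the column mean, then
repeated rank-`ncomp` SVD reconstruction overwriting only the missing
cells. With `regularized=True` (default) singular values are shrunk by
the noise variance estimated from the discarded components, the usual
guard against overfitting the gaps. Iteration stops when the summed
squared change of imputed cells drops below `tol` (1e−6), the standard
stopping rule for this algorithm family; the cap is 10,000 iterations
because convergence is geometric but slow (contraction ratio near 0.99)
at 30–40% missingness. Three components are the default, matching the
dimensionality that six correlated traits support.

PCA is computed on standardized columns (correlation PCA) because the
six traits carry incommensurable units; zero-variance columns are
dropped with a warning; loadings are sign-fixed so each component's
largest-magnitude weight is positive. Species separation is tested two
ways: one-way ANOVA per retained PC axis, and PERMANOVA on Euclidean
distances in the standardized six-trait space with unrestricted label
permutations (999 by default) and the add-one p-value. On univariate
input the pseudo-F reduces exactly to the classical ANOVA F, which the
tests exploit as an oracle identity (and cross-check against
scikit-bio's implementation).

## Synthetic generators

All generators are bit-reproducible from (spec, seed) via numpy
`SeedSequence` streams.

* **Communities.** `random` is independent Bernoulli(fill) occupancy.
  `segregated` pairs species off; each pair shares a site pool (a site
  enters the pool with probability 2·fill) and occupies it exclusively
  — one species per site, coin-flipped — with probability `effect`,
  falling back to independent 50/50 draws otherwise, so each species'
  expected fill stays at `fill` for every effect level. This is the
  classic interdigitated-checkerboard structure. A partition of sites
  among species was considered and rejected: it moves all structure
  into the margins, which a fixed-fixed null conditions away, so it has
  essentially no power under the very test it is meant to exercise (and
  at full effect every site is monospecific, pinning the C-score and
  degenerating the null). `aggregated` gives all species a shared
  preference for the same random site subset, with occupancy
  probabilities arranged so expected fill is again preserved and
  `effect=1` collapses all species onto an identical site set (C = 0).
* **Productivity.** The full crossed design: 3 blocks × 3 densities ×
  all 7 nonempty mixtures of the 3-species pool = 63 plots, with a
  configurable number of measurement units per plot and years. The mean
  structure is `baseline + β·richness`, plus independent Gaussian block,
  unit, and residual effects (defaults 1, 1, 2 around a baseline of 10 —
  coefficients of variation in the 10–25% range typical of field
  productivity data). Values truncate at zero (they are masses/areas);
  at the default baseline the truncation probability is ~1e−5, so the
  induced bias is negligible, but it grows at tiny baselines.
* **Traits.** Per species × source × trait, Normal(global mean +
  species offset, within-SD) draws with independent missing-at-random
  masking; a row that would lose every cell keeps one randomly chosen
  observation so the table stays imputable. Defaults (8 sources per
  species, 20% missingness) mimic a modest multi-source trait
  compilation.

What the generators do *not* emulate: spatial autocorrelation among
sites, phylogenetic signal in traits, heteroscedastic or temporally
autocorrelated growth, and observation error in ring widths. Passing
tests therefore certify the statistical machinery — calibration, power
against the encoded structures, parameter recovery — not robustness to
those real-data features.

## Numerical and design choices

* Binarization of abundance tables uses strict `> threshold`
  (default 0).
* Quasiswap samples draw from independent `SeedSequence` substreams, so
  results are reproducible regardless of evaluation order.
* The pipeline derives one 31-bit stage seed per stream from a single
  global seed; per-stage JSON plus a combined verdict table are written,
  and the combination is deliberately descriptive — the three streams
  are juxtaposed, never pooled into a single meta-statistic, because
  they answer different questions at different scales.
* Degenerate inputs fail loudly: infeasible margins, σ = 0 nulls,
  single-richness designs, all-identical trait points, groups of size
  one in ANOVA.

## Problem sizes used in validation

The calibration suites run at deliberately modest sizes chosen to make
the relevant distributions well-resolved: type-I error of the C-score
test over 200 random 30 × 3 communities with 200 nulls each; sampler
uniformity against the exhaustively enumerated 90-state space of a 4×4
margin set with 5000 samples; power against segregation at 100 sites ×
6 species; DP slope recovery over 200 simulated 63-plot experiments per
effect size; PERMANOVA null uniformity over 200 relabelings of 12-row
tables.

## Known limitations

* Satterthwaite denominator df are approximated by residual df (flagged
  in every result); exact fractional df require a solver that exposes
  the REML Hessian with respect to variance components.
* The C-score with only three species has limited resolution: the
  fixed-fixed constraint fixes total co-occurrence, so only its
  distribution across the three pairs can vary, and some margin
  configurations admit a single score (handled as degenerate nulls).
* Quasiswap mixing length is a tunable (`thin`); uniformity has been
  verified on enumerable state spaces, but very large sparse matrices
  may need longer mixing than the default heuristics used in tests.
* The imputation assumes missingness at random; systematically missing
  traits (e.g., seed mass never measured for one species) violate this
  and will bias completion toward the remaining species' structure.
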