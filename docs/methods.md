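# Methods

This note documents the statistical model behind `triepistasis`, the
choices made where the underlying methodology is genuinely open, the
numerical conventions, and what the simulation-based tests do and do not
demonstrate.

## Genetic setting and model

The package targets biparental fully homozygous populations — doubled
haploid (DH) or recombinant inbred lines — where every marker locus
carries one of the two parental alleles and is coded −1 or +1. Under
balanced segregation each coding occurs with probability ½, and loci on
the same chromosome are correlated through linkage: with the Haldane map
function (no crossover interference) the recombination fraction at
distance *d* cM is r(d) = (1 − e^(−2d/100))/2 and the correlation between
two ±1-coded loci at that distance is 1 − 2r.

The trait model is a linear regression on p selected markers and their
products,

y = 1μ + Xβ + Zγ + Wδ + e,

with X the n×p matrix of selected marker columns, Z all pairwise products
among the product-eligible markers (additive×additive effects γ), W the
three-way products (additive×additive×additive effects δ), and e i.i.d.
mean-zero noise. Because the markers are ±1, product columns are again ±1
and, on a balanced orthogonal design, all terms are mutually orthogonal —
the property the exact-recovery tests exploit.

Two estimators of the *total* three-way effect are provided:

* **Phenotypic**: aaa_p = ½(L̄_max + L̄_min) − L̄, from the means of the
  extreme-line groups and of all lines. It needs no marker data.
* **Genotypic**: aaa_g = Σ δ̂ over the triple terms retained in the fitted
  model (each unique triple counted once).

### A structural caveat on the phenotypic form

Under the ±1 product model, the symmetric combination
½(L̄_max + L̄_min) − L̄ cancels odd-order contributions of loci fixed at
opposite values in the two extreme groups — for a trait that is exactly a
pure triple product on a balanced design it returns 0, not δ. The formula
is nevertheless implemented exactly as classically stated; the
balanced-design contrast (below) makes the cancellation visible, and the
worked example in the README shows its practical consequence. The package
deliberately does not "correct" the estimator.

## Preprocessing

* **Angular transform.** Percentage traits may be transformed by
  arcsin √(x/100) (radians, [0, π/2]), selected per trait.
* **Normality screen.** Shapiro–Wilk, advisory only: the result is
  reported and never blocks the pipeline, since the downstream OLS is the
  analysis of record either way.
* **Missing-genotype imputation.** Each missing entry is replaced by its
  conditional expectation given the nearest observed flanking markers on
  the same chromosome under the two-state Markov chain: with flanks a, b
  at correlations t_L, t_R (t = 1 − 2r), E[x|a,b] =
  (a·t_L + b·t_R)/(1 + a·b·t_L·t_R); with a single flank, a·t_L; with no
  observed marker on the chromosome, 0 (the balanced-segregation prior).
  Imputed values are kept continuous by default because expectations
  preserve information in the regression; a switch rounds them to hard ±1
  calls for users who need strict two-level coding. The imputation is
  idempotent and never alters observed calls.
* **Segregation pre-test.** Per marker, χ² = (n₊ − n₋)²/(n₊ + n₋) with
  1 df against the 1:1 expectation, computed on hard calls only. The test
  is reported; exclusion of distorted markers is off by default
  (α = 0.05 when enabled), since reporting-only is the conservative
  default when the handling of distorted markers is not prescribed.

## Marker selection and inference

Selection minimises AIC = n·log(RSS/n) + 2(k+1), where k counts the
regression coefficients and the +1 the error variance; the additive
constant n·log(2π) + n is dropped, which cancels in every within-dataset
comparison the package makes. All three stages run the same bidirectional
stepwise search from the intercept-only model: at each iteration every
single-term addition and deletion is scored and the best strictly
AIC-improving move is applied (additions are scored in one vectorised
projection pass through the current orthonormal basis; the engine
reproduces R's `step()` selections on shared fixtures).

1. **Stage 1 — per chromosome**, additive terms of that chromosome's
   markers. Zero-variance markers are excluded from candidacy.
2. **Stage 2 — pooled survivors**, additive terms only; the outcome is
   the p "included markers" of the model.
3. **Additive-significance screen.** Product terms are restricted to loci
   with significant additive effects — the assumption that keeps the
   interaction pool far below C(p,3). Significance is a t-test in the
   joint stage-2 additive model at the Bonferroni-corrected level α/p.
   The correction matters: an uncorrected screen admits ≈ p·α false
   additive loci per trait, each spawning spurious product candidates.
   Setting `additive_alpha=None` disables the screen (products then form
   among all selected markers).
4. **Stage 3 — final selection** over the additive terms of the selected
   markers together with all eligible pairwise and triple products.
   Additive terms are candidates like any other: freezing them would let
   markers that entered stage 2 partly on a chance correlation with an
   epistatic signal drain the interaction coefficients, a conditional
   bias measurable by paired comparison with an oracle fit on simulated
   data (≈ −0.03 on a triple effect of 0.8 under the test conditions;
   roughly halved by the uniform search). The total number of fitted
   parameters is capped at `max_params` (default n − 10) to preserve
   residual degrees of freedom.

**Fitting.** OLS through a rank-revealing decomposition: aliased columns
are dropped deterministically (first kept in canonical map order) and
recorded; per-term t statistics and two-sided p-values use the residual
degrees of freedom; saturated fits keep exact estimates with undefined
(nan) inference.

**Multiple testing.** Each retained triple is tested at level α/m. By
default m is the number of interaction candidates scored in stage 3, not
the handful that reached the final model: the fitted t statistics are
maxima over the whole scored pool, so correcting only over the final
model's terms would leave a family-wise null error rate of 30–40% in
simulation, versus ≈ 3–5% with the candidate-pool correction
(`bonferroni_scope="model"` switches to the final-model denominator).
aaa_g itself always sums *all* retained triples; the NS flag (no
significant triple) controls reporting, not computation, so the numeric
total remains available for diagnostics.

**Selection bias, known limitation.** Even with the uniform stage-3
search, markers admitted to the stage-2 pool partly on chance correlation
with an epistatic signal leave a residual conditional bias of order
−0.01 to −0.02 on a triple coefficient of 0.8 (n = 150) — an inherent
selective-inference property of single-sample stepwise pipelines. Users
needing unbiased effect sizes should re-fit the selected model on
independent data.

## Balanced-design contrast

For unlinked markers with exact 1:1 segregation the genotypic total can
be written per triple as ½(ȳ⁺ + ȳ⁻) − ȳ, with ȳ⁺/ȳ⁻ the means over lines
whose three markers are all +1/all −1. This symmetric form is implemented
as stated; note that for a pure odd-order (triple) effect on a balanced
design it vanishes identically while the half-difference ½(ȳ⁺ − ȳ⁻)
returns δ — both are reported, the difference form as a diagnostic. The
χ² segregation test is the pre-test of the balanced-segregation
assumption behind this rewriting.

## Phenotypic estimator details

* **Extreme-group size** is nowhere standardised; the default takes
  ⌈0.05·n⌉ lines per tail (at least one), exposed as
  `--extreme-fraction`. Small groups best approximate the ideal of lines
  carrying only decreasing/only increasing alleles. Boundary ties are
  broken by line id, making the selection order-independent.
* **Effective-factor count** uses a Wright-type stand-in,
  K = round((L̄_max − L̄_min)²/(8·s²_y)), clamped at 0 — the classical
  formula family for "number of segregating genes"; the estimator is
  pluggable so another variant can be substituted. It is scale-invariant
  and labelled as a stand-in in the output.

## Simulator

`simulate` generates DH genotypes chromosome by chromosome as the same
two-state Markov chain assumed by the imputation (first locus ±1 with
probability ½, each next locus flipping with r(Δ cM), chromosomes
independent), then the trait y = μ + Σβx + Σγxx′ + Σδxx′x″ + e with
Gaussian noise, then masks genotypes missing completely at random —
masking after trait generation so the injected architecture stays well
defined. Two presets mirror familiar barley DH panel shapes: 150 lines /
223 markers / 5.66 cM mean spacing, and 145 lines / 127 markers /
10.62 cM. `make_full_factorial(k)` gives the 2^k orthogonal design used
as the exact-fit oracle fixture.

What the simulator does **not** emulate: segregation distortion,
crossover interference, genotyping error, multi-environment correlation
structure, non-Gaussian residuals, and missingness that depends on
genotype. Passing tests therefore demonstrate correctness of the
estimators under the stated genetic model, not robustness to those
real-data complications.

## Test conditions and problem sizes

The Monte-Carlo validation uses populations of 150 lines with 3
chromosomes × 20 markers at 10 cM spacing, three additive anchors of 1.0
mid-chromosome, residual SD 1.0, and — for the recovery study — one triple
effect of 0.8 on the anchors: an architecture where the additive signal is
unambiguous (|t| ≈ 12) so the behaviour of the *interaction* machinery is
what is measured. Recovery uses 200 replicates (retention rate and
conditional mean of the true triple's coefficient), the null study 500
replicates (family-wise rate of any significant triple at α = 0.05). The
acceptance script runs the same studies at 100/200 replicates as a faster
demonstration.

## Numerical conventions

* Rank tolerance: a candidate column is aliased when its residual norm
  after projection on the kept columns falls below 10⁻⁹ of its norm;
  RSS is floored at 10⁻³⁰⁰ inside the AIC logarithm so exact fits remain
  comparable.
* Stepwise ties: moves must improve AIC by more than 10⁻¹⁰; among
  improving moves the largest improvement wins, so aliased duplicates
  never enter and term order never affects the selected set.
* Ratios: (aaa_g/aaa_p)·100 is undefined — not 0, not ∞ — when aaa_p = 0
  or the genotypic result is NS, and undefined ratios are excluded from
  the summary quartiles.
* Determinism: every stochastic step draws from one generator seeded in
  the run configuration; identical configuration and seed reproduce all
  tables byte for byte.
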