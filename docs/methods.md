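# Methods

## Model

Two traits Y and Y′ are measured in distinct cohorts, each genotyped over
the same genomic region.  For a common set of q regressors (SNP dosages or
principal-component scores), per-cohort regression — linear for a
quantitative trait, logistic for case-control — yields coefficient
estimates b₁, b₂ with covariance matrices V₁, V₂.  At GWAS sample sizes the
joint sampling distribution of (b₁, b₂) is treated as Gaussian with V₁, V₂
known and Cov(b₁, b₂) = 0; the zero cross-covariance is an *assumption*
that holds only for disjoint samples, which is why the CLI refuses cohorts
sharing sample identifiers and a `split_controls` utility is provided for
studies with a common control pool.

A shared causal variant (or any shared set of causal variants with
proportional effects) implies β₁ = β₂/η for some scalar η, assuming the two
cohorts have the same LD structure.  The test statistic is Fieller's

    T(η)² = uᵀ V⁻¹ u,  u = b₁ − b₂/η,  V = V₁ + V₂/η².

Everything is computed in the angle θ = tan⁻¹(η):

    u(θ) = b₁ sinθ − b₂ cosθ,  V(θ) = V₁ sin²θ + V₂ cos²θ,

which is algebraically identical (multiply u by sinθ) and finite at η = 0
and ±∞.  T(θ)² is π-periodic.

**Profile test.**  T(θ)² is evaluated on the θ grid, the minimum refined by
bounded scalar minimisation (tolerance 1e-10 in θ), and T(θ̂)² referred to
χ²(q−1).  For q = 1 the profiled statistic is identically zero; the test is
undefined and p = 1 is returned with a warning.

**Posterior predictive p-value.**  Writing the null as β₁ = β cosθ,
β₂ = β sinθ, the Gaussian likelihood of the stacked (b₁; b₂) is
marginalised over β ∈ ℝ^q under a flat improper prior, giving (up to a
θ-free constant)

    log m(θ) = −½ log det A(θ) + ½ m(θ)ᵀ A(θ)⁻¹ m(θ),
    A = cos²θ·V₁⁻¹ + sin²θ·V₂⁻¹,
    m = cosθ·V₁⁻¹ b₁ + sinθ·V₂⁻¹ b₂.

A useful identity (verified numerically in the tests to 1e-14): the
marginal exponent equals −T(θ)²/2 exactly, so the posterior is
∝ |A(θ)|^{−1/2} e^{−T(θ)²/2} × prior(θ).  The prior on θ is induced by a
Cauchy(0, k) prior on η: p(θ) ∝ k/(k² cos²θ + sin²θ), uniform at the
default k = 1 (varying k has little effect at realistic sample sizes; it is
exposed as `prior_scale`).  The ppp is the posterior expectation of the
χ²(q) tail probability of T(θ)².

Because the statistic and the posterior concentrate at the same rate, the
ppp does **not** converge to 1 for exactly proportional data as V → 0; it
converges to the posterior mean of the tail probability (≈ 0.707 at q = 2).
ppp values are conservative relative to uniform and are interpreted as
evidence *against* colocalisation only when small.

**Credible interval for η.**  θ is periodic, so the grid is recentred on
the posterior mode before computing the cumulative distribution; central
quantiles are mapped through tan.  Flags report whether η = 0 (no effect on
trait 1 given an effect on trait 2) and η = 1 (equal effects) fall inside
the interval, checked on the θ circle so intervals wrapping through ±∞ are
handled.

### Numerical choices

- θ grid: `n_grid` (default 1001) equally spaced points on the closed
  interval [−π/2, π/2].  The endpoints describe the same model, so
  trapezoid quadrature over the closed grid is the periodic quadrature
  rule; normalisation, the ppp integral and the swap symmetry
  (exchanging cohorts reflects the posterior about θ = π/4) are then exact
  up to floating point.  Extremely informative data (posterior width below
  one grid step) need a larger `n_grid`.
- Singular V(θ) (collinear regressors) raises a numerical error with a
  condition-number report rather than silently regularising.
- p-values are upper-tail χ² probabilities, no continuity corrections.

## SNP summarisation

**Principal components.**  The two imputed cohorts are merged over common
SNPs (exact ref/alt swaps recoded as 2−dosage; other allele mismatches are
errors; strand-ambiguous A/T and C/G SNPs are flagged but kept).  The
combined matrix is centred and scaled per SNP, decomposed by SVD with a
deterministic sign convention, and the smallest leading component set whose
cumulative variance fraction reaches the threshold is retained.  Both
cohorts are projected with the *combined* means/scales so they land in the
same space.  Selection depends only on genotypes — never on the traits — so
coefficients at the selected components are unbiased.  The default
threshold is 0.90; the calibration studies in this repository use 0.85.
Cohorts enter the combined PCA with equal per-sample weight.

**Bayesian model averaging.**  All C(p, 2) (or C(p, 3)) SNP subsets are
fitted to both traits; each model's weight is
exp(−(BIC₁+BIC₂)/2), normalised — the product form is justified by cohort
independence.  The same SNP subset is used for both traits, as the
proportional test requires a common regressor set.  Models are ranked and
the minimal prefix holding `prune_mass` (default 0.9999) of the posterior
is retained before the per-model ppp values are computed; pruning at this
level changes the ppp by < 1e-3 in the internal consistency test.  The
reported ppp is Σ P*(m)P(m); the reported θ posterior is the
weight-mixture of per-model posteriors, from which the mixture-mode η̂ and
the credible interval are derived (an aggregation choice; weighted-moment
aggregation would be an alternative).  Model sizes are never mixed, since
there is no natural prior weight between a two- and a three-SNP model, and
four-SNP universes are deliberately unsupported.  BIC counts the intercept
(q+1 parameters); constant offsets cancel across equal-sized models.

## Regression layer

Quantitative fits are closed-form least squares (V uses the unbiased
residual variance); logistic fits use IRLS to tolerance 1e-8, max 50
iterations, with non-convergence flagged.  Scans report Wald p-values;
monomorphic SNPs get p = 1 with a warning and separated logistic fits fall
back to a score test.  Rank-deficient joint designs drop aliased columns
(first occurrence kept) with a warning.  Missing genotypes are imputed by
least-squares regression of each incomplete SNP on its `max_predictors`
(default 5) most-correlated complete SNPs, ties broken by SNP order,
fitted values clipped to [0, 2] and kept fractional.

## Biased baselines

Shipped for benchmarking only: conditional testing of the top SNP given the
other cohort's top SNP; the residual-rank (Spearman) score, whose value in
(0, 1] ranks how well the conditioning SNP removes the association
(exact-permutation p-values below n = 50, t approximation otherwise, the
test SNP excluded from and the conditioning SNP included in the rank set);
and the naive proportional selections — top pair, per-cohort lasso union,
and two-stage lasso in which cohort-1 selections enter cohort 2
unpenalised via residualisation.  Lasso penalties are chosen by 10-fold
cross-validation with the 1-SE rule at a fixed seed, on the squared-error
path for binary traits as well (selection only; the proportional test
itself always refits by the proper likelihood).

## Simulation engine

The panel generator stands in for a phased reference panel: within blocks
of `block_size` SNPs (default 25) a latent Gaussian AR(1) with parameter
`rho` (default 0.9) is thresholded at per-SNP quantiles with target allele
frequencies Uniform(`maf_floor`, 0.5), `maf_floor` defaulting to 0.05;
SNPs drifting below the floor are redrawn.  This reproduces block-wise r²
decay but not fine-scale recombination, allele-frequency spectra, or
haplotype-age structure of real data; the attainable r² between two SNPs is
also bounded by their frequency difference, so studies needing near-perfect
LD pairs use a tighter panel (rho 0.995).  Passing calibration tests on
these panels demonstrates correct behaviour under block-structured LD, not
under every real LD configuration.

Case-control cohorts: controls are random haplotype pairs; cases are
rejection-sampled with acceptance ∝ rr^(risk-allele count) — the
multiplicative model, matching the closed-form case allele frequency
f·rr/(1−f+f·rr) (checked in tests).  Quantitative traits give each causal
variant a fixed variance fraction v via β = √(v/(2f(1−f))) plus Gaussian
noise topping the variance up to 1.  Tag thinning keeps a random
ceil(fraction·p) SNP subset (default fraction 0.3), and the causal variant
is droppable like any other.  Replicates are screened per cohort to a
minimum single-SNP p ≤ 1e-4 — the test is intended for regions with
established association — and redrawn otherwise, with redraw counts logged.
Admixture draws each second-cohort haplotype from an alternate
(frequency-shifted) panel with probability π, for sensitivity analyses of
the equal-LD assumption.  All randomness descends from one seed; reruns are
bitwise identical.

### Study sizes used here

The packaged calibration runs use: 500 replicate pairs (acceptance script)
or 150 (test suite) for type-1 error at RR 1.2 with 2,000 cases/2,000
controls and 100-SNP panels; 60 replicates per r² bin for the
power-vs-LD study (quantitative, n = 1,000, 3% variance per variant); 60
replicates for the two- vs three-SNP BMA comparison (one shared plus one
private variant per trait, 5% variance each, 12 tag SNPs); and 100
replicates for credible-interval coverage at η₀ = 1 (n = 4,000, 10%
variance).  These sizes give binomial standard errors of 1–6 percentage
points, adequate for the directional and bounded claims being checked.

## Known limitations

- The β-marginalisation uses a flat improper prior; a proper Gaussian
  prior would shrink extreme effects and slightly alter the ppp in small
  samples.
- No covariate adjustment, mixed models, or meta-analysis in the
  regression layer.
- The merge step auto-fixes only exact ref/alt swaps; strand-ambiguous
  SNPs are the user's responsibility.
- ppp calibration to uniformity (e.g. by simulation) is not implemented;
  ppp values are used directly at the nominal level, which is
  conservative.
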