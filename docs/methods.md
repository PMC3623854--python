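# Methods

## Model and procedure

The unit of analysis is the small area. Each area *i* has a nonnegative
deprivation score IMD_i, counts of residents reporting "not good" general
health and Limiting Long-Term Illness (LLTI), and a denominator population
(adults 15–65). The pipeline estimates how morbidity relates to (a) an
area's deprivation and (b) its deprivation relative to its immediate
surroundings.

**Contiguity and lag.** Queen contiguity defines the neighbour sets: two
areas are neighbours iff their boundaries share at least one point. The
adjacent locality deprivation is the weighted neighbour mean
ALD_i = Σ_j w_ij IMD_j. Weights default to row-standardised binary queen
weights (the plain neighbour mean); the weighting convention behind
published national analyses is not uniquely pinned down, so a per-edge
custom-weight hook accepts population- or boundary-length-weighted schemes.
Areas with no neighbours (islands) have no ALD; they are dropped from all
downstream stages with a warning and a count in the run report. Imputing a
value instead would fabricate exactly the quantity (the differential) the
method is built to measure.

**Orthogonalization.** (IMD, ALD) are mean-centred and eigendecomposed via
their 2×2 sample covariance matrix. PC1 ("target area deprivation") is the
larger-eigenvalue component; PC2 ("deprivation differential") the smaller.
Scores are raw projections of the centred data; eigenvalues are reported as
variances explained. Sign convention: PC1 loadings nonnegative; PC2 loads
positively on IMD and negatively on ALD, so a positive differential always
means "more deprived than the neighbours". Exactly tied eigenvalues (a
measure-zero case reachable in constructed data) assign PC1 to the vector
with the larger IMD loading.

Covariance — not correlation — PCA is the default. With two variables,
correlation-matrix PCA always returns ±1/√2 loadings; the asymmetric
loadings reported for real national data (≈0.76/0.64) can only arise from
unstandardised inputs with unequal variances. A `correlation` mode is kept
for sensitivity analysis. No attempt is made to force synthetic-data
loadings to any particular published pair: the loadings are data-dependent.

**Outcomes.** Each outcome is expressed as a percentage of the denominator
and log-transformed (base 10), correcting the right skew of area morbidity
proportions. Percentage (not proportion) is the canonical pre-log scale —
the choice shifts log values by exactly 2 and cancels out of standardized
slopes, but fixes descriptive means. Zero numerators make the transform
undefined: the default policy is a hard error naming the areas, with an
opt-in +0.5 continuity correction. Outcomes are not age-standardised.

**Inference.** Outcome and predictors are z-scored with sample (n−1) SDs and
fitted by OLS (statsmodels), giving standardized slopes: a single-predictor
slope equals the Pearson correlation, and with orthogonal predictors the
multivariate slopes equal the bivariate ones and unadjusted R² is exactly
additive (adjusted R² additive up to O(1/n)). p-values are two-sided t-tests
with n−p−1 df, starred at 0.05/0.01/0.001. No spatial-error or
heteroskedasticity correction is applied — inference mirrors the plain OLS
design it reproduces, and residual spatial autocorrelation therefore makes
the stars optimistic (a known property of the design, not of this
implementation).

**Segmentation.** The additive model is re-estimated within IMD tertiles
(rank-based thirds, sizes differing by at most one, ties broken by area id)
or within categorical segments supplied with the data. Outcome and
predictors are re-z-scored *within each segment* so the per-segment slopes
are comparable standardized effects; the components themselves are computed
once globally and subset (a within-segment re-decomposition would change
the meaning of the differential). Each segment row reports β₁, β₂ and
β₁/β₂, ordered by descending ratio; |β₂| ≤ 1e−9 makes the ratio undefined
and is flagged rather than divided through. Segments smaller than a
configurable minimum (default 30, floored at the p+2 = 4 areas a 2-predictor
fit needs) are dropped with a warning.

## Synthetic regions

The generator emulates the study design on a rows×cols queen lattice:

- **Deprivation field**: iid N(0,1) innovations, then `smoothing_rounds`
  passes of d ← (1−ρ)d + ρ·(neighbour mean), then a shift to nonnegative.
  The moving-average smoother is the simplest mechanism producing the
  IMD↔ALD collinearity the orthogonalization exists to solve; a CAR/SAR
  field could be swapped in at one line.
- **Counts**: latent y_i = μ + b₁z(PC1) + b₂z(PC2) + σε on the
  log₁₀-percentage scale, with PC1/PC2 computed by the *pipeline's own*
  lag and decomposition stages; p_i = 10^y/100 clipped to
  [1/(den+2), 1−1/(den+2)]; counts ~ Binomial(denominator, p). For
  orthogonal z-scored predictors the population standardized slope is
  b/√(b₁²+b₂²+σ²) — the closed-form recovery target.
- **Segments**: deprivation-quantile bins with a seeded 10% of areas moved
  to an adjacent bin, mimicking geodemographic classes that correlate with
  (but are not functions of) deprivation.

Defaults are the reference study conditions used throughout the tests:
50×50 grid, ρ = 0.8 with 5 rounds, b₁ = 0.6, b₂ = 0.3, σ = 0.74, μ = 0.95
(≈9% baseline morbidity), denominators uniform on 900–2,100 (areas of
~1,500 residents), 13 segments. With these effects the model explains
≈45% of latent outcome variance, comparable to published national analyses
of self-reported morbidity; grids of 2,500 areas keep every test and the
acceptance run in seconds while leaving slope standard errors ≈0.02.

What the generator does *not* emulate: real IMD score distributions (it is
a shifted Gaussian field, not a composite index of seven domains), real
LSOA geography (a rectangular lattice has no coastline, no islands, nearly
constant degree), age structure, or migration between census and
deprivation reference dates. Passing recovery tests therefore demonstrate
that the pipeline's estimators are correct under the assumed generative
model, not that the substantive national findings are right.

Two numerical consequences of the heavy-noise conditions are worth noting.
First, with total latent SD ≈ 1 on the log₁₀ scale, the upper clip (p = 1)
binds for a visible share of areas and the lower clip leaves expected
counts near one, so a small number of binomial zeros is a legitimate
feature of simulated data; `run_simulation` therefore defaults to the
continuity correction (the strict error policy remains the default for
real data). Second, clipping attenuates fitted slopes by roughly 0.01–0.04
relative to the closed-form targets — within the ±0.05 recovery tolerance,
which is set by binomial and finite-sample noise at n = 2,500.

## Numerical choices

- All joins are by opaque area identifier, never row order; identical
  inputs give byte-identical CSV outputs.
- z-scores use n−1 SDs (immaterial to slopes; fixed for reproducible
  intermediates). Designs with condition number > 1e8 after z-scoring are
  rejected as collinear.
- Decomposition requires ≥3 areas and non-constant inputs; eigenvector
  signs follow the conventions above, so negating both inputs leaves the
  reported components unchanged.
- Ratios are printed to 3 decimals in text tables and written at full
  precision in CSV.
- Polygon contact tolerance defaults to 0 (exact shared-point test) with a
  `dwithin` option for dirty geometries. Polygon input is GeoJSON; edge
  lists are accepted as authoritative adjacency without geometric checks.

## Known limitations

- Ecological design: area-level associations, no individual inference.
- OLS stars ignore residual spatial autocorrelation (see above).
- One deprivation measure pair only (IMD, ALD); no robust/sparse variants.
- The categorical segmentation is consumed as labels; no classifier is
  implemented.
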