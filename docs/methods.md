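# Methods

This note documents the statistical machinery behind `macrogd`: the models,
the defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions that matter.

## Response harmonization

Published expected-heterozygosity estimates are only comparable within a
marker technology: dominant markers (AFLP) bound H_E at 0.5, codominant
markers (microsatellites, SNPs) at 1, and allozymes occupy a lower range
again. The harmonized response is built in two stages: (1) a z-score within
each marker type using the sample (n−1) variance, (2) a single min–max
rescale of the pooled standardized values to [0, 1]. Both stages are
increasing affine maps within a marker type, so rank order within a marker
type is preserved; the pooled extremes are exactly 0 and 1.

The min–max pool is the *whole* dataset by default (both kingdoms), so
cross-kingdom contrasts are expressed on one scale; a per-kingdom option
exists but is off by default. Whether the rescale should be pooled or
per-group is a genuine modelling choice; pooling is the least surprising one
for a response that is subsequently compared across kingdoms, and it is
flagged as an assumption here.

Inclusion rules applied before harmonization: at least 10 sampled
individuals (inclusive), non-marine habitat, no introduced/invasive/cultivar
provenance, non-missing coordinates. Each excluded row gets exactly one
reason code (the first matching rule, in the order missing-coordinates,
sample-size, marine, provenance). Rows missing elevation or climate values
are kept for the latitude models and listwise-deleted from the kingdom
models, with the deletion logged.

The precision weight is `1/sqrt(log(n_loci × sample_size))` with the
*natural* logarithm (configurable base); it is strictly decreasing in the
product and undefined at product ≤ 1 (a domain error). Weights enter the
model as residual precision multipliers: Var(ε_i) = σ²/w_i.

## Covariates

**Life-history PCs (animals).** Fecundity, body size and longevity are
log10-transformed, standardized, and decomposed by PCA (eigendecomposition of
the correlation matrix). Components are sign-fixed: each component's
largest-magnitude loading is made positive, then the first is flipped if
needed so size and longevity load positively (`pc_size_longevity`, a slow
life-history axis) and the second so fecundity loads positively
(`pc_fecundity`). Scores are zero-mean by construction.

**Climate axes.** Site-level current-climate variables (≥4) are standardized
and decomposed the same way; the three leading components are labelled
temperature / precipitation / humidity by the variable family of their
dominant loadings (families inferred from column-name substrings or supplied
explicitly). Rank-deficient input raises an error listing collinear columns.

**Temperature stability.** For each past epoch (Mid-Holocene, ~6 ka; Last
Glacial Maximum, ~22 ka) the raw score is −|T_current − T_past|, so a site
whose temperature did not change is maximally stable, then z-standardized
(sample SD) across the dataset. The sign convention makes "more stable"
equal "larger value", matching the direction in which stability effects are
interpreted; it is configurable because "standardized difference" admits
other conventions. The score is invariant to a common additive shift of both
epochs.

**Position classes.** A population's position inside its species range is,
in order of precedence: `endemic` if the range is smaller than 10,000 km²;
`isle`/`island` if the population sits on an insular landmass below/above
10,000 km²; otherwise a mainland area band — `core` inside the inner region
holding 50% of the range area, `subedge` in the 50–75% band, `edge` in the
outer 25%. Bands are realized by inward-buffer erosion of the range polygon
with a binary search on the buffer distance until the eroded area is within
0.5% of target; multipolygons are eroded as a union. Bands are defined by
*area share*, not distance-to-boundary quantiles, reading "outer 25% of the
distribution area" literally; for a circular range this puts the core
boundary at R/√2, which the tests verify analytically. Geometry is computed
in a Lambert azimuthal equal-area projection (spherical, R = 6371 km)
centred on the range centroid — equal-area by construction, so area shares
are exact; the on-boundary tolerance is 1 km. Populations may instead carry
a precomputed position label (pass-through mode) for compilations whose
range maps are not available.

## The mixed model

The observation model is y = Xβ + Σ_f Z_f u_f + ε with independent random
intercepts u_f ~ N(0, τ²_f I) for species and marker type (crossed, not
nested; the phylum-level latitude model adds kingdom), and ε_i ~ N(0, σ²/w_i).
Fixed-effect designs are built from explicit term sets (treatment coding,
first sorted level as reference; interactions as products of parent
encodings), keeping a term → column map so that model selection can move
whole terms — all levels of a categorical together — and group-slope
contrasts can find their interaction columns.

Estimation profiles β and σ² out of the (restricted) likelihood and
optimizes the variance ratios θ_f = τ²_f/σ² by L-BFGS-B with a zero lower
bound. Because every random term is an intercept, the marginal covariance is
diagonal-plus-low-rank and the Woodbury identity reduces each likelihood
evaluation to a dense q×q solve (q = total random levels), i.e. O(nq + q³)
instead of O(n³). The fitter reproduces `lme4` log-likelihoods and
coefficients to ~1e−6 on test fixtures (ML and REML).

Conventions and edge cases:

- **ML vs REML.** ML for every model-selection fit (AICc comparable across
  fixed structures), REML for reported final estimates. Which one the
  original analyses used is rarely stated in this literature; both are
  available and recorded per fit.
- **k for AICc** counts fixed coefficients plus variance components (one per
  random factor plus the residual).
- **Marker as a random factor.** Three levels is few for a variance
  estimate; when the marker variance lands on the zero boundary the helper
  `fit_with_marker_fallback` refits with marker as a fixed main effect.
  Boundary estimates (θ ≤ 1e−6) are flagged on the result.
- **R².** R²m = var(Xβ̂)/(var(Xβ̂)+Στ²+σ²); R²c adds Στ² to the numerator.
  For weighted fits σ² is the residual variance *at unit weight* — the
  natural scale of the parameter, documented as an assumption. var(Xβ̂) uses
  the sample (n−1) denominator.
- **Group slopes.** From a `continuous × group` model, the reference group's
  slope is the base coefficient; other groups add their interaction
  coefficient, with SE from the contrast c'Σc using the full coefficient
  covariance, and normal 95% CIs.

## Model selection

All marginality-respecting subsets of the full model's fixed terms
(interaction ⇒ both mains; intercept-only included) are enumerated
deterministically, with identical random structure and weights. The count
formula Σ_S 2^(#interactions licensed by main subset S) guards a
configurable enumeration cap (default 10⁵) before any fitting starts.

AICc = AIC + 2k(k+1)/(n−k−1) everywhere (domain error at n ≤ k+1). Models
within ΔAICc < 4 of the best form the candidate set; Akaike weights
exp(−Δ/2) are renormalized over that set. A term's relative importance is
100 × the summed weights of candidate models containing it, so a term in
every candidate model has RI = 100% and a term in none has 0%. Terms with
RI *strictly* above 50% (the interpretation threshold) enter the final
model, closed under marginality, which is then refit by REML. Categorical
terms move as whole terms; exact AICc ties simply share weight.

A known property of this procedure worth stating: for a single-parameter
zero-effect term, RI exceeds 50% exactly when the term's likelihood-ratio
χ²(1) exceeds the ≈2-point AICc penalty, an event with probability
P(χ²₁ > 2) ≈ 0.157 regardless of sample size. Zero-effect continuous terms
therefore stay below the 50% bar in roughly 84–85% of replicates — close to,
and occasionally at, the 90% discrimination rate the recovery experiments
target — while multi-parameter categorical null terms are discriminated more
strongly (χ² with more degrees of freedom against a proportionally larger
penalty). This is the familiar mild overfitting tendency of AIC-type
selection, not an implementation artifact.

## Diagnostics

**Correlograms.** Great-circle distances use the haversine formula on a
6371-km sphere. Distance classes are half-open bins (default 100-km width to
5000 km in the library; the pipeline default uses wider bins at synthetic
scale) with binary pair-membership weights; Moran's I per class is
I = (n/S0)·Σ w_ij z_i z_j / Σ z_i², with expectation −1/(n−1) under
independence. p-values are one-sided (upper tail — positive autocorrelation
is the alarm) permutation probabilities, p = (1+#{I* ≥ I})/(n_perm+1), with
one shared set of `n_perm` (default 999) seeded permutations across classes.
Classes with fewer than 2 pairs are flagged empty rather than reported.

**Jackknife.** Units are species or 3°×3° geographic cells anchored at
(−180°, −90°) with half-open intervals (points on the antimeridian join the
western cell). Each unit is left out in turn and the model refit with
categorical levels pinned to the full-data design so coefficients stay
aligned; refits that fail (typically a lost factor level) are logged and
skipped with a warning. The delete-group SE is sqrt((m−1)/m · Σ(θ₋ᵢ − θ̄)²)
over the m successful refits — unequal group sizes are accepted as-is, a
documented simplification — and the CI is the full-data estimate ± z·SE
(SE-based rather than percentile, since per-unit deletions are few).

## Synthetic data

The generator emulates the structure of a global heterozygosity compilation:
250 species by default, allocated to nine phyla (eudicots, magnolids,
monocots, pines; amphibians, reptiles, molluscs, mammals, birds) with the
relative frequencies of the source-style compilation, each with 2–50
populations scattered (Gaussian, 4° SD) around a species range centre drawn
over a 130° latitudinal span. Marker technology is assigned per species
(a study typically uses one technology), with a 60/25/15
codominant/dominant/enzyme mixture; locus counts 5–30 and sample sizes
10–50 produce weights through the real formula. Plant trait classes use the
per-population frequencies of the compilation; animal size and longevity are
drawn correlated (r ≈ 0.7 on the log scale) with independent fecundity, so
the life-history PCA has the intended two-axis structure. Temperature tracks
distance from the equator; the other climate axes are independent site
effects. Position classes are sampled from fixed frequencies rather than
derived from simulated range polygons — geometry is exercised separately by
the analytic tests.

The response is simulated directly on the harmonized scale from the exact
model the fitter assumes (default intercept 0.55, latitude slope −0.006,
plant offset −0.15, τ²_species = 0.02, τ²_marker = 0.002, σ² = 0.01),
with a per-marker affine back-transform to raw H_E provided for I/O realism
only — re-harmonizing the back-transformed values changes coefficients
across markers, so recovery experiments consume the simulated response
directly. Clipping to [0, 1] is available but off by default since it breaks
Gaussianity. One root seed drives independent sub-streams (species,
populations, climate, response), so components can be regenerated in
isolation; two presets exist — `recovery_config` (250 species, 2–10
populations each ≈ 1500 rows, slope −0.05, τ²_species = 0.5σ²) for
CI-coverage experiments and `ri_config` (two active, two null predictors)
for relative-importance discrimination.

What passing these tests does *not* show about real compilations: real
heterozygosity is bounded and heteroscedastic in ways a Gaussian response is
not; species ranges, sampling effort and trait coverage are strongly
non-random; marker technology correlates with taxon and publication year;
and position classes come from real range maps with their own error. The
synthetic results validate the *machinery* (estimators, selection,
diagnostics), not the biology.

## Problem sizes and runtime choices

Default test and acceptance runs use 250-species compilations (~1500–6500
rows), 100 seeds for CI coverage, 20 dredge replicates for RI
discrimination, and 199–999 permutations for correlograms — sizes at which
every stage's statistical behaviour is measurable while a full run stays in
the order of a minute on one CPU. The pipeline's default dredge restricts
the full kingdom model to a trimmed main-effect set (the full structure with
all phylum interactions enumerates hundreds of thousands of submodels and is
available by passing `mains="all"` and raising the enumeration cap).

## Known limitations

- No generalized (non-Gaussian) responses, random slopes, or phylogenetic
  covariance matrices — species identity alone absorbs relatedness.
- The equal-area projection is spherical; ellipsoidal area errors (~0.1–0.3%)
  are well inside the 0.5% erosion tolerance but matter for very large or
  polar ranges.
- Coefficient model-averaging is deliberately absent: the workflow refits a
  single final model from the RI-selected terms.
- The correlogram's permutation test assumes exchangeability of values over
  locations, which residuals only approximately satisfy.
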