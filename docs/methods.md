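# Methods

`nichecast` implements an envelope-based ensemble species distribution
modelling (SDM) pipeline for pest-risk mapping, together with the survey and
field statistics that typically accompany such a risk assessment. This note
records the models, their assumptions, the numerical choices, and what the
synthetic validation does and does not establish.

## Data model

Rasters live on a regular row-major grid with row 0 at the northern edge;
cells are half-open `[x, x+dx) × (y−dy, y]`, so a point maps to a unique cell
by flooring its fractional index (a point exactly on a shared edge belongs to
the east/south neighbour). Layers in a `ClimateStack` share a single nodata
mask — the union of the per-layer nodata — so every cell is either valid in
all layers or excluded everywhere. Occurrence records falling off-grid or on
masked cells are flagged by index and excluded from fits with a warning,
never silently dropped: occurrence compilations routinely contain coastal
points that fall off a terrestrial grid. Multiple records in one cell are
thinned to a single presence cell for model fitting (configurable off), the
standard guard against pseudo-replication in SDMs.

Raster I/O supports plain-text ESRI ASCII grids (square cells; floats written
with nine significant digits so float32 data round-trip bit-exactly) and
float32 TIFF via `tifffile` with a JSON sidecar carrying the geotransform and
nodata value.

## Variable selection

Candidate climate layers are reduced in two stages.

1. **Ward clustering of correlated layers.** The dissimilarity is
   `d(i,j) = 1 − |r(i,j)|` (Pearson `r` over sampled valid cells), so a
   distance threshold of 0.3 groups variables correlated above roughly 70%.
   The absolute value means strong *negative* correlation also counts as
   redundancy. Ward linkage is applied to this dissimilarity directly, with
   no Euclidean embedding; Ward formally assumes Euclidean distances, so this
   is a pragmatic convention (and the one the clustering literature most often
   sees in practice for correlation screens). The agglomeration is verified
   in the tests against an independent greedy Lance–Williams implementation.
2. **Representative choice and VIF filter.** "Most informative" member of a
   cluster is not a well-defined quantity; the default rule takes the member
   with the largest variance after z-scoring over the study area, and a
   `force_keep` list overrides the rule so a published predictor set (e.g.
   BIO3, BIO7, BIO10, BIO15, BIO18, BIO19) can be imposed exactly. Surviving
   variables then pass an iterative variance-inflation-factor filter:
   `VIF_i = 1/(1 − R_i²)` from ordinary least squares of the z-scored
   variable on the others, dropping the worst while any VIF exceeds 5.
   Exact collinearity yields an infinite VIF and an immediate drop rather
   than an error. Correlations and VIFs are computed on at most 50 000
   randomly sampled valid cells (seeded) for tractability; whether to sample
   all cells or presence cells only is an open question in this kind of
   analysis — all valid cells is the default.

## Envelope, background and pseudoabsences

The environmental envelope is the per-variable `[min, max]` interval spanned
by presence cells, with closed boundaries so that every presence cell lies
inside its own envelope. Each valid cell is classified by the number of
selected variables whose value falls strictly outside its interval:

| failures | class | used as |
|---|---|---|
| 0 | background | available environment (MaxEnt contrast) |
| 1 | excluded | neither pool |
| ≥ 2 | pseudoabsence | surrogate absence |

Cells failing exactly one variable belong to neither pool: the rule set
defines background (fail 0) and pseudoabsence (fail ≥ 2) and is silent about
fail-1 cells, so forcing them into either pool would invent information.
Point samples are drawn uniformly without replacement from each pool at cell
centers; defaults are one pseudoabsence per presence and ten background
points per presence (both configurable, both capped at the pool size).

Note a structural consequence: a one-variable envelope can never produce
pseudoabsences (no cell can fail two of one variable), so single-predictor
models must be given a partition built from a larger variable set.

## Ensemble model

`EnsembleSDM.fit` runs six algorithm families — the set conventionally
bundled by SDM ensemble platforms — as scikit-learn pipelines on z-scored
features:

* **GLM** — logistic regression with linear + quadratic terms, no penalty;
* **GAM** — logistic regression on per-variable cubic spline bases
  (5 knots), lightly ridge-penalized for stability;
* **ANN** — one-hidden-layer (5 units) multilayer perceptron;
* **CTA** — a single classification tree, depth ≤ 8, ≥ 5 points per leaf;
* **RF** — 500-tree random forest, ≥ 2 points per leaf;
* **MAXENT** — L1-regularized logistic contrast of presences against
  *background* points with linear + quadratic + pairwise-product features,
  the standard maximum-entropy/logistic equivalence for presence–background
  data.

All families except MAXENT are trained on presences (1) vs pseudoabsences
(0). The schedule is: a stratified 25% *external* holdout of presences,
pseudoabsences and background is set aside once, before the iteration loop,
and enters no fit; each of the `n_iterations` (default 100) iterations draws
a fresh stratified 75/25 split of the remaining pool, fits all six
algorithms on the 75% side and scores an *internal* AUC
(presences vs pseudoabsences) on the 25% side. With the defaults this
attempts 6 × 100 = 600 member models. A member contributes to the ensemble
only if its internal AUC is *strictly* greater than the keep threshold
(default 0.7). A member that fails to converge is marked failed, logged in
the run table, and the pipeline continues; if no member survives, fitting
aborts with the full AUC table in the error.

The **consensus** map is the cell-wise mean of kept-member predictions; the
**lower/upper bound** maps are cell-wise 2.5th/97.5th percentiles of the
kept-member predictions (configurable to min/max). "Bound models" have no
canonical definition in ensemble SDM practice; percentiles were chosen
because they are robust to a single wild member. The percentile of a mean
can in principle cross the mean on skewed member distributions, so the
bounds are clamped to the consensus, making `lower ≤ consensus ≤ upper` an
identity. External AUC for consensus, lower and upper is the AUC of the
corresponding ensemble statistic evaluated at the held-out presence and
pseudoabsence points.

All randomness descends from one master seed through
`numpy.random.SeedSequence` spawning; the same seed reproduces the run table
and all maps bit-for-bit.

**Variable contributions** are permutation importances: for a member, the
contribution of a variable is `1 − max(r, 0)` where `r` is the Pearson
correlation between its predictions on the training matrix and on the same
matrix with that variable's column permuted (three permutations per member,
averaged over an algorithm's kept members, reported in percent; MAXENT is
evaluated on its presence–background matrix). Negative correlations are
floored at zero so contributions stay in [0, 100]%.

**Binarization** uses a closed rule: a cell is suitable iff its consensus
value is ≥ the cut-off (default 0.55). **Validation** extracts the consensus
at independent occurrence points and counts points above/below the cut-off.

A `shuffle_labels=True` fit permutes the presence/pseudoabsence labels before
the external split — a built-in null-calibration diagnostic whose external
AUC should sit near 0.5. Two practical notes from that diagnostic: (i) the
AUC keep filter must be disabled (`auc_keep=-1`) because under the null
almost no member exceeds 0.7, and (ii) when the pseudoabsence pool is much
smaller than the presence sample, the fixed-count label permutation
anti-correlates the train and eval label totals and overfit members show a
genuine *negative* AUC bias — the diagnostic is only clean with roughly
balanced pools, so the validation suite runs it on balanced pools of
uniformly random cells (labels independent of climate by construction).

## Niche contrast

No-record comparison points are sampled from valid cells that hold no
occurrence record and fall below the cut-off in *both* the lower and upper
bound maps — cells the ensemble confidently calls unsuitable. One hundred
sets, each the size of the (thinned) presence sample, are drawn without
replacement. The default reduction averages the no-record value vectors
element-wise across sets into a single comparison sample of presence-sample
size (positions within a set are random, so this approximates the pooled
mean with reduced variance); `mode="pool"` concatenates the sets instead.
The contrast per variable is a two-sample Student's t with pooled variance
and `df = n₁ + n₂ − 2`.

Two caveats are inherent to this design and documented rather than "fixed":
the procedure is circular (the no-record sample is defined through the
fitted model it then characterizes), and the averaging mode shrinks the
no-record sample's variance, making the t statistics larger than a plain
two-sample contrast would give. The contrast describes where the model
places the species, not an independent habitat test.

## Crop overlap

The continuous pest-suitability raster is paired cell-by-cell with the
categorical crop map (suitable / conditioned / unsuitable); on mismatched
grids each crop cell reads the suitability cell containing its center
(nearest-neighbour, no interpolation). Cells with nodata in either layer are
excluded pairwise. Category differences are tested with a one-way
fixed-effects ANOVA and Bonferroni-adjusted pairwise t-tests (raw p times
the number of pairs, capped at 1). Grid cells are treated as independent
observations, as is conventional in this kind of overlay; under spatial
autocorrelation that inference is anticonservative, which is why the
per-category means and SEs, not the astronomically large F values, are the
quantities to interpret.

## Survey and field statistics

Per-tree counts (males, females, copulae, egg clusters) are tested for a
clumped distribution via Shapiro–Wilk and sample skewness; both the biased
moment estimator `g1 = m₃/m₂^{3/2}` and the small-sample adjusted `G1` are
reported, with the sign convention that positive skew means a few trees
accumulate most observations. Associations between count types use Pearson
correlation, including egg clusters per copula restricted to trees with at
least one mating pair; zero-variance columns are reported as degenerate, not
errors.

Survey regressions follow the one-covariate-at-a-time design. Attack (0/1)
is fitted by maximum-likelihood logistic regression; the reported statistic
is the likelihood-ratio χ² against the intercept-only model (df = 1), with
`D² = (null deviance − residual deviance)/null deviance`. A constant
covariate yields LR = 0 and p = 1 exactly; perfect separation is reported as
non-estimable with a diagnostic note instead of raising. Perceived impact
(0/1/2, defined only for attacked fields) is fitted by the proportional-odds
cumulative-logit model (statsmodels `OrderedModel`); the reported statistic
is the Wald z-type `t = β/SE` with a two-sided normal p, a McFadden-style
`D² = 1 − ll/ll₀`, and df reported as the number of threshold parameters
(2 for a three-rank outcome), matching the conventional presentation of such
tables.

## Synthetic study systems

The generators in `nichecast.synthetic` emulate the statistical structure
every downstream stage assumes, with a known truth for recovery testing:

* **Climate stacks** — Gaussian-filtered white noise (σ = `smoothness`
  cells, default 5) rescaled to realistic ranges of the six bioclimatic
  variables retained in the motivating Iberian analysis (BIO3, BIO7, BIO10,
  BIO15, BIO18, BIO19); a `mix` parameter injects pairwise correlation.
* **True niche** — logistic in the z-scored variables, optionally quadratic.
  The canonical "well-separated" demonstration niche used in validation is
  `β₀ = −2, β = (4, −3, 2)` on BIO3/BIO7/BIO10: presences concentrate in a
  climatic hotspot and leave a broad unsuitable hinterland, the geometry a
  thermophilic Mediterranean species shows at peninsular scale. Milder
  niches make most of the landscape habitable, which shrinks the
  pseudoabsence pool and genuinely degrades both rank recovery and the null
  diagnostics — a property of envelope-based pseudoabsence designs, not of
  this implementation.
* **Presences** — cells drawn with probability proportional to true
  suitability, with replacement, points at cell centers (downstream thinning
  handles duplicates).
* **Crop maps** — category regions carved from a smooth latent field by its
  quantiles, so areal proportions are met to ±1 cell and regions are
  contiguous-ish.
* **Surveys** — field areas log-normal (defaults reproduce a 0.7–119 ha
  range with mean ≈ 11); age compositions mix pure young/moderate/old fields
  with Dirichlet-mixed ones; attack is Bernoulli on a logit linear in area,
  age percentages and suitability; impact follows a proportional-odds model
  with two thresholds, generated only for attacked fields. The default
  effect structure (weak positive suitability effect on attack, weak
  negative on impact, null everything else) mirrors the effect pattern such
  surveys report.
* **Tree counts** — negative binomial with mean m and dispersion k
  (variance m + m²/k); k → ∞ recovers Poisson. The source field data report
  only non-normality and skewness, so the negative binomial is the natural
  minimal model for the clumping; defaults (e.g. males: m = 18, k = 0.6)
  reproduce Shapiro–Wilk W ≈ 0.7–0.8 and skewness ≈ 2 at 59 trees.

What passing the synthetic suites shows: the pipeline's bookkeeping is exact
(oracle agreement), its estimators are calibrated under their own assumed
data-generating processes (type-I error, CI coverage), and the ensemble can
recover a known smooth logistic niche from presence-only data. What it does
not show: behaviour under sampling bias, spatial autocorrelation of errors,
niche truncation at the study-area boundary, or classification of real
landscapes — the synthetic fields are smooth, isotropic and unbiased in ways
real occurrence data are not.

## Validation problem sizes

The validation suites use a 60 × 60 grid with six variables, 200 presences
and 100 ensemble iterations (600 member models) for recovery, five
replicate seeds; 20 × 20 × 4 stacks × 100 seeds for the envelope oracle;
500 replicates for the type-I-error and CI-coverage checks (surveys of 165
and 300 fields). These sizes give the calibration checks binomial standard
errors of about 0.01 while keeping a full validation run in the
tens-of-minutes range on one CPU.

## Known limitations

* The six learners are this package's own surrogates for the algorithm
  families usually run through platform wrappers; coefficients and maps are
  not expected to be bit-compatible with any other implementation.
* The envelope partition ignores geography: pools are defined in climate
  space only, with no distance buffers around presences.
* Ordinal D² uses the McFadden form; other pseudo-R² conventions will give
  different values for the same fit.
* No reprojection: all inputs must share a grid (crop maps may differ and
  are matched by nearest neighbour).
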