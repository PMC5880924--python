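# Methods

This note documents the models and procedures betashift implements, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Data model

The analysis takes two site × species presence/absence matrices (an early
"historical" and a late "current" survey of the same regional site set), a
species × categorical-trait table, and optionally a per-site, per-period
covariate table of human-impact descriptors (lake area in km², total
phosphorus in mg L⁻¹, Secchi depth in cm, fishery catch in t km⁻²) plus
site centroids in decimal degrees. Alignment intersects the site sets
(keeping historical order), takes the union of the species axes zero-filled
where absent, drops species absent from both periods, and retains — but
flags — sites that are empty in one period, since several downstream
ratios divide by richness. Long occurrence tables collapse with OR
semantics (any record ⇒ present), matching the pooling of repeated surveys
of one site. An optional boolean `invasive` trait column supports excluding
non-native species before analysis (off by default).

## Functional space

Five categorical traits are used by default — life form (submerged,
floating-leaved, emergent, free-floating), life cycle (annual, perennial),
morphology (turion, stem, rosette, leafy), dispersal range (local,
regional, Asian endemic, cosmopolitan) and sexual propagation (monoecism,
dioecy); 16 levels in all. The default pipeline one-hot encodes them,
computes Euclidean distances between species, and embeds the distance
matrix by principal coordinates analysis, retaining m = 3 axes. A Gower
(simple-matching) distance is offered because categorical traits are more
conventionally handled that way; for traits with equal level counts the two
give the same distance ranking.

PCoA choices: the squared-distance matrix is double-centered (Gower
transform) and eigendecomposed; coordinates are eigenvectors scaled by
√eigenvalue. Negative eigenvalues are excluded from both the coordinates
and the quality denominator (quality = positive-eigenvalue mass captured by
the retained axes); a Lingoes correction is available behind a flag but is
not applied by default. Axis orientation is fixed by forcing each axis's
largest-magnitude loading positive, so runs are bit-reproducible; ties in
eigenvalues are broken by input species order, which amounts to an
arbitrary rotation within the tied subspace (documented, harmless to
volumes and distances). If fewer than m positive eigenvalues exist the
space is reduced with a warning.

With one-hot Euclidean distances on five traits, three axes capture roughly
45–50% of the positive eigenvalue mass for a ~275-species pool of
independently drawn traits. Empirical trait tables are strongly correlated
across traits and concentrate more variance in the leading axes; the
package reports the realized quality rather than assuming one.

## Diversity indices

Taxonomic richness is the species count; functional richness (FRic) is the
m-dimensional convex-hull volume of an assemblage's species coordinates
standardized by the hull volume of the *combined two-period pool* (the
per-period pool is available by flag, but cross-period comparability
requires a common denominator). Assemblages with fewer than m+1 affinely
independent points have zero hull volume; FRic is 0 for them.

Pairwise dissimilarity uses the Jaccard family by default (Sørensen behind
a flag): D = (b+c)/(a+b+c), turnover D_tu = 2min(b,c)/(a+2min(b,c)),
nestedness D_ne = D − D_tu. For the functional facet the components are
hull volumes: a = volume(hull(X) ∩ hull(Y)), b = V(X) − a, c = V(Y) − a.
The union volume is always V(X)+V(Y)−a; the hull of the pooled points is
never used because it can exceed the true union. The intersection is
computed by stacking the two hulls' facet half-spaces and finding a
Chebyshev-center interior point by linear programming; an infeasible or
zero-radius program means disjoint interiors (a = 0), otherwise the
half-space intersection's vertices are hulled for the volume. This is exact
up to floating point and is verified in the tests against Monte Carlo
rejection sampling. Volumes below 1e−12 of the pool volume are treated as
zero to stabilize ratios. Pairs in which either hull is degenerate are
flagged missing and excluded from functional summaries, with the flag
carried in the output tables.

## Temporal change

Every index (richness ratio, D, D_tu, D_ne and the two contribution ratios,
for both facets) is differenced current − historical. A pair with a
positive change in D is classified as differentiation; zero change is
binned with homogenization ("no change or homogenization"), with exact
zeros counted separately. Functional cells are additionally cross-labelled
by the taxonomic class (TH/TD), and cross-class percentages add to their
facet totals because all percentages share the retained-pair denominator.
Intensities are the mean ± SD of the deltas within each cell.

Per-species extirpation is the number of sites occupied historically but
not currently; colonization is counted separately and never subtracted.
The regional richness decline is reported both as the decline of the mean
(computed from the two period means) and as the mean of per-site percent
declines — these differ and are labelled distinctly. "Species lost from a
pair" (used in the Mantel test against dissimilarity change) is the number
of species present in the union of the pair's historical assemblages but
absent from the union of its current assemblages; a per-site-sum variant is
available by flag since the construction is not canonical.

## Inference

Predictor construction: each covariate's between-period change is taken on
a variance-stabilizing scale — log ratio for area and total phosphorus,
difference of square roots for Secchi depth, plain relative change for
catch — then min-max standardized to [0, 1]. Taking the change on the
transformed scale (rather than transforming a signed relative change,
which is undefined for log) is this package's operationalization of
"transform, then standardize".

Mantel and MRM share one permutation core. Statistics are computed on
lower-triangle entries; the null relabels the objects of the response
matrix (simultaneous row/column permutation); p-values are two-sided with
the +1 correction, p = (#{|t*| ≥ |t|}+1)/(nperm+1), or exact by full
enumeration of all n! relabelings on small problems (p = #{|t*| ≥ |t|}/n!,
identity included). Spearman correlations rank-transform the triangles
once up front — valid because relabeling permutes the multiset of pair
values. MRM re-estimates all coefficients each permutation via a
precomputed pseudoinverse; its R² also gets a (one-sided, ≥) permutation
p-value. Defaults are 10,000 permutations; tests and the acceptance script
use fewer for speed.

Matrix inference runs on the sites that support it: taxonomic change
matrices need sites occupied in both periods, functional ones sites with
non-degenerate hulls in both periods. Restricting the *site set* (rather
than dropping individual pairs) keeps the permutation null exact; the site
lists used are recorded in the results.

GLMs are fitted by IRLS through statsmodels: Gaussian/identity for per-site
richness changes on the four impact predictors (ordinary R² reported),
Poisson/log for per-species extirpation counts on the PCoA axes
(deviance-based pseudo-R²). VIFs (1/(1−R²_j) from auxiliary OLS fits) are
attached whenever there are ≥ 2 predictors; the conventional screening
threshold in this literature is VIF < 2. Coefficient drift beyond 1e8 or
IRLS non-convergence is flagged on the result, not raised. Geographic
structure enters MRM as a great-circle distance matrix between site
centroids (an additional fixed predictor); a site-level random effect is
out of scope for these fixed-effect GLMs, so the GLMs instead accept two
standardized coordinate covariates behind a flag (off by default). This is
a documented divergence from treating geography as a "random covariate",
which has no literal fixed-effects implementation.

## Null model

The null asks whether the current assemblages' mean pairwise taxonomic
nestedness component exceeds what random regional loss would produce.
"Preserving the characteristics of the observed matrix" is operationalized
as: each replicate removes ⌈loss_fraction · S_hist⌉ species from the
historical pool (uniformly by default, or with probability ∝ 1/occupancy
under `occupancy_weighted`), then draws each site's simulated current
assemblage uniformly from its surviving historical species with size equal
to the observed current richness, capped at availability (capped sites are
counted and reported). Row sums are therefore preserved up to the cap, and
every simulated assemblage is a subset of its historical one. The loss
fraction defaults to the observed pool reduction. The p-value is one-sided
("observed greater"), (#{null ≥ obs}+1)/(nreps+1), default 9,999
replicates. The statistic defaults to the mean pairwise taxonomic D_ne;
pairs undefined because both sites are empty are excluded.

## Synthetic data generator

The generator targets the statistical structure of a two-period regional
macrophyte survey — not hydrology or population dynamics. Defaults are the
emulated study conditions: 30 sites, a 275-species pool, mean historical
richness 67.5, a mean extirpation probability of 0.41 (matching the
observed mean per-lake richness decline), trait-level frequencies with 65%
cosmopolitan and 25% Asian-endemic dispersal, susceptibility elevated for
submerged and cosmopolitan species, and impact effects led by habitat loss
and fishery intensity with weaker water-quality effects.

Historical matrices: sites are uniform on a plane; each species has a
Beta-distributed occupancy propensity and a uniform niche center; presence
probability is the propensity times an exponential distance-decay kernel
(rate = `turnover_strength`, 0 disables spatial structure), globally
rescaled — iterating against the 0.98 probability clip — so realized mean
richness hits the target. Every site is guaranteed ≥ 1 species. Expected
pairwise dissimilarity thus increases with inter-site distance, the
distance-decay mechanism appropriate for environmental filtering across a
hydrological mosaic.

Current matrices: per-site loss intensity is a linear combination of
standardized covariate changes (signs oriented so "more impact" is
positive: area and Secchi losses, phosphorus and catch gains) plus
lognormal noise; per-species log-hazard comes from trait-level
susceptibilities and/or per-PCoA-axis coefficients. Removal probabilities
`base_loss · exp(η_i + h_s)` are renormalized over occupied cells — again
iterating against the 0.97 clip — so the realized mean loss matches
`base_loss`, then applied as independent Bernoulli draws. Colonization is
off by default, making every current assemblage an exact subset of its
historical one. A `ranked_loss` variant removes each site's top-ranked
species deterministically — by rarity (lowest historical occupancy first,
the classic nested-subset structure) or by trait hazard — and is the
scenario used to exercise null-model power: rarity-ranked loss produces
observed nestedness far above the random-loss null, while Bernoulli loss
does not, which is itself informative about what the null detects.

What the generator does **not** emulate: phylogenetic or trait correlation
structure (traits are drawn independently), abundance, detection error,
temporal autocorrelation of surveys, and regional pool extinction dynamics
beyond what site-level Bernoulli loss induces (its realized pool reduction
of a few percent is an emergent property, smaller than empirical regional
losses driven by selective extirpation of rare species). Passing tests
therefore demonstrate correctness of the estimators and calibration of the
inference under these mechanisms, not that empirical systems behave this
way.

## Numerical conventions

Volumes: Qhull via scipy; degenerate inputs return 0 with a flag rather
than raising. Partition identity D = D_tu + D_ne holds to 1e−10 and is
asserted in tests. Permutation p-value comparisons use a 1e−12 tolerance
on |statistic| to make ties robust to floating point. All stochastic steps
take a seed; the model derives per-stage seeds from one root seed via
`SeedSequence` and records them in the run manifest. Report floats are
written at 6 significant digits so byte-identity of reruns is well-defined.

## Problem sizes used in the checks

The test suite and acceptance script scale simulations to the package's
verification needs: type-I error uses 500 independent 15-site datasets at
499 permutations; parameter recovery uses 100 (Poisson) and 50 (MRM)
full-size bundles; null-model calibration uses 200 scaled-down (12-site)
runs of 99 replicates; the acceptance report uses 999 permutations and 999
null replicates. Library defaults remain 10,000 and 9,999.

## Known limitations

- Functional beta for assemblages with < m+1 species is undefined (flagged
  missing), so heavily extirpated sites drop out of functional matrix
  inference; the retained site lists are reported.
- The MRM pairwise impact predictor |Δᵢ − Δⱼ| is one defensible
  construction; a mean-based alternative is provided, and results can
  differ between them.
- No multi-site (> 2 assemblage) beta diversity, no abundance-based
  indices, no dendrogram-based functional diversity, and no fixed-fixed
  swap/curveball co-occurrence nulls (a different question from regional
  loss).
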