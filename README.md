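# betashift

Temporal change in the taxonomic and functional diversity of species
assemblages, analysed the way regional before/after surveys of freshwater
macrophytes (or any presence/absence community data) are: trait-based
functional spaces, convex-hull functional richness, Jaccard-family
beta-diversity partitioned into turnover and nestedness, classification of
pairwise homogenization vs differentiation, trait-based extirpation models,
permutation inference against human-impact covariates, and a Monte Carlo
null model for nestedness — plus a synthetic-data generator with known
ground truth so the whole pipeline is testable without any field data.

## Who this is for

Community ecologists comparing two survey periods of a regional set of
sites (lakes, plots, islands...) recorded as site × species presence/absence
matrices, with categorical species traits and per-site environmental or
human-impact covariates.

## The statistics at the core

**Beta diversity and its partition.** For two assemblages with `a` shared
species, `b` unique to the first and `c` unique to the second, the Jaccard
dissimilarity and its decomposition are

    D    = (b + c) / (a + b + c)
    D_tu = 2·min(b,c) / (a + 2·min(b,c))        (turnover)
    D_ne = D − D_tu                              (nestedness)

(Sørensen family available behind a flag). Functional dissimilarity uses the
same formulas with convex-hull volumes in trait space: `a` is the volume of
the intersection of the two assemblages' hulls (computed by half-space
intersection about a Chebyshev-center interior point), `b` and `c` the
volumes unique to each hull.

**Functional space and richness.** Categorical traits are one-hot encoded,
species distances are Euclidean, and principal coordinates analysis (PCoA)
embeds them; the first three axes define the functional space. Functional
richness (FRic) is the hull volume of an assemblage's species divided by
the pool hull volume, ranging 0 (one species) to 1 (the full pool).

**Temporal change.** Every index is differenced `current − historical`; a
positive change in pairwise dissimilarity is *differentiation*, a negative
or zero change *homogenization*. Frequencies and mean ± SD intensities are
tabulated per facet and cross-classified.

**Inference.** Mantel tests and multiple regression on distance matrices
(MRM) with two-sided permutation p-values (simultaneous row/column
relabeling, +1 correction, exact enumeration on small problems); Gaussian
and Poisson GLMs with VIF screening for richness-change and extirpation
models; a paired t-test for the regional richness decline.

**Null model.** Is the observed mean pairwise nestedness of the current
assemblages larger than expected after random regional species loss? Each
Monte Carlo replicate removes the observed fraction of the historical pool
at random and redraws every site's current assemblage from its surviving
historical species at the observed current richness.

## Worked example

```python
from betashift import SyntheticScenario, TemporalDiversityModel

scenario = SyntheticScenario(seed=42)          # 30 lakes, 275-species pool
model = TemporalDiversityModel.from_scenario(scenario)
results = model.fit(nperm=999, null_reps=999, seed=1)
print(results.summary())
```

prints

```
Temporal diversity change summary
========================================
sites: 30   species pool: 247 -> 230 (6.9% reduction)
functional space: 3 axes, quality 0.458
mean richness: 67.8 -> 38.8  (paired t = 7.94, p = 0.0000)
taxonomic dissimilarity change: +0.144 +/- 0.095  (98.2% differentiation)
functional dissimilarity change: +0.209 +/- 0.215  (95.3% differentiation)
nestedness null model: observed 0.130 vs null 0.122 +/- 0.015 (p = 0.306, 999 reps)
MRM[tax]: R2 = 0.353 (p = 0.001); top predictor: area_km2 (p = 0.001)
MRM[fun]: R2 = 0.048 (p = 0.52); top predictor: secchi_cm (p = 0.224)
GLM[taxonomic]: R2 = 0.804, max VIF = 1.27
GLM[functional]: R2 = 0.790, max VIF = 1.27
extirpation GLM (poisson): pseudo-R2 = 0.049
```

Reading this: the synthetic region lost 29 of 68 mean species per lake
(paired t = 7.94), nearly every lake pair became more dissimilar in both
facets (differentiation), the impact regressions recover habitat loss
(`area_km2`) as the dominant driver of taxonomic change with all VIFs well
below 2, and the random-loss null model does not flag the (Bernoulli-loss)
current assemblages as unusually nested. `results.save("outdir/")` writes
the full report bundle (beta tables, change table, summary tables,
extirpation records, JSON results, run manifest with every seed).

The same analysis runs from the shell on CSV inputs:

```sh
betashift simulate --outdir bundle --seed 42
betashift run --historical bundle/historical.csv --current bundle/current.csv \
    --traits bundle/traits.csv --covariates bundle/covariates.csv \
    --outdir report --seed 1
betashift nullmodel --historical bundle/historical.csv \
    --current bundle/current.csv --reps 9999 --seed 1
```

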