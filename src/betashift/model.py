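"""Top-level modelling interface.

:class:`TemporalDiversityModel` bundles the aligned two-period assemblage
matrices, the trait table and (optionally) the human-impact covariates;
``fit()`` runs the full analysis — functional space, pairwise beta diversity
for both periods, temporal change classification, extirpation and richness
GLMs, Mantel/MRM permutation tests and the nestedness null model — and
returns a :class:`TemporalDiversityResults` carrying every table and test,
with ``summary()`` and ``save()``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .change import (
    build_change_table,
    classify_changes,
    extirpation_counts,
    pair_species_loss_matrix,
    pool_reduction,
    site_richness_change,
    table1_summary,
)
from .diversity import (
    _hull_or_none,
    hull_volume,
    pairwise_beta,
    taxonomic_beta_matrices,
)
from .exceptions import CoverageError, StageError
from .functional_space import build_functional_space, space_quality
from .inference import (
    glm_fit,
    great_circle_matrix,
    mantel,
    mrm,
    paired_t,
    transform_standardize,
)
from .io import (
    CovariateTable,
    PairedAssemblages,
    TraitTable,
    align_periods,
    read_assemblage_matrix,
    read_covariate_table,
    read_trait_table,
    traitless_species,
)
from .nullmodel import null_nestedness_test

__all__ = ["TemporalDiversityModel", "TemporalDiversityResults",
           "DEFAULT_TRANSFORMS", "impact_change_predictors",
           "square_from_pairs"]

#: Variance-stabilizing transform per covariate, applied to the per-period
#: values before the between-period change is taken (log: log-ratio change;
#: sqrt: difference of square roots; none: plain relative change).
DEFAULT_TRANSFORMS = {"area_km2": "log", "tp_mg_l": "log",
                      "secchi_cm": "sqrt", "catch_t_km2": "none"}


def impact_change_predictors(covariates: CovariateTable,
                             transforms: dict | None = None) -> pd.DataFrame:
    """Per-site standardized impact-change predictors, one column each.

    The change between periods is taken on the transformed scale, then
    min-max standardized to [0, 1].
    """
    transforms = dict(DEFAULT_TRANSFORMS, **(transforms or {}))
    hist = covariates.period("historical")
    curr = covariates.period("current")
    out = {}
    for cov in hist.columns:
        t = transforms.get(cov, "none")
        if t == "log":
            delta = np.log(curr[cov] / hist[cov])
        elif t == "sqrt":
            delta = np.sqrt(curr[cov]) - np.sqrt(hist[cov])
        else:
            delta = (curr[cov] - hist[cov]) / hist[cov]
        out[cov] = transform_standardize(delta.to_numpy(), "none")
    return pd.DataFrame(out, index=hist.index)


def square_from_pairs(pairs: pd.DataFrame, column: str,
                      site_ids: list) -> np.ndarray:
    """Square symmetric matrix (zero diagonal) from a long pair table."""
    idx = {s: k for k, s in enumerate(site_ids)}
    M = np.zeros((len(site_ids), len(site_ids)))
    i = pairs["site_i"].map(idx).to_numpy()
    j = pairs["site_j"].map(idx).to_numpy()
    v = pairs[column].to_numpy(dtype=float)
    M[i, j] = v
    M[j, i] = v
    return M


@dataclass
class TemporalDiversityResults:
    """Everything the fitted model computed.

    Attributes mirror the analysis stages: the functional space and its
    quality, per-period beta tables, the per-pair change table with its
    Table-1/Table-2 style summaries, per-site richness changes and the
    paired t-test, per-species extirpation records with the Poisson trait
    GLM, richness-change GLMs, Mantel/MRM permutation tests, and the
    nestedness null model.
    """

    model: "TemporalDiversityModel"
    space_quality: float
    pool_volume: float
    beta_historical: pd.DataFrame
    beta_current: pd.DataFrame
    change_table: pd.DataFrame
    table1: pd.DataFrame
    table2: pd.DataFrame
    site_change: pd.DataFrame
    extirpation: pd.DataFrame
    pool_reduction_pct: float
    mean_pct_richness_decline: float
    richness_t: object
    extirpation_glm: object | None = None
    richness_glm: dict = field(default_factory=dict)
    mrm_results: dict = field(default_factory=dict)
    mantel_results: dict = field(default_factory=dict)
    richness_congruence: float | None = None
    null_result: object | None = None
    seeds: dict = field(default_factory=dict)
    #: sites supporting each facet's matrix inference (tax: occupied in both
    #: periods; fun: non-degenerate hulls in both periods)
    inference_sites: dict = field(default_factory=dict)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Temporal diversity change summary",
            "=" * 40,
            f"sites: {len(m.paired.site_ids)}   "
            f"species pool: {m.paired.historical.pool_size} -> "
            f"{m.paired.current.pool_size} "
            f"({self.pool_reduction_pct:.1f}% reduction)",
            f"functional space: {m.n_axes} axes, quality "
            f"{self.space_quality:.3f}",
            f"mean richness: {m.paired.historical.richness.mean():.1f} -> "
            f"{m.paired.current.richness.mean():.1f}  "
            f"(paired t = {self.richness_t.statistic:.2f}, "
            f"p = {self.richness_t.p_value:.4f})",
        ]
        for facet, label in (("tax", "taxonomic"), ("fun", "functional")):
            col = f"delta_{facet}_D"
            if col in self.change_table:
                d = self.change_table[col].dropna()
                lines.append(
                    f"{label} dissimilarity change: {d.mean():+.3f} "
                    f"+/- {d.std(ddof=1):.3f}  "
                    f"({100 * (d > 0).mean():.1f}% differentiation)")
        if self.null_result is not None:
            nr = self.null_result
            lines.append(
                f"nestedness null model: observed {nr.observed:.3f} vs "
                f"null {nr.null_mean:.3f} +/- {nr.null_sd:.3f} "
                f"(p = {nr.p_value:.4g}, {nr.n_replicates} reps)")
        for name, res in self.mrm_results.items():
            top = res.p_values.drop("intercept").idxmin()
            lines.append(f"MRM[{name}]: R2 = {res.r_squared:.3f} "
                        f"(p = {res.r_squared_p:.4g}); top predictor: {top} "
                        f"(p = {res.p_values[top]:.4g})")
        for name, g in self.richness_glm.items():
            lines.append(f"GLM[{name}]: R2 = {g.r_squared:.3f}, "
                         f"max VIF = {g.vif.max():.2f}" if g.vif is not None
                         else f"GLM[{name}]: R2 = {g.r_squared:.3f}")
        if self.extirpation_glm is not None:
            g = self.extirpation_glm
            lines.append(f"extirpation GLM (poisson): pseudo-R2 = "
                         f"{g.r_squared:.3f}")
        return "\n".join(lines)

    def save(self, outdir, float_format: str = "%.6g") -> dict:
        """Write the report bundle (CSV tables + JSON results + manifest)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = {}

        def _csv(name: str, df: pd.DataFrame):
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False, float_format=float_format)
            written[name] = path

        space = self.model.space
        coords = space.coordinates.copy()
        coords.insert(0, "species", coords.index)
        _csv("functional_space", coords)
        eig = pd.DataFrame({"axis": np.arange(1, space.eigenvalues.size + 1),
                            "eigenvalue": space.eigenvalues})
        _csv("eigenvalues", eig)
        _csv("beta_historical", self.beta_historical)
        _csv("beta_current", self.beta_current)
        _csv("change_table", self.change_table)
        _csv("table1_summary", self.table1)
        _csv("table2_summary", self.table2)
        _csv("site_change", self.site_change.reset_index(names="site"))
        _csv("extirpation", self.extirpation.reset_index(names="species"))

        def _glm_dict(g):
            return {
                "family": g.family, "r_squared": g.r_squared,
                "converged": g.converged, "nobs": g.nobs,
                "coefficients": g.coefficients.to_dict(),
                "std_errors": g.std_errors.to_dict(),
                "p_values": g.p_values.to_dict(),
                "vif": None if g.vif is None else g.vif.to_dict(),
            }

        results = {
            "space_quality": self.space_quality,
            "pool_volume": self.pool_volume,
            "pool_reduction_pct": self.pool_reduction_pct,
            "mean_pct_richness_decline": self.mean_pct_richness_decline,
            "richness_t": dataclasses.asdict(self.richness_t),
            "richness_congruence_pearson": self.richness_congruence,
            "mantel": {
                name: dataclasses.asdict(res)
                for name, res in self.mantel_results.items()
            },
            "mrm": {
                name: {
                    "coefficients": res.coefficients.to_dict(),
                    "p_values": res.p_values.to_dict(),
                    "r_squared": res.r_squared,
                    "r_squared_p": res.r_squared_p,
                    "nperm": res.nperm, "seed": res.seed,
                } for name, res in self.mrm_results.items()
            },
            "richness_glm": {k: _glm_dict(g)
                             for k, g in self.richness_glm.items()},
            "extirpation_glm": (None if self.extirpation_glm is None
                                else _glm_dict(self.extirpation_glm)),
            "null_model": (None if self.null_result is None
                           else self.null_result.to_dict()),
            "inference_sites": {k: list(v)
                                for k, v in self.inference_sites.items()},
        }
        path = outdir / "results.json"
        with open(path, "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True, default=float)
        written["results"] = path
        manifest = {
            "package_version": _pkg_version,
            "seeds": self.seeds,
            "options": {
                "n_axes": self.model.n_axes,
                "encoding": self.model.encoding,
                "metric": self.model.metric,
                "family": self.model.family,
                "transforms": self.model.transforms,
            },
            "n_sites": len(self.model.paired.site_ids),
            "n_species": len(self.model.paired.species_ids),
            "float_format": float_format,
        }
        path = outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written["manifest"] = path
        return written


class TemporalDiversityModel:
    """Two-period diversity-change analysis of a site x species system.

    Parameters
    ----------
    paired
        Aligned historical/current matrices (see :func:`betashift.io.align_periods`).
    traits
        Categorical trait table covering every species in the pair.
    covariates
        Optional per-site human-impact covariates; without them the
        impact regressions (GLMs on richness change, MRM) are skipped.
    family
        Dissimilarity family, ``"jaccard"`` (default) or ``"sorensen"``.
    """

    def __init__(self, paired: PairedAssemblages, traits: TraitTable,
                 covariates: CovariateTable | None = None, *,
                 n_axes: int = 3, encoding: str = "onehot",
                 metric: str = "euclidean", family: str = "jaccard",
                 transforms: dict | None = None,
                 include_geography: bool = True):
        missing = traitless_species(paired, traits)
        if missing:
            raise CoverageError(
                f"species without trait records: {missing[:10]}"
                f"{'...' if len(missing) > 10 else ''}")
        self.paired = paired
        self.traits = traits.subset(paired.species_ids)
        self.covariates = (covariates.subset(paired.site_ids)
                           if covariates is not None else None)
        self.n_axes = n_axes
        self.encoding = encoding
        self.metric = metric
        self.family = family
        self.transforms = dict(DEFAULT_TRANSFORMS, **(transforms or {}))
        self.include_geography = include_geography
        self.space = None

    @classmethod
    def from_csv(cls, historical, current, traits, covariates=None,
                 exclude_invasive: bool = False, **options
                 ) -> "TemporalDiversityModel":
        """Build the model from the canonical CSV files."""
        hist = read_assemblage_matrix(historical, period_label="historical")
        curr = read_assemblage_matrix(current, period_label="current")
        trait_table = read_trait_table(traits,
                                       exclude_invasive=exclude_invasive)
        if exclude_invasive:
            keep = set(trait_table.species_ids)
            hist.data = hist.data[[s for s in hist.species_ids if s in keep]]
            curr.data = curr.data[[s for s in curr.species_ids if s in keep]]
        paired = align_periods(hist, curr)
        cov = (read_covariate_table(covariates)
               if covariates is not None else None)
        return cls(paired, trait_table, cov, **options)

    @classmethod
    def from_scenario(cls, scenario, **options) -> "TemporalDiversityModel":
        """Build the model from a synthetic scenario (known ground truth)."""
        from .synthetic import generate_dataset
        ds = generate_dataset(scenario)
        return cls(ds.paired, ds.traits, ds.covariates, **options)

    # -- fit ----------------------------------------------------------------

    def fit(self, nperm: int = 10000, null_reps: int = 9999,
            seed: int | None = None,
            include_functional: bool = True,
            run_null_model: bool = True) -> TemporalDiversityResults:
        """Run the full analysis; every stochastic step gets a recorded seed
        derived from ``seed``."""
        ss = np.random.SeedSequence(seed)
        child = ss.generate_state(8) % (2 ** 31)
        seeds = {"root": seed,
                 "mantel": int(child[0]), "mrm_tax": int(child[1]),
                 "mrm_fun": int(child[2]), "null_model": int(child[3])}

        def stage(name, fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # re-label with the failing stage
                raise StageError(name, str(exc)) from exc

        paired = self.paired
        space = stage("functional_space", build_functional_space,
                      self.traits, self.n_axes, self.encoding, self.metric)
        self.space = space
        quality = space_quality(space, self.n_axes)
        pool_volume = stage("functional_space", hull_volume,
                            space.points(paired.species_ids))

        beta_h = stage("diversity", pairwise_beta, paired.historical, space,
                       include_functional, self.family, pool_volume)
        beta_c = stage("diversity", pairwise_beta, paired.current, space,
                       include_functional, self.family, pool_volume)

        changes = stage("temporal_change", build_change_table, beta_h, beta_c)
        t1 = stage("temporal_change", table1_summary, beta_h, beta_c, changes)
        t2 = stage("temporal_change", classify_changes, changes)
        site_change = stage("temporal_change", site_richness_change,
                            paired, space if include_functional else None,
                            pool_volume if include_functional else None)
        ext = stage("temporal_change", extirpation_counts, paired)
        red = pool_reduction(paired.historical.pool_size,
                             paired.current.pool_size)
        t_test = stage("temporal_change", paired_t,
                       paired.historical.richness.to_numpy(),
                       paired.current.richness.to_numpy())
        mean_decline = float(site_change["pct_richness_decline"].mean())

        res = TemporalDiversityResults(
            model=self, space_quality=quality, pool_volume=pool_volume,
            beta_historical=beta_h, beta_current=beta_c,
            change_table=changes, table1=t1, table2=t2,
            site_change=site_change, extirpation=ext,
            pool_reduction_pct=red, mean_pct_richness_decline=mean_decline,
            richness_t=t_test, seeds=seeds,
        )

        # extirpation ~ trait axes (Poisson GLM)
        axes = space.coordinates.loc[ext.index]
        if len(ext) > axes.shape[1] + 1:
            res.extirpation_glm = stage(
                "inference", glm_fit, ext["loss"].to_numpy(), axes, "poisson")

        # Pairwise inference runs on the sites that support each facet:
        # taxonomic change matrices need sites occupied in both periods;
        # functional ones need non-degenerate hulls in both periods.  Pairs
        # of such sites always have defined indices, so restricting the site
        # set (rather than dropping pairs) keeps the permutation null exact.
        sites = paired.site_ids
        rich_ok = [s for s in sites
                   if paired.historical.richness[s] > 0
                   and paired.current.richness[s] > 0]
        fun_ok = []
        if include_functional:
            for s in rich_ok:
                ok = True
                for mat in (paired.historical, paired.current):
                    row = mat.data.loc[s]
                    pts = space.points(row.index[row.astype(bool)])
                    if _hull_or_none(pts) is None:
                        ok = False
                        break
                if ok:
                    fun_ok.append(s)
        facet_sites = {"tax": rich_ok}
        if include_functional:
            facet_sites["fun"] = fun_ok
        res.inference_sites = facet_sites

        def _sub(square: np.ndarray, facet: str) -> np.ndarray:
            idx = [sites.index(s) for s in facet_sites[facet]]
            return square[np.ix_(idx, idx)]

        Dh, delta_sq = {}, {}
        for facet in facet_sites:
            if f"{facet}_D" not in beta_h.columns:
                continue
            if len(facet_sites[facet]) < 5:
                continue  # too few supported sites for matrix inference
            Dh[facet] = _sub(square_from_pairs(beta_h, f"{facet}_D", sites),
                             facet)
            delta_sq[facet] = _sub(
                square_from_pairs(changes.fillna({f"delta_{facet}_D": 0.0}),
                                  f"delta_{facet}_D", sites), facet)

        # Mantel suite (facet congruence, nestedness driver, history, loss)
        mantels = {}
        if "tax" in delta_sq and "fun" in delta_sq:
            idx = [sites.index(s) for s in facet_sites["fun"]]
            tax_on_fun = square_from_pairs(
                changes, "delta_tax_D", sites)[np.ix_(idx, idx)]
            mantels["delta_tax_vs_delta_fun"] = stage(
                "inference", mantel, tax_on_fun, delta_sq["fun"],
                "spearman", nperm, seeds["mantel"])
        loss_mat = pair_species_loss_matrix(paired)
        for facet in delta_sq:
            mantels[f"delta_{facet}_vs_delta_nestedness_contribution"] = (
                stage("inference", mantel, delta_sq[facet],
                      _sub(square_from_pairs(
                          changes.fillna({
                              f"delta_{facet}_nestedness_contribution": 0.0}),
                          f"delta_{facet}_nestedness_contribution", sites),
                          facet),
                      "spearman", nperm, seeds["mantel"]))
            mantels[f"delta_{facet}_vs_historical"] = stage(
                "inference", mantel, delta_sq[facet], Dh[facet],
                "spearman", nperm, seeds["mantel"])
            mantels[f"delta_{facet}_vs_species_loss"] = stage(
                "inference", mantel, delta_sq[facet], _sub(loss_mat, facet),
                "spearman", nperm, seeds["mantel"])
        res.mantel_results = mantels

        if "delta_fric" in site_change.columns:
            res.richness_congruence = float(np.corrcoef(
                site_change["delta_richness"], site_change["delta_fric"])[0, 1])

        # impact regressions need covariates
        if self.covariates is not None:
            predictors = stage("inference", impact_change_predictors,
                               self.covariates, self.transforms)
            y_tax = site_change["delta_richness"].to_numpy(dtype=float)
            res.richness_glm["taxonomic"] = stage(
                "inference", glm_fit, y_tax, predictors, "gaussian")
            if "delta_fric" in site_change.columns:
                res.richness_glm["functional"] = stage(
                    "inference", glm_fit,
                    site_change["delta_fric"].to_numpy(), predictors,
                    "gaussian")
            pred_mats = {c: np.abs(predictors[c].to_numpy()[:, None]
                                   - predictors[c].to_numpy()[None, :])
                         for c in predictors.columns}
            if self.include_geography:
                coords = self.covariates.coordinates
                pred_mats["geography"] = great_circle_matrix(
                    coords["lon"], coords["lat"])
            for facet in delta_sq:
                res.mrm_results[facet] = stage(
                    "inference", mrm, delta_sq[facet],
                    {name: _sub(M, facet) for name, M in pred_mats.items()},
                    nperm, seeds[f"mrm_{facet}"])

        if run_null_model:
            res.null_result = stage(
                "null_model", null_nestedness_test, paired, null_reps,
                seeds["null_model"], None, "uniform", self.family)
        return res
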