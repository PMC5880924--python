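"""Reading, validation and alignment of assemblage, trait and covariate tables.

The canonical on-disk format for a site x species occurrence matrix is a wide
CSV: first column the site id, remaining columns species ids, cells 0/1.  A
long occurrence table (columns ``site, species[, period]``) is accepted for
convenience; duplicate records collapse with OR semantics (any record means
present), mirroring the pooling of repeat surveys of the same site.

Trait tables are one row per species with one column per categorical trait;
levels are validated against a declared vocabulary (case-insensitively, with
spaces/hyphens normalized to underscores).  Covariate tables are long with a
``period`` column and carry the four human-impact descriptors plus site
centroid coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    FormatError,
    ValidationError,
    VocabularyError,
)

__all__ = [
    "DEFAULT_TRAIT_VOCABULARY",
    "AssemblageMatrix",
    "TraitTable",
    "CovariateTable",
    "PairedAssemblages",
    "AlignmentReport",
    "read_assemblage_matrix",
    "write_assemblage_matrix",
    "read_trait_table",
    "read_covariate_table",
    "align_periods",
    "traitless_species",
]

#: Five categorical macrophyte traits with their allowed levels (level counts
#: 4, 2, 4, 4, 2 — sixteen levels in total).
DEFAULT_TRAIT_VOCABULARY: dict[str, tuple[str, ...]] = {
    "life_form": ("submerged", "floating_leaved", "emergent", "free_floating"),
    "life_cycle": ("annual", "perennial"),
    "morphology": ("turion", "stem", "rosette", "leafy"),
    "dispersal_range": ("local", "regional", "asian_endemic", "cosmopolitan"),
    "sexual_propagation": ("monoecism", "dioecy"),
}

COVARIATE_COLUMNS = ("area_km2", "tp_mg_l", "secchi_cm", "catch_t_km2")
PERIODS = ("historical", "current")


def _normalize_level(value) -> str:
    return str(value).strip().lower().replace("-", "_").replace(" ", "_")


@dataclass
class AssemblageMatrix:
    """Binary site x species occurrence matrix for one survey period.

    Parameters
    ----------
    data
        Sites in rows, species in columns, entries 0/1.
    period_label
        Free-text label for the survey period (e.g. ``"historical"``).
    """

    data: pd.DataFrame
    period_label: str = ""

    def __post_init__(self):
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate site ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate species ids: {dups}")
        values = df.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            bad = np.unique(values[~np.isin(values, (0, 1))])
            raise ValidationError(f"non-binary occurrence entries: {bad!r}")
        self.data = df.astype(np.int8)
        empty = self.empty_sites
        if empty:
            warnings.warn(
                f"{self.period_label or 'assemblage'}: sites with no species "
                f"(richness 0): {empty}",
                stacklevel=3,
            )

    @property
    def site_ids(self) -> list:
        return list(self.data.index)

    @property
    def species_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def empty_sites(self) -> list:
        sums = self.data.sum(axis=1)
        return list(sums.index[sums == 0])

    @property
    def richness(self) -> pd.Series:
        """Per-site species count."""
        return self.data.sum(axis=1).astype(int)

    @property
    def occupancy(self) -> pd.Series:
        """Per-species site count."""
        return self.data.sum(axis=0).astype(int)

    @property
    def pool_size(self) -> int:
        """Number of species present in at least one site."""
        return int((self.data.sum(axis=0) > 0).sum())


@dataclass
class TraitTable:
    """Species x categorical-trait table with a declared level vocabulary."""

    data: pd.DataFrame
    vocabulary: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_VOCABULARY)
    )
    invasive: pd.Series | None = None

    def __post_init__(self):
        df = self.data
        if df.index.has_duplicates:
            raise ValidationError("duplicate species ids in trait table")
        missing_traits = [t for t in self.vocabulary if t not in df.columns]
        if missing_traits:
            raise ValidationError(f"trait columns missing: {missing_traits}")
        df = df[list(self.vocabulary)].copy()
        for trait, levels in self.vocabulary.items():
            col = df[trait]
            if col.isna().any():
                bad = list(df.index[col.isna()])
                raise ValidationError(f"missing {trait} for species {bad}")
            norm = col.map(_normalize_level)
            unknown = sorted(set(norm) - set(levels))
            if unknown:
                raise VocabularyError(
                    f"unknown {trait} level(s) {unknown}; allowed: {levels}"
                )
            df[trait] = norm
        self.data = df

    @property
    def species_ids(self) -> list:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.vocabulary)

    def subset(self, species_ids) -> "TraitTable":
        missing = [s for s in species_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"species without trait records: {missing}")
        return TraitTable(self.data.loc[list(species_ids)], dict(self.vocabulary))


@dataclass
class CovariateTable:
    """Per-site, per-period human-impact covariates plus site centroids.

    ``data`` is indexed by (site, period) with the four impact columns;
    ``coordinates`` is indexed by site with ``lon``/``lat`` in decimal degrees.
    """

    data: pd.DataFrame
    coordinates: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"covariate columns missing: {missing}")
        df = df[list(COVARIATE_COLUMNS)].astype(float)
        if (df.to_numpy() <= 0).any():
            raise ValidationError("covariates must be strictly positive")
        sites = df.index.get_level_values(0).unique()
        for site in sites:
            have = set(df.loc[site].index)
            if not set(PERIODS) <= have:
                raise ValidationError(f"site {site!r} lacks both periods: {have}")
        self.data = df
        coords = self.coordinates
        if not {"lon", "lat"} <= set(coords.columns):
            raise ValidationError("coordinates need lon and lat columns")
        self.coordinates = coords[["lon", "lat"]].astype(float)

    @property
    def site_ids(self) -> list:
        return list(self.coordinates.index)

    def period(self, period: str) -> pd.DataFrame:
        """Covariate values for one period, indexed by site."""
        return self.data.xs(period, level=1)

    def subset(self, site_ids) -> "CovariateTable":
        idx = [(s, p) for s in site_ids for p in PERIODS]
        return CovariateTable(
            self.data.loc[idx], self.coordinates.loc[list(site_ids)]
        )


@dataclass
class AlignmentReport:
    """Sites/species dropped while pairing the two period matrices."""

    dropped_sites_historical: list
    dropped_sites_current: list
    dropped_species: list


@dataclass
class PairedAssemblages:
    """Historical and current matrices on a shared site order and the
    union species axis (zero-filled where a species is absent in a period)."""

    historical: AssemblageMatrix
    current: AssemblageMatrix
    report: AlignmentReport = field(
        default_factory=lambda: AlignmentReport([], [], [])
    )

    def __post_init__(self):
        if self.historical.site_ids != self.current.site_ids:
            raise AlignmentError("paired matrices must share site order")
        if self.historical.species_ids != self.current.species_ids:
            raise AlignmentError("paired matrices must share the species axis")

    @property
    def site_ids(self) -> list:
        return self.historical.site_ids

    @property
    def species_ids(self) -> list:
        return self.historical.species_ids


def read_assemblage_matrix(source, dialect: str = "wide",
                           period_label: str = "") -> AssemblageMatrix:
    """Read a site x species presence/absence matrix.

    Parameters
    ----------
    source
        Path or file-like handle of a delimited text file.
    dialect
        ``"wide"`` (canonical: site rows, species columns, 0/1 cells) or
        ``"long"`` (columns ``site, species``; duplicates collapse to 1).
    """
    if dialect == "wide":
        df = pd.read_csv(source, index_col=0)
        values = df.to_numpy()
        try:
            numeric = values.astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric occurrence cell: {exc}") from None
        if numeric.size and not np.isin(numeric, (0.0, 1.0)).all():
            bad = np.unique(numeric[~np.isin(numeric, (0.0, 1.0))])
            raise FormatError(f"wide matrix cells must be 0/1, found {bad}")
        binary = pd.DataFrame(
            numeric.astype(np.int8), index=df.index, columns=df.columns
        )
        binary.index.name = None
        binary.columns.name = None
        return AssemblageMatrix(binary, period_label)
    if dialect == "long":
        df = pd.read_csv(source)
        needed = {"site", "species"}
        if not needed <= set(df.columns):
            raise FormatError(f"long table needs columns {sorted(needed)}")
        wide = (
            pd.crosstab(df["site"], df["species"]).clip(upper=1).astype(np.int8)
        )
        wide.index.name = None
        wide.columns.name = None
        return AssemblageMatrix(wide, period_label)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_assemblage_matrix(matrix: AssemblageMatrix, path) -> None:
    """Write the canonical wide CSV (round-trips bit-exactly)."""
    matrix.data.to_csv(path, index_label="site")


def read_trait_table(source, vocabulary=None,
                     exclude_invasive: bool = False) -> TraitTable:
    """Read a species x trait CSV and validate against the vocabulary.

    An optional boolean ``invasive`` column is honoured: with
    ``exclude_invasive=True``, flagged species are dropped before analysis
    (non-native species are excluded from the study design); default keeps
    them and records the flag.
    """
    vocabulary = dict(vocabulary or DEFAULT_TRAIT_VOCABULARY)
    df = pd.read_csv(source, index_col=0)
    invasive = None
    if "invasive" in df.columns:
        invasive = df["invasive"].astype(bool)
        df = df.drop(columns=["invasive"])
        if exclude_invasive:
            df = df.loc[~invasive]
            invasive = invasive.loc[df.index]
    return TraitTable(df, vocabulary, invasive=invasive)


def read_covariate_table(source) -> CovariateTable:
    """Read the long covariate CSV (site, period, impacts, lon, lat)."""
    df = pd.read_csv(source)
    needed = {"site", "period", *COVARIATE_COLUMNS, "lon", "lat"}
    if not needed <= set(df.columns):
        raise FormatError(f"covariate table needs columns {sorted(needed)}")
    df["period"] = df["period"].map(_normalize_level)
    unknown = set(df["period"]) - set(PERIODS)
    if unknown:
        raise ValidationError(f"unknown period labels: {sorted(unknown)}")
    coords = (
        df[df["period"] == "historical"]
        .set_index("site")[["lon", "lat"]]
    )
    data = df.set_index(["site", "period"])[list(COVARIATE_COLUMNS)]
    return CovariateTable(data, coords)


def align_periods(hist: AssemblageMatrix,
                  curr: AssemblageMatrix) -> PairedAssemblages:
    """Pair the two period matrices on common sites and the union species axis.

    Sites are intersected (kept in historical order); species become the
    union of both periods, zero-filled where absent, with species absent from
    both periods (possible after upstream filtering) dropped silently.
    Dropped sites are listed in the report.  Idempotent on aligned inputs.
    """
    common = [s for s in hist.site_ids if s in set(curr.site_ids)]
    if not common:
        raise AlignmentError("no site shared between the two periods")
    union = list(hist.species_ids)
    seen = set(union)
    union += [s for s in curr.species_ids if s not in seen]

    def _expand(mat: AssemblageMatrix) -> pd.DataFrame:
        return mat.data.reindex(index=common, columns=union, fill_value=0)

    h, c = _expand(hist), _expand(curr)
    present = (h.sum(axis=0) + c.sum(axis=0)) > 0
    dropped_species = list(h.columns[~present])
    h, c = h.loc[:, present], c.loc[:, present]
    report = AlignmentReport(
        dropped_sites_historical=[s for s in hist.site_ids if s not in set(common)],
        dropped_sites_current=[s for s in curr.site_ids if s not in set(common)],
        dropped_species=dropped_species,
    )
    with warnings.catch_warnings():
        # empty-in-one-period sites are retained by design; flag once here
        warnings.simplefilter("ignore")
        pair = PairedAssemblages(
            AssemblageMatrix(h, hist.period_label or "historical"),
            AssemblageMatrix(c, curr.period_label or "current"),
            report,
        )
    empties = sorted(set(pair.historical.empty_sites) | set(pair.current.empty_sites))
    if empties:
        warnings.warn(f"sites empty in at least one period: {empties}", stacklevel=2)
    return pair


def traitless_species(paired: PairedAssemblages, traits: TraitTable) -> list:
    """Species of the paired matrices that have no trait record."""
    have = set(traits.species_ids)
    return [s for s in paired.species_ids if s not in have]
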