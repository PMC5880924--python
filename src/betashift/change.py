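"""Temporal change between survey periods: per-pair deltas of the diversity
indices, homogenization/differentiation classification, summary tables, and
per-species extirpation counts.

Every change index is ``current - historical``, so a positive value means the
index increased over time: a positive change in pairwise dissimilarity is
biotic *differentiation*, a negative (or zero) change *homogenization*.
Pairs with a zero delta are binned with homogenization ("no change or
homogenization") and their count is reported separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diversity import hull_volume
from .exceptions import BetashiftError
from .functional_space import FunctionalSpace
from .io import PairedAssemblages

__all__ = [
    "change_index",
    "build_change_table",
    "site_richness_change",
    "classify_changes",
    "extirpation_counts",
    "pool_reduction",
    "table1_summary",
    "pair_species_loss_matrix",
]

#: Pairwise indices differenced between periods (both facets).
CHANGE_COLUMNS = [
    "richness_ratio", "D", "Dtu", "Dne",
    "turnover_contribution", "nestedness_contribution",
]


def change_index(historical_value, current_value):
    """Signed temporal change, ``current - historical`` (NaN propagates)."""
    return current_value - historical_value


def build_change_table(beta_hist: pd.DataFrame,
                       beta_curr: pd.DataFrame) -> pd.DataFrame:
    """Per-pair change table from two period beta tables.

    Emits ``delta_*`` columns for each facet/index, plus classification
    labels: ``tax_class`` / ``fun_class`` in {homogenization,
    differentiation} (zero change grouped with homogenization) and a
    ``cross_class`` TH/TD label combining the two facets.
    """
    keys = ["site_i", "site_j"]
    h = beta_hist.set_index(keys)
    c = beta_curr.set_index(keys)
    if not h.index.equals(c.index):
        raise BetashiftError("period beta tables cover different pairs")
    out = pd.DataFrame(index=h.index)
    for facet in ("tax", "fun"):
        cols = {
            "richness_ratio": ("richness_ratio" if facet == "tax"
                               else "fun_richness_ratio"),
            "D": f"{facet}_D", "Dtu": f"{facet}_Dtu", "Dne": f"{facet}_Dne",
            "turnover_contribution": f"{facet}_turnover_contribution",
            "nestedness_contribution": f"{facet}_nestedness_contribution",
        }
        for name, col in cols.items():
            if col in h.columns:
                out[f"delta_{facet}_{name}"] = change_index(h[col], c[col])
    out["tax_class"] = np.where(out["delta_tax_D"] > 0,
                                "differentiation", "homogenization")
    if "delta_fun_D" in out.columns:
        out["fun_class"] = np.where(
            out["delta_fun_D"].isna(), "missing",
            np.where(out["delta_fun_D"] > 0, "differentiation",
                     "homogenization"),
        )
        out["cross_class"] = np.where(
            out["fun_class"] == "missing", "missing",
            np.where(out["tax_class"] == "homogenization", "TH", "TD"),
        )
    return out.reset_index()


def site_richness_change(paired: PairedAssemblages,
                         space: FunctionalSpace | None = None,
                         pool_volume: float | None = None) -> pd.DataFrame:
    """Per-site change in taxonomic richness and (optionally) FRic.

    FRic is standardized by the combined two-period pool hull volume so the
    two periods are on one scale; percent richness decline per site is also
    emitted (NaN where historical richness is zero).
    """
    hr = paired.historical.richness
    cr = paired.current.richness
    out = pd.DataFrame({
        "richness_historical": hr, "richness_current": cr,
        "delta_richness": cr - hr,
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pct_richness_decline"] = np.where(
            hr > 0, 100.0 * (hr - cr) / hr, np.nan
        )
    if space is not None:
        if pool_volume is None:
            pool_volume = hull_volume(space.points(paired.species_ids))
        if pool_volume <= 0:
            raise BetashiftError("degenerate species-pool hull")
        fric = {}
        for label, mat in (("historical", paired.historical),
                           ("current", paired.current)):
            vols = []
            for site in mat.site_ids:
                row = mat.data.loc[site]
                vols.append(hull_volume(
                    space.points(row.index[row.astype(bool)])))
            fric[label] = np.asarray(vols) / pool_volume
        out["fric_historical"] = fric["historical"]
        out["fric_current"] = fric["current"]
        out["delta_fric"] = out["fric_current"] - out["fric_historical"]
    return out


def _cell(deltas: np.ndarray, n_total: int) -> dict:
    n = deltas.size
    return {
        "n_pairs": int(n),
        "percent": 100.0 * n / n_total if n_total else np.nan,
        "mean": float(np.mean(deltas)) if n else np.nan,
        "sd": float(np.std(deltas, ddof=1)) if n > 1 else np.nan,
    }


def classify_changes(changes: pd.DataFrame) -> pd.DataFrame:
    """Frequency and intensity summary of the change table.

    For each facet: percentage of pairs showing homogenization (delta <= 0)
    vs differentiation (delta > 0) of total dissimilarity, and increases vs
    decreases of the turnover and nestedness contributions, each cell with
    its mean +/- SD of deltas.  Functional cells are additionally split by
    the taxonomic class (TH/TD).  Percentages are of all retained
    (non-missing) pairs per facet, so cross-class cells add up to their
    facet total.
    """
    if changes.empty:
        raise BetashiftError("empty change table")
    rows = []
    for facet in ("tax", "fun"):
        dcol = f"delta_{facet}_D"
        if dcol not in changes.columns:
            continue
        sub = changes.loc[changes[dcol].notna()]
        n_total = len(sub)
        specs = [
            ("dissimilarity", dcol, "differentiation", sub[dcol] > 0),
            ("dissimilarity", dcol, "homogenization", sub[dcol] <= 0),
        ]
        for comp in ("turnover", "nestedness"):
            ccol = f"delta_{facet}_{comp}_contribution"
            ok = sub[ccol].notna()
            specs.append((f"{comp}_contribution", ccol, "increase",
                          ok & (sub[ccol] > 0)))
            specs.append((f"{comp}_contribution", ccol, "decrease",
                          ok & (sub[ccol] < 0)))
        for index_name, col, direction, mask in specs:
            base = {"facet": facet, "index": index_name,
                    "direction": direction, "tax_class": "all"}
            rows.append(base | _cell(sub.loc[mask, col].to_numpy(), n_total))
            if facet == "fun":
                for tclass, label in (("homogenization", "TH"),
                                      ("differentiation", "TD")):
                    m2 = mask & (sub["tax_class"] == tclass)
                    rows.append(
                        {"facet": facet, "index": index_name,
                         "direction": direction, "tax_class": label}
                        | _cell(sub.loc[m2, col].to_numpy(), n_total)
                    )
        rows.append({"facet": facet, "index": "dissimilarity",
                     "direction": "exact_zero", "tax_class": "all"}
                    | _cell(sub.loc[sub[dcol] == 0, dcol].to_numpy(), n_total))
    return pd.DataFrame(rows)


def extirpation_counts(paired: PairedAssemblages) -> pd.DataFrame:
    """Per-species occupancy bookkeeping between periods.

    ``loss`` counts sites occupied historically but not currently (the
    extirpation frequency modelled against trait axes); ``colonization`` the
    reverse, counted separately and never subtracted.
    """
    H = paired.historical.data
    C = paired.current.data
    return pd.DataFrame({
        "historical_occupancy": H.sum(axis=0).astype(int),
        "current_occupancy": C.sum(axis=0).astype(int),
        "loss": ((H == 1) & (C == 0)).sum(axis=0).astype(int),
        "colonization": ((H == 0) & (C == 1)).sum(axis=0).astype(int),
    })


def pool_reduction(hist_pool_size: int, curr_pool_size: int) -> float:
    """Percent reduction of the regional species pool between periods."""
    if hist_pool_size <= 0:
        raise ZeroDivisionError("historical pool size must be positive")
    return 100.0 * (hist_pool_size - curr_pool_size) / hist_pool_size


def pair_species_loss_matrix(paired: PairedAssemblages,
                             mode: str = "union") -> np.ndarray:
    """Square matrix of species lost per site pair.

    ``mode="union"`` (default): species present in the union of the pair's
    two historical assemblages but absent from the union of its current
    assemblages.  ``mode="site_sum"``: sum of the two sites' individual
    losses.
    """
    H = paired.historical.values.astype(bool)
    C = paired.current.values.astype(bool)
    n = H.shape[0]
    if mode == "site_sum":
        per_site = (H & ~C).sum(axis=1).astype(float)
        out = per_site[:, None] + per_site[None, :]
        np.fill_diagonal(out, 0.0)
        return out
    if mode != "union":
        raise ValueError(f"unknown mode {mode!r}")
    out = np.zeros((n, n))
    for i in range(n):
        hu = H[i][None, :] | H
        cu = C[i][None, :] | C
        out[i] = (hu & ~cu).sum(axis=1)
    np.fill_diagonal(out, 0.0)
    return out


def _mean_sd_range(values: pd.Series) -> dict:
    v = values.dropna().to_numpy()
    return {
        "mean": float(v.mean()) if v.size else np.nan,
        "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
        "min": float(v.min()) if v.size else np.nan,
        "max": float(v.max()) if v.size else np.nan,
        "n_pairs": int(v.size),
    }


def table1_summary(beta_hist: pd.DataFrame, beta_curr: pd.DataFrame,
                   changes: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD (and ranges) of richness ratio, dissimilarity and the
    turnover/nestedness contributions: historical, current, and change rows
    for both facets."""
    index_cols = {
        "richness_ratio": ("richness_ratio", "fun_richness_ratio"),
        "dissimilarity": ("tax_D", "fun_D"),
        "turnover_contribution": ("tax_turnover_contribution",
                                  "fun_turnover_contribution"),
        "nestedness_contribution": ("tax_nestedness_contribution",
                                    "fun_nestedness_contribution"),
    }
    delta_cols = {
        "richness_ratio": "richness_ratio",
        "dissimilarity": "D",
        "turnover_contribution": "turnover_contribution",
        "nestedness_contribution": "nestedness_contribution",
    }
    rows = []
    for index_name, (tax_col, fun_col) in index_cols.items():
        for facet, col in (("tax", tax_col), ("fun", fun_col)):
            for period, table in (("historical", beta_hist),
                                  ("current", beta_curr)):
                if col in table.columns:
                    rows.append({"index": index_name, "facet": facet,
                                 "period": period}
                                | _mean_sd_range(table[col]))
            dcol = f"delta_{facet}_{delta_cols[index_name]}"
            if dcol in changes.columns:
                rows.append({"index": index_name, "facet": facet,
                             "period": "change"}
                            | _mean_sd_range(changes[dcol]))
    return pd.DataFrame(rows)
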