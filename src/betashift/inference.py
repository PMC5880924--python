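"""Permutation and regression inference.

Mantel tests and multiple regression on distance matrices (MRM) share one
permutation core: the null hypothesis of no matrix association is simulated
by relabelling the objects of one matrix (simultaneous row/column
permutation) and recomputing the statistic on lower-triangle entries.
Permutation p-values are two-sided with the +1 correction,

    p = (#{permutations with |t*| >= |t|} + 1) / (nperm + 1),

or exact by full enumeration of all n! relabelings on small problems
(``nperm="exact"``), where p = #{|t*| >= |t|} / n! including the identity.

GLMs (Gaussian and Poisson/log) are fitted through statsmodels; VIFs come
from auxiliary OLS fits.  Predictor vectors are transformed (log or square
root) and min-max standardized to [0, 1] before modelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import (
    DegenerateInputError,
    RankDeficiencyError,
    StandardizationError,
)

__all__ = [
    "MantelResult",
    "MRMResult",
    "GLMResult",
    "PairedTResult",
    "transform_standardize",
    "relative_change",
    "pairwise_change_matrix",
    "great_circle_matrix",
    "mantel",
    "mrm",
    "glm_fit",
    "vif",
    "paired_t",
]

_PERM_CHUNK = 2000
_FP_TOL = 1e-12


# ---------------------------------------------------------------------------
# predictor construction

def transform_standardize(values, transform: str = "none") -> np.ndarray:
    """Apply log/sqrt transform then min-max rescale to [0, 1].

    Raises on a constant vector (standardization undefined) and on
    nonpositive values with the log transform.
    """
    v = np.asarray(values, dtype=float)
    if transform == "log":
        if (v <= 0).any():
            raise ValueError("log transform requires strictly positive values")
        v = np.log(v)
    elif transform == "sqrt":
        if (v < 0).any():
            raise ValueError("sqrt transform requires nonnegative values")
        v = np.sqrt(v)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    span = v.max() - v.min()
    if span == 0 or not np.isfinite(span):
        raise StandardizationError("constant vector cannot be standardized")
    return (v - v.min()) / span


def relative_change(hist_value, curr_value):
    """Relative change between periods, ``(curr - hist) / hist``."""
    hist = np.asarray(hist_value, dtype=float)
    curr = np.asarray(curr_value, dtype=float)
    if np.any(hist == 0):
        raise ZeroDivisionError("historical value of zero in relative change")
    out = (curr - hist) / hist
    return float(out) if out.ndim == 0 else out


def pairwise_change_matrix(values, mode: str = "abs_diff") -> np.ndarray:
    """Pairwise predictor matrix from a per-site vector.

    ``abs_diff`` (default): ``|v_i - v_j|``; ``mean``: ``(v_i + v_j)/2``.
    """
    v = np.asarray(values, dtype=float)
    if mode == "abs_diff":
        out = np.abs(v[:, None] - v[None, :])
    elif mode == "mean":
        out = (v[:, None] + v[None, :]) / 2.0
        np.fill_diagonal(out, 0.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def great_circle_matrix(lon, lat, radius_km: float = 6371.0) -> np.ndarray:
    """Haversine great-circle distance matrix (km) between site centroids."""
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    dlon = lon[:, None] - lon[None, :]
    dlat = lat[:, None] - lat[None, :]
    h = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
    return 2.0 * radius_km * np.arcsin(np.minimum(np.sqrt(h), 1.0))


# ---------------------------------------------------------------------------
# permutation core

def _as_square(M) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(M, M.T, equal_nan=True):
        raise ValueError("matrix must be symmetric")
    return M


def _tril(M: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(M.shape[0], k=-1)
    return M[i, j]


def _rank_matrix(M: np.ndarray) -> np.ndarray:
    """Replace lower-triangle entries by their ranks (symmetric rebuild).

    Relabeling sites permutes the multiset of pair values, so ranking
    commutes with the permutation null and Spearman reduces to Pearson on
    ranked matrices.
    """
    n = M.shape[0]
    i, j = np.tril_indices(n, k=-1)
    ranks = stats.rankdata(M[i, j])
    R = np.zeros_like(M)
    R[i, j] = ranks
    R[j, i] = ranks
    return R


def _permuted_triangles(M: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """(k, n_pairs) array of lower triangles of M under k relabelings."""
    i, j = np.tril_indices(M.shape[0], k=-1)
    return M[perms[:, i], perms[:, j]]


def _iter_perm_blocks(n: int, nperm, rng: np.random.Generator):
    """Yield blocks of permutation index arrays (exact or sampled)."""
    if nperm == "exact":
        block = []
        for p in iter_permutations(range(n)):
            block.append(p)
            if len(block) == _PERM_CHUNK:
                yield np.asarray(block)
                block = []
        if block:
            yield np.asarray(block)
        return
    remaining = int(nperm)
    while remaining > 0:
        k = min(remaining, _PERM_CHUNK)
        yield rng.permuted(
            np.broadcast_to(np.arange(n), (k, n)), axis=1
        )
        remaining -= k


def _perm_total(n: int, nperm) -> int:
    return math.factorial(n) if nperm == "exact" else int(nperm)


@dataclass(frozen=True)
class MantelResult:
    """Mantel correlation between two site-labelled matrices."""

    correlation: float
    p_value: float
    nperm: int
    method: str
    exact: bool
    seed: int | None


def mantel(A, B, method: str = "pearson", nperm: int | str = 10000,
           seed: int | None = None) -> MantelResult:
    """Mantel permutation test between two square symmetric matrices.

    The correlation is computed over lower-triangle entries; the null is
    simulated by simultaneous row/column permutation of ``B``.  Set
    ``nperm="exact"`` to enumerate all n! relabelings.
    """
    A = _as_square(A)
    B = _as_square(B)
    if A.shape != B.shape:
        raise ValueError("matrices must have matching shape")
    if method == "spearman":
        A, B = _rank_matrix(A), _rank_matrix(B)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    a = _tril(A)
    b = _tril(B)
    if np.std(a) == 0 or np.std(b) == 0:
        raise DegenerateInputError("constant lower triangle: r undefined")
    az = (a - a.mean()) / a.std()
    r_obs = float(az @ (b - b.mean()) / b.std() / a.size)
    rng = np.random.default_rng(seed)
    exceed = 0
    for perms in _iter_perm_blocks(A.shape[0], nperm, rng):
        tri = _permuted_triangles(B, perms)
        tri = (tri - tri.mean(axis=1, keepdims=True))
        sd = tri.std(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_perm = (tri @ az) / sd / a.size
        r_perm = np.nan_to_num(r_perm)
        exceed += int((np.abs(r_perm) >= np.abs(r_obs) - _FP_TOL).sum())
    total = _perm_total(A.shape[0], nperm)
    if nperm == "exact":
        p = exceed / total
    else:
        p = (exceed + 1) / (total + 1)
    return MantelResult(correlation=r_obs, p_value=float(p), nperm=total,
                        method=method, exact=nperm == "exact", seed=seed)


@dataclass(frozen=True)
class MRMResult:
    """Multiple regression on distance matrices.

    ``coefficients``/``p_values`` are indexed by predictor name (plus
    ``intercept``); p-values come from re-estimating the coefficients under
    row/column permutations of the response matrix.
    """

    coefficients: pd.Series
    r_squared: float
    p_values: pd.Series
    r_squared_p: float
    nperm: int
    exact: bool
    seed: int | None


def mrm(response, predictors: dict, nperm: int | str = 10000,
        seed: int | None = None) -> MRMResult:
    """MRM: OLS of the response matrix's lower triangle on predictor
    triangles, with permutation p-values.

    ``predictors`` maps name -> square symmetric matrix on the same sites.
    """
    Y = _as_square(response)
    names = list(predictors)
    mats = [_as_square(predictors[k]) for k in names]
    for M in mats:
        if M.shape != Y.shape:
            raise ValueError("predictor shape mismatch")
    y = _tril(Y)
    X = np.column_stack([np.ones_like(y)] + [_tril(M) for M in mats])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError("collinear predictor triangles")
    pinv = np.linalg.pinv(X)
    beta = pinv @ y
    resid = y - X @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise DegenerateInputError("constant response triangle")
    r2_obs = 1.0 - float((resid ** 2).sum()) / tss

    rng = np.random.default_rng(seed)
    n = Y.shape[0]
    exceed = np.zeros(X.shape[1])
    exceed_r2 = 0
    for perms in _iter_perm_blocks(n, nperm, rng):
        y_perm = _permuted_triangles(Y, perms)  # (k, n_pairs)
        beta_perm = y_perm @ pinv.T  # (k, p+1)
        fitted = beta_perm @ X.T
        rss = ((y_perm - fitted) ** 2).sum(axis=1)
        tss_perm = ((y_perm - y_perm.mean(axis=1, keepdims=True)) ** 2
                    ).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2_perm = 1.0 - rss / tss_perm
        exceed += (np.abs(beta_perm) >= np.abs(beta) - _FP_TOL).sum(axis=0)
        exceed_r2 += int((r2_perm >= r2_obs - _FP_TOL).sum())
    total = _perm_total(n, nperm)
    if nperm == "exact":
        pvals = exceed / total
        p_r2 = exceed_r2 / total
    else:
        pvals = (exceed + 1) / (total + 1)
        p_r2 = (exceed_r2 + 1) / (total + 1)
    idx = ["intercept"] + names
    return MRMResult(
        coefficients=pd.Series(beta, index=idx),
        r_squared=r2_obs,
        p_values=pd.Series(pvals, index=idx),
        r_squared_p=float(p_r2),
        nperm=total, exact=nperm == "exact", seed=seed,
    )


# ---------------------------------------------------------------------------
# GLMs

@dataclass
class GLMResult:
    """Fitted GLM: coefficients, SEs, p-values, fit quality and VIFs."""

    family: str
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    r_squared: float
    converged: bool
    nobs: int
    vif: pd.Series | None = field(default=None)

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "coef": self.coefficients,
            "se": self.std_errors,
            "p": self.p_values,
        })
        if self.vif is not None:
            out["vif"] = self.vif.reindex(out.index)
        return out


def glm_fit(y, X: pd.DataFrame, family: str = "gaussian",
            offset=None) -> GLMResult:
    """Fit a GLM by IRLS (Gaussian/identity or Poisson/log).

    ``X`` is the predictor frame *without* a constant (added here).  Gaussian
    fits report ordinary R^2; Poisson fits a deviance-based pseudo-R^2
    (1 - deviance/null deviance).  VIFs are attached when there are >= 2
    predictors.  Non-convergence is flagged, not raised.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any() or X.isna().any().any():
        raise ValueError("missing values in GLM inputs")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("need n > number of parameters")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise RankDeficiencyError("rank-deficient GLM design")
    fam = {"gaussian": sm.families.Gaussian(),
           "poisson": sm.families.Poisson()}.get(family)
    if fam is None:
        raise ValueError(f"unknown family {family!r}")
    model = sm.GLM(y, design, family=fam, offset=offset)
    res = model.fit(maxiter=100, tol=1e-8)
    converged = bool(getattr(res, "converged", True))
    if np.abs(res.params).max() > 1e8 or not np.isfinite(res.params).all():
        converged = False  # coefficient drift (separation analog)
    if family == "gaussian":
        resid = y - res.fittedvalues
        tss = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - float((resid ** 2).sum()) / tss if tss > 0 else np.nan
    else:
        r2 = (1.0 - res.deviance / res.null_deviance
              if res.null_deviance > 0 else np.nan)
    vifs = vif(X) if X.shape[1] >= 2 else None
    return GLMResult(
        family=family,
        coefficients=pd.Series(res.params, index=design.columns),
        std_errors=pd.Series(res.bse, index=design.columns),
        p_values=pd.Series(res.pvalues, index=design.columns),
        r_squared=float(r2),
        converged=converged,
        nobs=len(y),
        vif=vifs,
    )


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, 1/(1 - R^2_j) from auxiliary OLS fits.

    Perfect collinearity yields ``inf`` for the affected predictors.
    """
    X = pd.DataFrame(X).astype(float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]), has_constant="add")
        r2 = sm.OLS(X[col], others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass(frozen=True)
class PairedTResult:
    statistic: float
    df: int
    p_value: float
    mean_difference: float


def paired_t(x, y) -> PairedTResult:
    """Paired t-test: t = mean(d) / (sd(d)/sqrt(n)), d = x - y, df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero-variance differences: t undefined")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTResult(statistic=float(t), df=n - 1, p_value=float(p),
                         mean_difference=float(d.mean()))
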