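"""Alpha and beta diversity: richness, convex-hull functional richness, and
the turnover/nestedness partition of pairwise dissimilarity.

Taxonomic dissimilarity between two assemblages X, Y is built from the
shared/unique species counts a = |X n Y|, b = |X \\ Y|, c = |Y \\ X| and the
Jaccard family of indices

    D      = (b + c) / (a + b + c)
    D_tu   = 2 min(b, c) / (a + 2 min(b, c))          (turnover)
    D_ne   = D - D_tu                                 (nestedness)

Functional dissimilarity uses the same formulas with volumes in the PCoA
trait space: a = volume of the intersection of the two assemblages' convex
hulls, b and c the volumes unique to each hull.  The union volume is always
a + b + c = V(X) + V(Y) - V(X n Y); the hull of the pooled points is never
used (it can exceed the true union).  Intersection volumes are computed by
half-space intersection about a Chebyshev-center interior point found by
linear programming; an infeasible program means disjoint hulls (a = 0).

The Sørensen family (D = (b+c)/(2a+b+c), D_tu = min(b,c)/(a+min(b,c))) is
available behind the ``family`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

from .exceptions import CoverageError, EmptyPairError
from .functional_space import FunctionalSpace
from .io import AssemblageMatrix

__all__ = [
    "PairComponents",
    "BetaPartition",
    "species_richness",
    "hull_volume",
    "functional_richness",
    "taxonomic_components",
    "functional_components",
    "hull_intersection_volume",
    "jaccard_partition",
    "pairwise_beta",
    "taxonomic_beta_matrices",
]

#: Volumes below this fraction of the pool volume are treated as zero to
#: stabilize overlap ratios.
VOLUME_FLOOR_FRACTION = 1e-12


@dataclass(frozen=True)
class PairComponents:
    """Shared (a) and unique (b, c) magnitudes for one assemblage pair.

    ``mode`` is ``"counts"`` (species sets) or ``"volumes"`` (hull volumes).
    """

    a: float
    b: float
    c: float
    mode: str = "counts"

    def __post_init__(self):
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("components must be nonnegative")


@dataclass(frozen=True)
class BetaPartition:
    """Total dissimilarity and its turnover/nestedness decomposition.

    ``total = turnover + nestedness`` (to 1e-10); the contribution fields are
    NaN when total dissimilarity is zero (identical assemblages).
    """

    total: float
    turnover: float
    nestedness: float

    @property
    def turnover_contribution(self) -> float:
        return self.turnover / self.total if self.total > 0 else float("nan")

    @property
    def nestedness_contribution(self) -> float:
        return self.nestedness / self.total if self.total > 0 else float("nan")


def species_richness(row) -> int:
    """Number of species present in one assemblage (count of 1s)."""
    return int(np.asarray(row).sum())


def hull_volume(points: np.ndarray) -> float:
    """Volume of the convex hull of ``points`` (k x m array).

    Returns 0.0 for affinely degenerate inputs (fewer than m+1 points, or
    points spanning a lower-dimensional subspace).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < points.shape[1] + 1:
        return 0.0
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        return 0.0


def functional_richness(row, space: FunctionalSpace, pool_volume: float) -> float:
    """Standardized FRic: assemblage hull volume / species-pool hull volume.

    Ranges from 0 (single-species or degenerate assemblages) to 1 (the
    assemblage fills the pool's hull).  ``pool_volume`` must be the hull
    volume of the full (two-period) species pool and be positive.
    """
    if pool_volume <= 0:
        raise ValueError("pool_volume must be positive")
    row = pd.Series(row) if not isinstance(row, pd.Series) else row
    present = list(row.index[row.astype(bool)])
    missing = [s for s in present if s not in space.coordinates.index]
    if missing:
        raise CoverageError(f"species without coordinates: {missing}")
    return hull_volume(space.points(present)) / pool_volume


def taxonomic_components(x, y) -> PairComponents:
    """Shared/unique species counts for two binary rows on one species axis."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("rows must share the species axis")
    return PairComponents(
        a=int((x & y).sum()), b=int((x & ~y).sum()), c=int((~x & y).sum()),
        mode="counts",
    )


def _hull_or_none(points: np.ndarray):
    points = np.asarray(points, dtype=float)
    if points.shape[0] < points.shape[1] + 1:
        return None
    try:
        return ConvexHull(points)
    except QhullError:
        return None


def hull_intersection_volume(hull_x: ConvexHull, hull_y: ConvexHull) -> float:
    """Volume of the intersection of two (full-dimensional) convex hulls.

    The two hulls' facet half-spaces are stacked; a Chebyshev center (the
    deepest interior point) is found by linear programming.  An infeasible
    or zero-radius program means the interiors do not intersect (volume 0);
    otherwise the half-space intersection's vertices are hulled for the
    volume.
    """
    halfspaces = np.vstack([hull_x.equations, hull_y.equations])
    A = halfspaces[:, :-1]
    b = halfspaces[:, -1]
    m = A.shape[1]
    norms = np.linalg.norm(A, axis=1, keepdims=True)
    # maximize r subject to A x + ||A_i|| r <= -b
    res = linprog(
        c=np.r_[np.zeros(m), -1.0],
        A_ub=np.hstack([A, norms]),
        b_ub=-b,
        bounds=[(None, None)] * m + [(0, None)],
        method="highs",
    )
    if not res.success or res.x[-1] <= 1e-12:
        return 0.0
    interior = res.x[:m]
    try:
        hs = HalfspaceIntersection(halfspaces, interior)
        return float(ConvexHull(hs.intersections).volume)
    except QhullError:
        return 0.0


def functional_components(x, y, space: FunctionalSpace,
                          volume_floor: float = 0.0) -> PairComponents | None:
    """Hull-overlap volume components for two assemblages in trait space.

    Returns ``None`` (pair flagged missing) when either assemblage's hull is
    degenerate in the retained space.  ``volume_floor`` (absolute) zeroes
    numerically negligible volumes.
    """
    x = pd.Series(x) if not isinstance(x, pd.Series) else x
    y = pd.Series(y) if not isinstance(y, pd.Series) else y
    hx = _hull_or_none(space.points(x.index[x.astype(bool)]))
    hy = _hull_or_none(space.points(y.index[y.astype(bool)]))
    if hx is None or hy is None:
        return None
    return _components_from_hulls(hx, hy, volume_floor)


def _components_from_hulls(hx: ConvexHull, hy: ConvexHull,
                           volume_floor: float = 0.0) -> PairComponents:
    vx, vy = float(hx.volume), float(hy.volume)
    shared = hull_intersection_volume(hx, hy)
    shared = min(shared, vx, vy)  # clip numerical overshoot
    vals = [0.0 if v < volume_floor else v
            for v in (shared, vx - shared, vy - shared)]
    return PairComponents(a=vals[0], b=max(vals[1], 0.0), c=max(vals[2], 0.0),
                          mode="volumes")


def jaccard_partition(comp: PairComponents, family: str = "jaccard") -> BetaPartition:
    """Partition pairwise dissimilarity into turnover and nestedness.

    ``family="jaccard"`` (default) or ``"sorensen"``.  Raises
    :class:`EmptyPairError` when a + b + c = 0.
    """
    a, b, c = comp.a, comp.b, comp.c
    if a + b + c == 0:
        raise EmptyPairError("both assemblages empty (a + b + c = 0)")
    m = min(b, c)
    if family == "jaccard":
        total = (b + c) / (a + b + c)
        turnover = 2.0 * m / (a + 2.0 * m) if (a + 2.0 * m) > 0 else 0.0
    elif family == "sorensen":
        total = (b + c) / (2.0 * a + b + c)
        turnover = m / (a + m) if (a + m) > 0 else 0.0
    else:
        raise ValueError(f"unknown family {family!r}")
    return BetaPartition(total=total, turnover=turnover,
                         nestedness=total - turnover)


def _partition_record(prefix: str, part: BetaPartition | None) -> dict:
    if part is None:
        return {
            f"{prefix}_D": np.nan, f"{prefix}_Dtu": np.nan,
            f"{prefix}_Dne": np.nan, f"{prefix}_turnover_contribution": np.nan,
            f"{prefix}_nestedness_contribution": np.nan,
        }
    return {
        f"{prefix}_D": part.total,
        f"{prefix}_Dtu": part.turnover,
        f"{prefix}_Dne": part.nestedness,
        f"{prefix}_turnover_contribution": part.turnover_contribution,
        f"{prefix}_nestedness_contribution": part.nestedness_contribution,
    }


def pairwise_beta(matrix: AssemblageMatrix,
                  space: FunctionalSpace | None = None,
                  include_functional: bool = True,
                  family: str = "jaccard",
                  pool_volume: float | None = None) -> pd.DataFrame:
    """Per-pair dissimilarity table for one period.

    One row per unordered site pair (n(n-1)/2 rows) with: per-site richness,
    the min/max richness ratio, the taxonomic partition, and — when
    ``include_functional`` — per-site hull volumes, the functional richness
    ratio, and the functional partition (NaN + ``functional_missing`` flag
    where either hull is degenerate).  ``pool_volume`` sets the absolute
    volume floor (``VOLUME_FLOOR_FRACTION`` of it).
    """
    if include_functional and space is None:
        raise ValueError("functional beta requires a functional space")
    sites = matrix.site_ids
    data = matrix.data
    hulls: dict = {}
    floor = 0.0
    if include_functional:
        missing = [s for s in matrix.species_ids
                   if s not in space.coordinates.index]
        if missing:
            raise CoverageError(f"species without coordinates: {missing}")
        if pool_volume is None:
            pool_volume = hull_volume(space.points(matrix.species_ids))
        floor = VOLUME_FLOOR_FRACTION * pool_volume
        for site in sites:
            row = data.loc[site]
            hulls[site] = _hull_or_none(
                space.points(row.index[row.astype(bool)])
            )
    records = []
    for si, sj in combinations(sites, 2):
        xi, xj = data.loc[si], data.loc[sj]
        ri, rj = int(xi.sum()), int(xj.sum())
        rec = {
            "site_i": si, "site_j": sj,
            "richness_i": ri, "richness_j": rj,
            "richness_ratio": (min(ri, rj) / max(ri, rj)
                               if max(ri, rj) > 0 else np.nan),
        }
        comp = taxonomic_components(xi.to_numpy(), xj.to_numpy())
        try:
            tax = jaccard_partition(comp, family)
        except EmptyPairError:
            tax = None
        rec.update(_partition_record("tax", tax))
        if include_functional:
            hi, hj = hulls[si], hulls[sj]
            if hi is None or hj is None:
                rec.update(_partition_record("fun", None))
                rec.update({
                    "volume_i": np.nan, "volume_j": np.nan,
                    "volume_shared": np.nan, "fun_richness_ratio": np.nan,
                    "functional_missing": True,
                })
            else:
                fcomp = _components_from_hulls(hi, hj, floor)
                fun = (jaccard_partition(fcomp, family)
                       if fcomp.a + fcomp.b + fcomp.c > 0 else None)
                vi = fcomp.a + fcomp.b
                vj = fcomp.a + fcomp.c
                rec.update(_partition_record("fun", fun))
                rec.update({
                    "volume_i": vi, "volume_j": vj, "volume_shared": fcomp.a,
                    "fun_richness_ratio": (min(vi, vj) / max(vi, vj)
                                           if max(vi, vj) > 0 else np.nan),
                    "functional_missing": False,
                })
        records.append(rec)
    return pd.DataFrame.from_records(records)


def taxonomic_beta_matrices(matrix: AssemblageMatrix, family: str = "jaccard"
                            ) -> dict[str, np.ndarray]:
    """Square D / D_tu / D_ne matrices for one period, fully vectorized.

    Used where every pair is needed as a distance matrix (Mantel/MRM inputs,
    null-model statistics).  Pairs with a + b + c = 0 are NaN.
    """
    X = matrix.values.astype(float)
    shared = X @ X.T
    rich = X.sum(axis=1)
    b = rich[:, None] - shared
    c = rich[None, :] - shared
    m = np.minimum(b, c)
    with np.errstate(divide="ignore", invalid="ignore"):
        if family == "jaccard":
            total = (b + c) / (shared + b + c)
            turnover = np.where(shared + 2 * m > 0,
                                2 * m / (shared + 2 * m), 0.0)
        elif family == "sorensen":
            total = (b + c) / (2 * shared + b + c)
            turnover = np.where(shared + m > 0, m / (shared + m), 0.0)
        else:
            raise ValueError(f"unknown family {family!r}")
    np.fill_diagonal(total, 0.0)
    np.fill_diagonal(turnover, 0.0)
    return {"D": total, "Dtu": turnover, "Dne": total - turnover}
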