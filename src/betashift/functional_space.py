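"""Trait encoding, species functional distances, and the PCoA trait space.

The functional space is built by one-hot encoding the categorical traits,
computing a Euclidean distance matrix between species, and embedding it with
principal coordinates analysis (PCoA).  The first ``m`` axes (default three)
define the space in which convex-hull functional richness and overlap are
measured.  A Gower (simple-matching) distance is offered as an option, as is
a Lingoes correction for negative eigenvalues; by default negative
eigenvalues are simply excluded from both the coordinates and the quality
denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .exceptions import DegenerateInputError
from .io import TraitTable

__all__ = [
    "FunctionalSpace",
    "encode_traits",
    "trait_distance",
    "pcoa",
    "space_quality",
    "build_functional_space",
]

_EIG_REL_TOL = 1e-10


@dataclass
class FunctionalSpace:
    """Species coordinates on the retained PCoA axes.

    Attributes
    ----------
    coordinates
        Species x m DataFrame with columns ``PcoA1..PcoAm``; axes are ordered
        by descending eigenvalue, columns are centered, and the sign of each
        axis is fixed so its largest-magnitude loading is positive.
    eigenvalues
        The full eigenvalue spectrum, descending (negatives included so the
        embedding quality can be audited).
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray

    @property
    def species_ids(self) -> list:
        return list(self.coordinates.index)

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    @property
    def quality(self) -> float:
        """Fraction of positive-eigenvalue mass captured by the retained axes."""
        return space_quality(self, self.n_axes)

    def points(self, species_ids) -> np.ndarray:
        """Coordinate rows for the given species (raises on missing ids)."""
        return self.coordinates.loc[list(species_ids)].to_numpy()


def encode_traits(traits: TraitTable, scheme: str = "onehot") -> pd.DataFrame:
    """One-hot encode categorical traits into a species x indicator matrix.

    ``scheme="onehot"`` yields one 0/1 indicator column per declared level
    (columns ordered by the vocabulary, so unused levels still appear and the
    feature space is stable across datasets).  ``scheme="gower"`` rescales
    the same indicators by ``1/sqrt(2 T)`` (T = number of traits) so that
    *squared* Euclidean distance equals the simple-matching Gower
    dissimilarity (mismatched traits / T).
    """
    if scheme not in ("onehot", "gower"):
        raise ValueError(f"unknown encoding scheme {scheme!r}")
    blocks = []
    for trait, levels in traits.vocabulary.items():
        col = traits.data[trait]
        for level in levels:
            blocks.append((f"{trait}={level}", (col == level).astype(float)))
    encoded = pd.DataFrame(dict(blocks), index=traits.data.index)
    n_traits = len(traits.vocabulary)
    if scheme == "gower":
        encoded = encoded / np.sqrt(2.0 * n_traits)
    encoded.attrs["n_traits"] = n_traits
    encoded.attrs["scheme"] = scheme
    return encoded


def trait_distance(encoded: pd.DataFrame, metric: str = "euclidean") -> pd.DataFrame:
    """Symmetric species distance matrix from an encoded trait matrix.

    ``metric="euclidean"`` is the straight Euclidean distance on the encoded
    features (with plain one-hot encoding, two species differing in one trait
    are sqrt(2) apart).  ``metric="gower"`` returns the simple-matching
    dissimilarity (# mismatched traits / # traits) and requires the encoding
    produced by :func:`encode_traits`.
    """
    if len(encoded) < 2:
        raise DegenerateInputError("need at least two species for distances")
    X = encoded.to_numpy(dtype=float)
    if metric == "euclidean":
        d = squareform(pdist(X, metric="euclidean"))
    elif metric == "gower":
        n_traits = encoded.attrs.get("n_traits")
        if n_traits is None:
            raise ValueError("gower metric needs a matrix from encode_traits")
        scale = 1.0 if encoded.attrs.get("scheme") == "gower" else 1.0 / (2.0 * n_traits)
        d = squareform(pdist(X, metric="sqeuclidean")) * scale
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(d, index=encoded.index, columns=encoded.index)


def _lingoes(d2: np.ndarray, eigvals: np.ndarray) -> np.ndarray:
    """Lingoes correction: add -2*lambda_min to off-diagonal squared distances."""
    c = -eigvals.min()
    d2c = d2 + 2.0 * c
    np.fill_diagonal(d2c, 0.0)
    return d2c


def pcoa(dist: pd.DataFrame, m: int = 3,
         negative_eigenvalue_policy: str = "discard") -> FunctionalSpace:
    """Principal coordinates analysis of a species distance matrix.

    The squared distance matrix is double-centered (Gower transform) and
    eigendecomposed; coordinates are eigenvectors scaled by the square root
    of their (positive) eigenvalues.  When the input distances are
    Euclidean-embeddable the full positive space reproduces them exactly.

    Parameters
    ----------
    m
        Number of axes to retain (1 <= m < n_species).  If fewer than ``m``
        positive eigenvalues exist, the space is reduced with a warning.
    negative_eigenvalue_policy
        ``"discard"`` (default: negatives excluded from coordinates and from
        the quality denominator) or ``"lingoes"`` (constant correction making
        the matrix embeddable before decomposition).
    """
    n = dist.shape[0]
    if not 1 <= m < n:
        raise ValueError(f"m must satisfy 1 <= m < {n}, got {m}")
    D = dist.to_numpy(dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    d2 = D ** 2
    eigvals, eigvecs = _center_and_decompose(d2)
    if negative_eigenvalue_policy == "lingoes" and eigvals.min() < -_eig_tol(eigvals):
        eigvals, eigvecs = _center_and_decompose(_lingoes(d2, eigvals))
    elif negative_eigenvalue_policy not in ("discard", "lingoes"):
        raise ValueError(
            f"unknown negative_eigenvalue_policy {negative_eigenvalue_policy!r}"
        )
    tol = _eig_tol(eigvals)
    n_pos = int((eigvals > tol).sum())
    if n_pos == 0:
        raise DegenerateInputError("no positive eigenvalue: degenerate space")
    if m > n_pos:
        warnings.warn(
            f"requested {m} axes but only {n_pos} positive eigenvalues; "
            f"retaining {n_pos}",
            stacklevel=2,
        )
        m = n_pos
    coords = eigvecs[:, :m] * np.sqrt(eigvals[:m])
    # reproducible axis orientation: largest-magnitude loading positive
    flip = coords[np.abs(coords).argmax(axis=0), np.arange(m)] < 0
    coords[:, flip] *= -1.0
    frame = pd.DataFrame(
        coords, index=dist.index, columns=[f"PcoA{k + 1}" for k in range(m)]
    )
    return FunctionalSpace(frame, eigvals)


def _center_and_decompose(d2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = d2.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order]


def _eig_tol(eigvals: np.ndarray) -> float:
    return max(np.abs(eigvals).max(), 1.0) * _EIG_REL_TOL


def space_quality(space: FunctionalSpace, m: int | None = None) -> float:
    """Fraction of positive eigenvalue mass captured by the first ``m`` axes."""
    eigvals = space.eigenvalues
    tol = _eig_tol(eigvals)
    pos = eigvals[eigvals > tol]
    if pos.size == 0:
        raise DegenerateInputError("no positive eigenvalue: quality undefined")
    if m is None:
        m = space.n_axes
    return float(pos[: min(m, pos.size)].sum() / pos.sum())


def build_functional_space(traits: TraitTable, n_axes: int = 3,
                           encoding: str = "onehot",
                           metric: str = "euclidean",
                           negative_eigenvalue_policy: str = "discard",
                           ) -> FunctionalSpace:
    """Convenience pipeline: encode -> distance -> PCoA with ``n_axes`` axes."""
    encoded = encode_traits(traits, scheme=encoding)
    dist = trait_distance(encoded, metric=metric)
    return pcoa(dist, m=n_axes,
                negative_eigenvalue_policy=negative_eigenvalue_policy)
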