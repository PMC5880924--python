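"""Monte Carlo null model for the nestedness component under random
regional species loss.

The question: is the observed mean pairwise nestedness of the *current*
assemblages larger than expected if the regional pool had simply lost the
same fraction of species at random, with each lake then holding a random
subset of its surviving historical species of the observed current richness?

Each replicate (i) removes ``ceil(loss_fraction * S_hist)`` species from the
historical regional pool — uniformly, or with probability inversely
proportional to historical occupancy under ``occupancy_weighted`` — and
(ii) draws every site's simulated current assemblage uniformly from its
surviving historical species, of size equal to the observed current richness
(capped at availability; capped sites are counted).  Row sums (per-site
current richness) are therefore preserved up to the cap, the operational
reading of "preserving the characteristics of the observed matrix".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import taxonomic_beta_matrices
from .exceptions import BetashiftError
from .io import AssemblageMatrix, PairedAssemblages

__all__ = ["NullModelResult", "randomize_current", "null_nestedness_test",
           "mean_pairwise_nestedness"]


@dataclass(frozen=True)
class NullModelResult:
    """Observed statistic against its Monte Carlo null distribution."""

    observed: float
    null_mean: float
    null_sd: float
    n_replicates: int
    p_value: float
    seed: int | None
    scheme: str
    loss_fraction: float
    statistic: str
    capped_site_fraction: float

    def to_dict(self) -> dict:
        return {
            "observed": self.observed, "null_mean": self.null_mean,
            "null_sd": self.null_sd, "n_replicates": self.n_replicates,
            "p_value": self.p_value, "seed": self.seed,
            "scheme": self.scheme, "loss_fraction": self.loss_fraction,
            "statistic": self.statistic,
            "capped_site_fraction": self.capped_site_fraction,
        }


def _simulate_current(H: np.ndarray, target_richness: np.ndarray,
                      occupancy: np.ndarray, loss_fraction: float,
                      scheme: str, rng: np.random.Generator,
                      subsample: bool = True) -> tuple[np.ndarray, int]:
    """One replicate matrix plus the number of availability-capped sites."""
    n_sites, n_species = H.shape
    pool = np.flatnonzero(occupancy > 0)
    n_remove = math.ceil(loss_fraction * pool.size)
    if scheme == "uniform":
        removed = rng.choice(pool, size=n_remove, replace=False)
    elif scheme == "occupancy_weighted":
        w = 1.0 / occupancy[pool]
        removed = rng.choice(pool, size=n_remove, replace=False,
                             p=w / w.sum())
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    surviving = np.ones(n_species, dtype=bool)
    surviving[removed] = False
    sim = np.zeros_like(H)
    capped = 0
    for i in range(n_sites):
        avail = np.flatnonzero(H[i].astype(bool) & surviving)
        if not subsample:
            sim[i, avail] = 1
            continue
        k = int(target_richness[i])
        if k > avail.size:
            capped += 1
            k = avail.size
        if k > 0:
            sim[i, rng.choice(avail, size=k, replace=False)] = 1
    return sim, capped


def randomize_current(paired: PairedAssemblages, loss_fraction: float,
                      scheme: str = "uniform",
                      rng: np.random.Generator | None = None,
                      subsample: bool = True) -> AssemblageMatrix:
    """One simulated current matrix under random regional loss.

    With ``subsample=False`` sites keep *all* their surviving historical
    species (no richness constraint) — the degenerate loss_fraction=0 case
    then reproduces the historical matrix exactly.
    """
    if not 0 <= loss_fraction < 1:
        raise ValueError("loss_fraction must be in [0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    H = paired.historical.values
    sim, _ = _simulate_current(
        H, paired.current.richness.to_numpy(),
        paired.historical.occupancy.to_numpy(),
        loss_fraction, scheme, rng, subsample,
    )
    frame = pd.DataFrame(sim, index=paired.site_ids,
                         columns=paired.species_ids)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty simulated sites are expected
        return AssemblageMatrix(frame, "simulated_current")


def mean_pairwise_nestedness(matrix: AssemblageMatrix,
                             family: str = "jaccard") -> float:
    """Mean taxonomic nestedness component over all site pairs (NaN pairs —
    both sites empty — excluded)."""
    Dne = taxonomic_beta_matrices(matrix, family)["Dne"]
    i, j = np.tril_indices(Dne.shape[0], k=-1)
    vals = Dne[i, j]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise BetashiftError("no valid pair for the nestedness statistic")
    return float(vals.mean())


def null_nestedness_test(paired: PairedAssemblages, nreps: int = 9999,
                         seed: int | None = None,
                         loss_fraction: float | None = None,
                         scheme: str = "uniform",
                         family: str = "jaccard") -> NullModelResult:
    """Monte Carlo test of the observed mean pairwise nestedness.

    ``loss_fraction`` defaults to the observed regional pool reduction.
    The p-value is for the "observed greater than null" alternative,
    ``p = (#{null >= observed} + 1) / (nreps + 1)``.
    """
    if nreps < 1:
        raise ValueError("nreps must be >= 1")
    if loss_fraction is None:
        hist_pool = paired.historical.pool_size
        curr_pool = paired.current.pool_size
        loss_fraction = max(0.0, (hist_pool - curr_pool) / hist_pool)
    observed = mean_pairwise_nestedness(paired.current, family)
    rng = np.random.default_rng(seed)
    H = paired.historical.values
    target = paired.current.richness.to_numpy()
    occupancy = paired.historical.occupancy.to_numpy()
    sites = paired.site_ids
    species = paired.species_ids
    null_vals = np.empty(nreps)
    capped_total = 0
    for r in range(nreps):
        sim, capped = _simulate_current(
            H, target, occupancy, loss_fraction, scheme, rng
        )
        capped_total += capped
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mat = AssemblageMatrix(
                pd.DataFrame(sim, index=sites, columns=species), "null")
        null_vals[r] = mean_pairwise_nestedness(mat, family)
    p = (int((null_vals >= observed - 1e-12).sum()) + 1) / (nreps + 1)
    return NullModelResult(
        observed=observed,
        null_mean=float(null_vals.mean()),
        null_sd=float(null_vals.std(ddof=1)) if nreps > 1 else 0.0,
        n_replicates=nreps,
        p_value=float(p),
        seed=seed,
        scheme=scheme,
        loss_fraction=float(loss_fraction),
        statistic="mean_pairwise_nestedness",
        capped_site_fraction=capped_total / (nreps * len(sites)),
    )
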