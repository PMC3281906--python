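"""Angle-normalized Gaussian likelihood of intensity observations given dosage.

An intensity pair ``(x, y)`` is L1-normalized to the scalar coordinate
``r = x / (x + y)``; a dosage-``g`` individual of ploidy ``m`` is expected at
the angle ``g / m``, and deviations are penalized by a Gaussian with unknown
standard deviation ``sigma`` (shared across dosages and searched on a grid).
The per-locus table caches the per-individual, per-dosage log-likelihoods
aggregated over replicates, together with the parameter-free sorted order of
individuals along the normalized axis that the geometric search relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import LocusDataset

logger = logging.getLogger(__name__)


def normalize_point(x: float, y: float) -> float:
    """L1-normalize an intensity pair to the allele-A fraction ``x / (x + y)``.

    Scale-invariant: ``normalize_point(l*x, l*y) == normalize_point(x, y)``
    for any ``l > 0``.
    """
    total = x + y
    if total <= 0:
        raise ValueError(f"cannot normalize non-positive total intensity ({x}, {y})")
    return x / total


def genotype_loglik(r, g, m: int, sigma: float):
    """Gaussian log-density of normalized coordinate ``r`` given dosage ``g``.

    ``log N(r; g/m, sigma^2)`` — the likelihood model on the normalized axis.
    Vectorized over ``r`` and/or ``g``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return stats.norm.logpdf(r, loc=np.asarray(g) / m, scale=sigma)


def sorted_individuals(dataset: LocusDataset) -> tuple[list[str], np.ndarray]:
    """Order individuals by mean normalized coordinate (ties by id, stable).

    This ordering along the line x + y = 1 is parameter-free: it is computed
    once per locus and reused for every (ploidy, sigma) searched.
    Returns (ids in sorted order, their mean coordinates in that order).
    """
    grouped = dataset.points_by_individual()
    ids = list(grouped)
    means = np.array(
        [np.mean([normalize_point(p.x, p.y) for p in grouped[i]]) for i in ids]
    )
    order = sorted(range(len(ids)), key=lambda k: (means[k], ids[k]))
    return [ids[k] for k in order], means[order]


@dataclass
class LikelihoodTable:
    """Cached per-individual, per-dosage log-likelihoods for one (m, sigma).

    Rows follow the sorted order of individuals along the normalized axis;
    ``logL[i, g]`` sums the Gaussian log-density over individual ``i``'s
    replicates.  Prefix cumulative sums and suffix maxima used by the search
    engines are computed lazily and cached.
    """

    m: int
    sigma: float
    individuals: list[str]
    coords: np.ndarray  # mean normalized coordinate, sorted non-decreasing
    logL: np.ndarray  # shape (n, m + 1)
    replicate_counts: np.ndarray

    _col_cumsum: np.ndarray | None = field(default=None, repr=False)
    _suffix_max: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def col_cumsum(self) -> np.ndarray:
        """``col_cumsum[g, i] = sum_{j < i} logL[j, g]`` — block likelihoods in O(1)."""
        if self._col_cumsum is None:
            cs = np.zeros((self.m + 1, self.n + 1))
            cs[:, 1:] = np.cumsum(self.logL.T, axis=1)
            self._col_cumsum = cs
        return self._col_cumsum

    @property
    def suffix_max(self) -> np.ndarray:
        """``suffix_max[k, i] = sum_{j >= i} max_{g >= k} logL[j, g]``.

        Row ``k = m + 1`` is the empty-dosage-set boundary: 0 for ``i = n``
        (nothing left to assign) and -inf otherwise.
        """
        if self._suffix_max is None:
            n, m = self.n, self.m
            sm = np.full((m + 2, n + 1), -np.inf)
            sm[:, n] = 0.0
            for k in range(m, -1, -1):
                best = np.max(self.logL[:, k:], axis=1)  # max over open dosages
                sm[k, :n] = np.cumsum(best[::-1])[::-1]
            self._suffix_max = sm
        return self._suffix_max


def build_table(
    dataset: LocusDataset,
    m: int,
    sigma: float,
    *,
    order: tuple[list[str], np.ndarray] | None = None,
) -> LikelihoodTable:
    """Build the cached likelihood table for one (ploidy, sigma) pair.

    ``order`` may carry the precomputed result of :func:`sorted_individuals`
    to avoid re-sorting across the parameter grid.
    """
    if order is None:
        order = sorted_individuals(dataset)
    ids, coords = order

    grouped = dataset.points_by_individual()
    counts = np.array([len(grouped[i]) for i in ids])
    if len(set(counts.tolist())) > 1:
        logger.warning(
            "locus %s has unequal replicate counts per individual; the exact-MAP "
            "guarantee of the search is proven only for equal counts",
            dataset.locus_id,
        )

    angles = np.arange(m + 1) / m
    logL = np.zeros((len(ids), m + 1))
    for i, ind in enumerate(ids):
        rs = np.array([normalize_point(p.x, p.y) for p in grouped[ind]])
        # sum over replicates of log N(r; g/m, sigma^2)
        logL[i] = stats.norm.logpdf(rs[:, None], loc=angles[None, :], scale=sigma).sum(
            axis=0
        )
    return LikelihoodTable(
        m=m,
        sigma=sigma,
        individuals=list(ids),
        coords=np.asarray(coords, dtype=float),
        logL=logL,
        replicate_counts=counts,
    )
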