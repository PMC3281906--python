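"""Theoretical genotype-frequency vectors under population models.

For a locus of ploidy ``m`` the genotype of an individual is its allele
dosage ``g`` in ``{0, ..., m}`` (copies of the x-channel allele).  A
population model supplies the theoretical frequency vector ``F`` over
dosages:

* Hardy-Weinberg: ``F_g = C(m, g) p^g (1-p)^(m-g)`` for allele frequency
  ``p``, searched on a discrete grid.
* F1 cross: gametes of a parent with dosage ``d`` carry ``j`` copies with
  hypergeometric probability ``C(d, j) C(m-d, m/2-j) / C(m, m/2)`` (random
  bivalent pairing, no double reduction); offspring dosage frequencies are
  the convolution of the two parental gamete distributions.
* Custom: user-supplied frequency vectors per parameter index.
"""

from __future__ import annotations

from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats


class HWParams(NamedTuple):
    """Hardy-Weinberg model parameter: allele-A frequency."""

    p: float


class F1Params(NamedTuple):
    """F1 model parameters: the dosages of the two parents."""

    p1: int
    p2: int


def hw_frequencies(m: int, p: float) -> np.ndarray:
    """Binomial genotype frequencies under Hardy-Weinberg equilibrium.

    Returns the vector ``F`` of length ``m + 1`` with
    ``F_g = C(m, g) p^g (1 - p)^(m - g)``.
    """
    if m < 1:
        raise ValueError(f"ploidy must be >= 1, got {m}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency must be in [0, 1], got {p}")
    return stats.binom.pmf(np.arange(m + 1), m, p)


def gamete_pmf(m: int, d: int) -> np.ndarray:
    """Hypergeometric gamete dosage distribution for a parent of dosage ``d``.

    A gamete carries ``m/2`` of the parent's ``m`` alleles, drawn without
    replacement; ``j`` of them are copies of allele A with probability
    ``C(d, j) C(m - d, m/2 - j) / C(m, m/2)``.  Returns a vector over
    ``j in {0, ..., m/2}`` summing to 1.
    """
    if m % 2 != 0 or m < 2:
        raise ValueError(f"gamete model requires even ploidy >= 2, got m={m}")
    if not 0 <= d <= m:
        raise ValueError(f"parental dosage must be in [0, {m}], got {d}")
    half = m // 2
    return stats.hypergeom.pmf(np.arange(half + 1), m, d, half)


def f1_frequencies(m: int, params: F1Params) -> np.ndarray:
    """Offspring dosage frequencies for an F1 cross: gamete-pmf convolution."""
    p1, p2 = params
    return np.convolve(gamete_pmf(m, p1), gamete_pmf(m, p2))


def enumerate_parent_pairs(
    m: int, *, ordered: bool = False, distinct_only: bool = False
) -> list[F1Params]:
    """Enumerate candidate parental dosage pairs for an F1 cross of ploidy ``m``.

    Unordered with repeats gives ``(m+1)(m+2)/2`` pairs; ordered gives
    ``(m+1)^2``; unordered distinct gives ``m(m+1)/2``.
    """
    if m % 2 != 0:
        raise ValueError(f"F1 model requires even ploidy, got m={m}")
    pairs: list[F1Params] = []
    for p1 in range(m + 1):
        lo = 0 if ordered else p1
        for p2 in range(lo, m + 1):
            if distinct_only and p1 == p2:
                continue
            pairs.append(F1Params(p1, p2))
    return pairs


def parent_pair_prior(m: int, has_parent_data: bool) -> float:
    """Uniform prior over distinguishable parental dosage pairs.

    Without parental data the parents are exchangeable, so the prior is
    uniform over the ``(m+1)(m+2)/2`` unordered pairs (repeats allowed).
    With parental data the parents are distinguishable and the prior is
    uniform over the ``(m+1)^2`` ordered pairs.
    """
    if m % 2 != 0:
        raise ValueError(f"F1 model requires even ploidy, got m={m}")
    if has_parent_data:
        return 1.0 / (m + 1) ** 2
    return 2.0 / ((m + 1) * (m + 2))


def allele_frequency_grid(resolution: float = 0.01) -> np.ndarray:
    """Discretized allele-frequency grid over [0, 1] at the given resolution."""
    if not 0 < resolution <= 0.5:
        raise ValueError(f"resolution must be in (0, 0.5], got {resolution}")
    n_steps = int(round(1.0 / resolution))
    return np.linspace(0.0, 1.0, n_steps + 1)


def parent_data_likelihood(parent_points, dosage: int, m: int, sigma: float) -> float:
    """Log-likelihood of parental replicate intensities given the parent's dosage.

    Replicates are conditionally independent given the genotype, so the
    result is the sum over replicates of the Gaussian log-density of the
    normalized coordinate at the expected angle ``dosage / m``.  An empty
    replicate collection contributes 0 (no evidence).
    """
    from .likelihood_model import genotype_loglik, normalize_point

    if not 0 <= dosage <= m:
        raise ValueError(f"dosage must be in [0, {m}], got {dosage}")
    total = 0.0
    for pt in parent_points:
        r = normalize_point(pt.x, pt.y)
        total += genotype_loglik(r, dosage, m, sigma)
    return total


def read_custom_model(path: str | Path) -> dict[str, np.ndarray]:
    """Read user-supplied frequency vectors: TSV columns (param_id, dosage, frequency).

    Each param_id must supply a frequency for every dosage 0..m (a contiguous
    index range) and the frequencies must sum to 1 (1e-6 tolerance).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"param_id", "dosage", "frequency"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: custom model needs columns {sorted(required)}")
    models: dict[str, np.ndarray] = {}
    for pid, grp in df.groupby("param_id", sort=False):
        dosages = grp["dosage"].to_numpy(dtype=int)
        freqs = grp["frequency"].to_numpy(dtype=float)
        m = dosages.max()
        if sorted(dosages) != list(range(m + 1)):
            raise ValueError(f"{path}: param {pid!r} must cover dosages 0..{m} once")
        F = np.empty(m + 1)
        F[dosages] = freqs
        if np.any(F < 0) or abs(F.sum() - 1.0) > 1e-6:
            raise ValueError(f"{path}: param {pid!r} frequencies must be a distribution")
        models[str(pid)] = F
    return models
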