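"""Exact MAP genotype-configuration inference and the outer parameter search.

The joint model couples all individuals at a locus through the genotype
distribution: for a configuration assigning dosage counts ``c`` over the
``m + 1`` dosage classes, the joint score is

    log multinomial(c; n, F) + sum_i log L(d_i | g_i) + log prior(theta)

where ``F`` is the theoretical frequency vector of the population model.
Because the multinomial term couples every individual, per-individual
(greedy) maximization is not exact.  Exact MAP engines provided:

* ``naive_map`` — exhaustive enumeration over all ``(m+1)^n`` configurations
  (test oracle, guarded).
* ``dp_map`` — layered dynamic program over partial count vectors with a
  conservative branch-and-bound; memory-guarded.
* ``geometric_map`` — branch-and-bound over genotype *distributions*: since
  the likelihood-optimal configuration for fixed counts assigns dosage
  classes as contiguous blocks of individuals sorted by normalized
  coordinate, the search tree has depth ``m + 1`` instead of ``n``, and each
  prefix admits a tight admissible upper bound.

The outer search grids over (ploidy, sigma, theta), keeps the jointly best
setting, and approximates the posterior of the MAP configuration by
normalizing per-setting MAP joints; a slack factor tau derived from the
requested maximum posterior error lets clearly inferior settings be pruned
at their greedy bound without violating the error guarantee.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
from scipy.special import gammaln, logsumexp

from .data_io import LocusDataset
from .likelihood_model import LikelihoodTable, build_table, sorted_individuals
from .population_models import (
    F1Params,
    HWParams,
    allele_frequency_grid,
    enumerate_parent_pairs,
    f1_frequencies,
    hw_frequencies,
    parent_data_likelihood,
    parent_pair_prior,
)

logger = logging.getLogger(__name__)

NEG_INF = float("-inf")


class NaiveSizeError(RuntimeError):
    """The naive enumeration would exceed its configuration-count guard."""


class DPMemoryError(RuntimeError):
    """The dynamic program's layer grew beyond the node-count guard."""

    def __init__(self, depth: int, layer_size: int, guard: int):
        super().__init__(
            f"dp layer at depth {depth} holds {layer_size} nodes "
            f"(guard: {guard}); the layered graph is too large for this instance"
        )
        self.depth = depth
        self.layer_size = layer_size
        self.guard = guard


@dataclass(frozen=True)
class SearchSettings:
    """Grids, guards and reporting knobs for the outer MAP search."""

    ploidy_range: tuple[int, ...] = (2, 4, 6, 8, 10, 12, 14, 16)
    sigma_grid: tuple[float, ...] = (0.01, 0.02, 0.04, 0.08, 0.16, 0.32)
    p_resolution: float = 0.01
    epsilon_max: float = 0.01
    posterior_threshold: float = 0.8
    engine: str = "geometric"
    ploidy_tiebreak: str = "lowest"
    seed: int | None = None
    allow_odd_ploidy: bool = False
    naive_guard: int = 2_000_000
    dp_max_layer_nodes: int = 200_000

    def __post_init__(self) -> None:
        if not self.ploidy_range or not self.sigma_grid:
            raise ValueError("ploidy_range and sigma_grid must be nonempty")
        if not 0.0 < self.epsilon_max < 1.0:
            raise ValueError("epsilon_max must be in (0, 1)")
        if self.engine not in ("greedy", "naive", "dp", "geometric"):
            raise ValueError(f"unknown engine {self.engine!r}")


@dataclass
class FitResult:
    """MAP fit of one locus: parameters, configuration and posteriors."""

    m: int
    sigma: float
    theta: HWParams | F1Params | str
    assignment: dict[str, int]
    distribution: np.ndarray
    log_joint: float
    config_posterior: float
    individual_posteriors: dict[str, np.ndarray]
    n_params_searched: int
    visited_nodes: int = 0


class EngineResult(NamedTuple):
    assignment: np.ndarray  # dosage per individual, in the table's sorted order
    log_joint: float
    visited_nodes: int


def _safe_logF(F: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(np.asarray(F, dtype=float))


def log_multinomial(counts: np.ndarray, logF: np.ndarray) -> float:
    """Log multinomial pmf of dosage counts under frequency vector exp(logF).

    Returns -inf when a dosage with zero theoretical frequency has nonzero
    count (a validly excluded configuration).
    """
    counts = np.asarray(counts)
    n = int(counts.sum())
    mask = counts > 0
    if np.any(np.isneginf(logF[mask])):
        return NEG_INF
    return float(
        gammaln(n + 1) - gammaln(counts + 1).sum() + counts[mask] @ logF[mask]
    )


def log_joint(
    distribution: np.ndarray,
    config_loglik: float,
    F: np.ndarray,
    prior_terms: float = 0.0,
) -> float:
    """Joint log-score of a genotype distribution and its configuration likelihood."""
    return log_multinomial(distribution, _safe_logF(F)) + config_loglik + prior_terms


def counts_of(assignment: np.ndarray, m: int) -> np.ndarray:
    return np.bincount(np.asarray(assignment, dtype=int), minlength=m + 1)


def greedy_fit(table: LikelihoodTable, F: np.ndarray) -> EngineResult:
    """Per-individual maximum-likelihood dosages, scored under the joint model.

    Each individual independently gets its most likely dosage (ties broken
    toward the lower dosage); the induced distribution is then scored with
    the multinomial term.  Serves as the branch-and-bound incumbent.
    """
    g = np.argmax(table.logL, axis=1)
    ll = float(table.logL[np.arange(table.n), g].sum())
    joint = log_multinomial(counts_of(g, table.m), _safe_logF(F)) + ll
    return EngineResult(g, joint, 1)


def best_config_for_distribution(
    table: LikelihoodTable, counts: np.ndarray
) -> tuple[np.ndarray, float]:
    """Likelihood-optimal configuration with the given dosage counts.

    By the contiguity property, it assigns the first ``c_0`` individuals in
    sorted order to dosage 0, the next ``c_1`` to dosage 1, and so on: any
    non-contiguous assignment with the same counts admits a distance-reducing
    swap.  O(n) after the cached sort.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.sum() != table.n or len(counts) != table.m + 1:
        raise ValueError("counts must be a length-(m+1) vector summing to n")
    assignment = np.repeat(np.arange(table.m + 1), counts)
    ll = float(table.logL[np.arange(table.n), assignment].sum())
    return assignment, ll


def naive_map(
    table: LikelihoodTable, F: np.ndarray, *, guard: int = 2_000_000
) -> EngineResult:
    """Exhaustive MAP over all ``(m+1)^n`` configurations (test oracle).

    Enumeration is lexicographic in the assignment vector, so ties resolve
    to the lexicographically smallest assignment.  Refuses instances beyond
    the configuration-count guard.
    """
    n, m = table.n, table.m
    n_configs = (m + 1) ** n
    if n_configs > guard:
        raise NaiveSizeError(
            f"naive enumeration of {n_configs} configurations exceeds guard {guard}"
        )
    configs = np.indices((m + 1,) * n).reshape(n, -1).T  # lexicographic order
    ll = table.logL[np.arange(n)[None, :], configs].sum(axis=1)
    counts = np.stack([(configs == g).sum(axis=1) for g in range(m + 1)], axis=1)
    logF = _safe_logF(F)
    finite = np.isfinite(logF)
    logF_safe = np.where(finite, logF, 0.0)
    mult = gammaln(n + 1) - gammaln(counts + 1).sum(axis=1) + counts @ logF_safe
    if not finite.all():
        mult[(counts[:, ~finite] > 0).any(axis=1)] = NEG_INF
    joint = ll + mult
    k = int(np.argmax(joint))
    return EngineResult(configs[k].copy(), float(joint[k]), n_configs)


def geometric_map(
    table: LikelihoodTable,
    F: np.ndarray,
    incumbent: float = NEG_INF,
    *,
    incumbent_assignment: np.ndarray | None = None,
    prune_floor: float = NEG_INF,
) -> EngineResult:
    """Exact MAP via geometric branch and bound over genotype distributions.

    The search tree enumerates distribution prefixes ``(c_0, ..., c_k)``;
    a prefix fixes the leading ``sum(c)`` individuals in sorted order to the
    closed dosage classes (contiguity).  A node's admissible upper bound is

        log n! + sum_{g<=k} (c_g log F_g - log c_g!)      (closed multinomial)
        + (n - s) log max_{g>k} F_g                        (open multinomial)
        + prefix log-likelihood                            (cached cumsums)
        + sum over unassigned individuals of max over open dosages of logL

    where the open-class multinomial bound is the exact maximum over suffix
    count allocations of ``sum_g (c_g log F_g - log c_g!)`` (the marginal
    gain of the ``c``-th individual in class ``g`` is ``log F_g - log c``,
    decreasing in ``c``, so the maximum is the sum of the ``n - s`` largest
    gains over open classes).  Subtrees with bound
    <= max(best-so-far, prune_floor) are pruned; with ``prune_floor=-inf``
    the returned optimum is exact and independent of the incumbent.
    ``prune_floor`` implements the tau-slack used when marginalizing over
    parameter settings: the returned value may then undershoot the true MAP
    by a provably bounded amount, never overshoot.
    """
    n, m = table.n, table.m
    logF = _safe_logF(F)
    CL = table.col_cumsum
    SM = table.suffix_max
    lg = gammaln(np.arange(n + 1) + 1.0)
    log_nfact = float(lg[n])

    # suffix_mult[k][R]: max over allocations of R individuals to open
    # classes g >= k of sum_g (c_g log F_g - log c_g!); index m+1: none open
    with np.errstate(invalid="ignore"):
        gains = logF[:, None] - np.log(np.arange(1, n + 1))[None, :]
    gains[np.isnan(gains)] = NEG_INF
    suffix_mult = np.full((m + 2, n + 1), NEG_INF)
    suffix_mult[:, 0] = 0.0
    for k in range(m, -1, -1):
        flat = np.sort(gains[k:].ravel())[::-1][:n]
        suffix_mult[k, 1:] = np.cumsum(flat)

    # child ordering: counts near the greedy distribution first, for strong
    # incumbents early (correctness is unaffected by the order)
    greedy_counts = counts_of(np.argmax(table.logL, axis=1), m)

    best = incumbent
    best_counts: np.ndarray | None = None
    visited = 0
    counts = [0] * (m + 1)

    def dfs(k: int, s: int, prefix_ll: float, prefix_mult: float) -> None:
        nonlocal best, best_counts, visited
        visited += 1
        remaining = n - s
        if k == m:
            c = remaining
            if c > 0 and np.isneginf(logF[m]):
                return
            freq_term = c * logF[m] if c > 0 else 0.0
            total = (
                log_nfact
                + prefix_mult
                + freq_term
                - lg[c]
                + prefix_ll
                + (CL[m][n] - CL[m][s])
            )
            if total > best:
                best = total
                counts[m] = c
                best_counts = np.array(counts)
            return
        order = sorted(range(remaining + 1), key=lambda c: abs(c - greedy_counts[k]))
        closed_zero = np.isneginf(logF[k])
        for c in order:
            if closed_zero and c > 0:
                continue
            s2 = s + c
            ll2 = prefix_ll + (CL[k][s2] - CL[k][s])
            mult2 = prefix_mult + (c * logF[k] if c > 0 else 0.0) - lg[c]
            bound = log_nfact + mult2 + suffix_mult[k + 1][n - s2] + ll2 + SM[k + 1][s2]
            if bound > best and bound > prune_floor:
                counts[k] = c
                dfs(k + 1, s2, ll2, mult2)
        counts[k] = 0

    dfs(0, 0, 0.0, 0.0)

    if best_counts is None:
        if incumbent_assignment is None:
            raise RuntimeError(
                "search pruned every configuration and no incumbent was supplied"
            )
        return EngineResult(np.asarray(incumbent_assignment), best, visited)
    assignment = np.repeat(np.arange(m + 1), best_counts)
    return EngineResult(assignment, best, visited)


def dp_map(
    table: LikelihoodTable,
    F: np.ndarray,
    incumbent: float = NEG_INF,
    *,
    max_layer_nodes: int = 200_000,
) -> tuple[EngineResult, int]:
    """Exact MAP via a layered dynamic program over partial count vectors.

    Layer ``i`` holds one node per distinct count vector of the first ``i``
    sorted individuals, keeping the greatest prefix log-likelihood (prefixes
    with equal counts admit identical suffixes, so only the best need be
    kept).  Nodes are pruned when prefix likelihood plus the best possible
    suffix likelihood (multinomial log-pmf bounded by 0) cannot beat the
    incumbent — a deliberately conservative bound.  Aborts with
    :class:`DPMemoryError` when a layer exceeds the node guard, which on
    large-ploidy/large-sigma instances happens long before completion.

    Returns ``(engine_result, peak_layer_size)``.
    """
    n, m = table.n, table.m
    logF = _safe_logF(F)
    suffix_all = table.suffix_max[0]  # best unconstrained suffix likelihood
    # small slack so an incumbent equal to the optimum (e.g. the greedy
    # configuration when it is already MAP) is rediscovered, not pruned away
    cut = incumbent - 1e-9
    zero = (0,) * (m + 1)
    layers: list[dict[tuple, tuple[float, int]]] = [{zero: (0.0, -1)}]
    peak = 1
    visited = 1
    for i in range(n):
        prev = layers[-1]
        nxt: dict[tuple, tuple[float, int]] = {}
        row = table.logL[i]
        tail = suffix_all[i + 1]
        for key, (val, _) in prev.items():
            for g in range(m + 1):
                nv = val + row[g]
                if nv + tail <= cut:  # multinomial log-pmf <= 0
                    continue
                child = list(key)
                child[g] += 1
                ck = tuple(child)
                cur = nxt.get(ck)
                if cur is None or nv > cur[0]:
                    nxt[ck] = (nv, g)
        visited += len(nxt)
        if len(nxt) > max_layer_nodes:
            raise DPMemoryError(i + 1, len(nxt), max_layer_nodes)
        if not nxt:
            break
        peak = max(peak, len(nxt))
        layers.append(nxt)

    best = NEG_INF
    best_key = None
    if len(layers) == n + 1:
        for key, (val, _) in layers[n].items():
            total = val + log_multinomial(np.array(key), logF)
            if total > best:
                best = total
                best_key = key
    if best_key is None:
        raise RuntimeError(
            "dp search found no configuration above the incumbent; "
            "rerun with incumbent=-inf"
        )

    # backtrack the per-individual assignments through the layers
    assignment = np.empty(n, dtype=int)
    key = best_key
    for i in range(n, 0, -1):
        _, g = layers[i][key]
        assignment[i - 1] = g
        prev_key = list(key)
        prev_key[g] -= 1
        key = tuple(prev_key)
    return EngineResult(assignment, best, visited), peak


def tau_from_epsilon(epsilon_max: float, n_settings: int) -> float:
    """Slack factor guaranteeing posterior error <= epsilon_max.

    The absolute error of the approximate configuration posterior is bounded
    by tau times the number of parameter settings other than the MAP, so
    ``tau = epsilon / max(1, n_settings - 1)``.
    """
    if not 0.0 < epsilon_max < 1.0:
        raise ValueError("epsilon_max must be in (0, 1)")
    if n_settings < 1:
        raise ValueError("n_settings must be >= 1")
    return epsilon_max / max(1, n_settings - 1)


def approximate_posterior(scores: Mapping, map_setting) -> float:
    """Approximate posterior of the MAP setting from per-setting MAP joints.

    Normalizes exp(log_joint) of each searched setting's MAP configuration
    via log-sum-exp; settings pruned during search contribute whatever lower
    bound was recorded for them (0 in the worst case), keeping the result
    within the tau-accounted error of the exact normalization.
    """
    if map_setting not in scores:
        raise KeyError("map_setting missing from scores")
    values = np.array([v for v in scores.values() if v > NEG_INF])
    if values.size == 0:
        return 1.0
    return float(np.exp(scores[map_setting] - logsumexp(values)))


def individual_posteriors(table: LikelihoodTable) -> dict[str, np.ndarray]:
    """Per-individual dosage posteriors as relative likelihoods at the MAP setting.

    ``P_i(g) = exp(logL[i,g]) / sum_g' exp(logL[i,g'])`` — the normalized
    likelihood ratio between each dosage and the alternatives.
    """
    shifted = table.logL - logsumexp(table.logL, axis=1, keepdims=True)
    probs = np.exp(shifted)
    return {ind: probs[i] for i, ind in enumerate(table.individuals)}


def _run_engine(
    table: LikelihoodTable,
    F: np.ndarray,
    settings: SearchSettings,
    greedy: EngineResult,
    prune_floor: float,
) -> EngineResult:
    if settings.engine == "greedy":
        return greedy
    if settings.engine == "naive":
        return naive_map(table, F, guard=settings.naive_guard)
    if settings.engine == "dp":
        res, _ = dp_map(
            table, F, incumbent=NEG_INF, max_layer_nodes=settings.dp_max_layer_nodes
        )
        return res
    return geometric_map(
        table,
        F,
        incumbent=greedy.log_joint,
        incumbent_assignment=greedy.assignment,
        prune_floor=prune_floor,
    )


def fit(
    dataset: LocusDataset,
    settings: SearchSettings | None = None,
    model: str = "hw",
    custom_models: Mapping[str, np.ndarray] | None = None,
) -> FitResult:
    """Grid-search MAP fit of ploidy, sigma, population parameters and genotypes.

    Loops over every (m, sigma, theta) in the settings grids, computes the
    per-setting MAP configuration with the selected engine, and returns the
    global joint argmax with an approximate configuration posterior and
    per-individual dosage posteriors.  Ploidy ties resolve toward the lowest
    ploidy searched (Occam's razor on m).

    ``model`` is ``"hw"`` (theta = allele frequency on a grid), ``"f1"``
    (theta = parental dosage pair; parental replicate data, when present,
    enters as an additive log-likelihood on each candidate pair) or
    ``"custom"`` (theta indexes ``custom_models`` frequency vectors).
    """
    if settings is None:
        settings = SearchSettings()
    if model not in ("hw", "f1", "custom"):
        raise ValueError(f"unknown model {model!r}")
    if model == "custom" and not custom_models:
        raise ValueError("custom model requires custom_models vectors")
    if dataset.n_individuals == 0:
        raise ValueError("empty dataset")

    ploidies = sorted(settings.ploidy_range)
    for m in ploidies:
        if m % 2 and (model == "f1" or not settings.allow_odd_ploidy):
            raise ValueError(
                f"odd ploidy {m} requires the HW model with allow_odd_ploidy=True"
            )

    order = sorted_individuals(dataset)
    p_grid = allele_frequency_grid(settings.p_resolution)

    # theta candidates and log-priors per ploidy (sigma-independent parts)
    def thetas_for(m: int) -> list[tuple[object, np.ndarray, float]]:
        out: list[tuple[object, np.ndarray, float]] = []
        if model == "hw":
            lp = -math.log(len(p_grid))
            for p in p_grid:
                out.append((HWParams(float(p)), hw_frequencies(m, float(p)), lp))
        elif model == "f1":
            has_parents = dataset.has_parent_data
            lp = math.log(parent_pair_prior(m, has_parents))
            pairs = enumerate_parent_pairs(m, ordered=has_parents)
            for pair in pairs:
                out.append((pair, f1_frequencies(m, pair), lp))
        else:
            for pid, F in custom_models.items():
                if len(F) == m + 1:
                    out.append((pid, np.asarray(F, dtype=float), 0.0))
        return out

    # enumerate all settings with greedy joints first: the best greedy joint
    # seeds the tau-slack floor so clearly inferior settings prune at the root
    tables: dict[tuple[int, float], LikelihoodTable] = {}
    greedy_cache: dict[tuple[int, float], EngineResult] = {}
    parent_ll: dict[tuple[int, float], tuple[np.ndarray, np.ndarray]] = {}
    entries = []  # (key, table, F, log_prior, greedy_joint)
    for m in ploidies:
        theta_list = thetas_for(m)
        if not theta_list:
            continue
        for sigma in settings.sigma_grid:
            table = tables.setdefault((m, sigma), build_table(dataset, m, sigma, order=order))
            g_assign = np.argmax(table.logL, axis=1)
            g_ll = float(table.logL[np.arange(table.n), g_assign].sum())
            g_counts = counts_of(g_assign, m)
            if model == "f1" and dataset.has_parent_data:
                key_ms = (m, sigma)
                if key_ms not in parent_ll:
                    pl1 = np.array(
                        [
                            parent_data_likelihood(dataset.parent1_points, d, m, sigma)
                            for d in range(m + 1)
                        ]
                    )
                    pl2 = np.array(
                        [
                            parent_data_likelihood(dataset.parent2_points, d, m, sigma)
                            for d in range(m + 1)
                        ]
                    )
                    parent_ll[key_ms] = (pl1, pl2)
            for theta, F, lp in theta_list:
                prior = lp
                if model == "f1" and dataset.has_parent_data:
                    pl1, pl2 = parent_ll[(m, sigma)]
                    prior = lp + float(pl1[theta.p1]) + float(pl2[theta.p2])
                gj = log_multinomial(g_counts, _safe_logF(F)) + g_ll + prior
                greedy_cache[(m, sigma)] = EngineResult(g_assign, gj - prior, 1)
                entries.append(((m, sigma, theta), table, F, prior, gj))

    n_settings = len(entries)
    if n_settings == 0:
        raise ValueError("no parameter settings to search (check ploidy_range/model)")
    tau = tau_from_epsilon(settings.epsilon_max, n_settings)
    log_tau = math.log(tau)

    global_best = max(e[4] for e in entries)
    scores: dict[tuple, float] = {}
    best_joint = NEG_INF
    best_entry = None
    best_assignment = None
    total_visited = 0

    for key, table, F, prior, greedy_joint in entries:
        m, sigma, theta = key
        greedy = EngineResult(
            greedy_cache[(m, sigma)].assignment, greedy_joint - prior, 1
        )
        floor = log_tau + global_best - prior
        res = _run_engine(table, F, settings, greedy, floor)
        joint = res.log_joint + prior
        total_visited += res.visited_nodes
        scores[key] = joint
        if joint > global_best:
            global_best = joint
        if joint > best_joint:
            best_joint = joint
            best_entry = (key, table, F, prior)
            best_assignment = res.assignment

    (m, sigma, theta), table, F, prior = best_entry
    posterior = approximate_posterior(scores, (m, sigma, theta))
    assignment = {
        ind: int(best_assignment[i]) for i, ind in enumerate(table.individuals)
    }
    logger.info(
        "fit %s: MAP m=%d sigma=%g theta=%s log_joint=%.4f posterior=%.4g "
        "(%d settings, %d nodes visited)",
        dataset.locus_id,
        m,
        sigma,
        theta,
        best_joint,
        posterior,
        n_settings,
        total_visited,
    )
    return FitResult(
        m=m,
        sigma=sigma,
        theta=theta,
        assignment=assignment,
        distribution=counts_of(best_assignment, m),
        log_joint=best_joint,
        config_posterior=posterior,
        individual_posteriors=individual_posteriors(table),
        n_params_searched=n_settings,
        visited_nodes=total_visited,
    )
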