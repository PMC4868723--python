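"""Search-based feature selection: greedy stepwise and a genetic algorithm.

Both selectors maximize a class-separation evaluator computed on the
standardized data: the squared Euclidean distance between the tumor and
control centroids restricted to the candidate subset. Because squared
centroid distance is additive over features, three normalizations are
offered (``d2[j]`` is the squared standardized group-mean gap of
feature ``j``, ``k`` the subset size):

``"energy"`` (selector default)
    ``Σ d2[j] / √k`` — rewards adding a feature whose separation exceeds
    roughly half the subset mean, so hill-climbing recovers every strong
    feature and still terminates before noise features.
``"rms"``
    ``√(Σ d2[j]) / √k`` — the per-feature root-mean-square gap; under
    strict hill-climbing this is maximized by the single best feature.
``"none"``
    the bare centroid distance ``√(Σ d2[j])``, monotone in the subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import MetabolomicsDataset
from .decomposition import standardize

NORMALIZATIONS = ("energy", "rms", "none")
DEFAULT_NORMALIZATION = "energy"


@dataclass(frozen=True)
class FeatureSet:
    """An ordered metabolite subset with its evaluator score."""

    names: tuple[str, ...]
    score: float
    trace: tuple[float, ...] | None = field(default=None, compare=False)


@dataclass(frozen=True)
class GaParams:
    """Genetic-search parameters (defaults follow the published run)."""

    population_size: int = 20
    generations: int = 20
    p_crossover: float = 0.6
    p_mutation: float = 0.033
    report_frequency: int = 20
    seed: int = 1

    def __post_init__(self) -> None:
        if self.population_size < 1 or self.generations < 1:
            raise ValueError("population_size and generations must be >= 1")
        if not (0 <= self.p_crossover <= 1 and 0 <= self.p_mutation <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.report_frequency < 1:
            raise ValueError("report_frequency must be >= 1")


# ---------------------------------------------------------------------------
# evaluator
# ---------------------------------------------------------------------------

def squared_gaps(ds: MetabolomicsDataset) -> np.ndarray:
    """Per-metabolite squared standardized group-mean gap ``d2``.

    Group means are taken over non-missing entries of the standardized
    columns, so ``class_distance`` of any subset is a function of these.
    """
    Z = standardize(ds.values, ds.metabolite_names)
    Z = np.where(np.isnan(ds.values), np.nan, Z)
    mu_case = np.nanmean(Z[ds.case_mask], axis=0)
    mu_ctrl = np.nanmean(Z[ds.control_mask], axis=0)
    return (mu_case - mu_ctrl) ** 2


def _score(total_d2: float, k: int, normalization: str) -> float:
    if normalization == "rms":
        return math.sqrt(total_d2 / k)
    if normalization == "energy":
        return total_d2 / math.sqrt(k)
    if normalization == "none":
        return math.sqrt(total_d2)
    raise ValueError(f"unknown normalization {normalization!r}")


def class_distance(
    ds: MetabolomicsDataset,
    subset: list[str] | tuple[str, ...],
    normalization: str = "rms",
) -> float:
    """Separation between the tumor and control centroids on a subset.

    The default is the Euclidean centroid distance divided by √|subset|;
    see the module docstring for the other normalizations.
    """
    if not subset:
        raise ValueError("subset must be non-empty")
    d2 = squared_gaps(ds)
    idx = [ds.column_index(name) for name in subset]
    if len(set(idx)) != len(idx):
        raise ValueError("subset contains duplicate metabolites")
    return _score(float(d2[idx].sum()), len(idx), normalization)


# ---------------------------------------------------------------------------
# greedy stepwise
# ---------------------------------------------------------------------------

def greedy_stepwise(
    ds: MetabolomicsDataset,
    direction: str = "forward",
    normalization: str = DEFAULT_NORMALIZATION,
) -> FeatureSet:
    """Hill-climbing subset search without backtracking.

    Forward search starts from the empty set and repeatedly adds the
    feature with the largest evaluator gain, stopping when no addition
    strictly increases the score (the first feature is always added).
    Backward search symmetrically deletes from the full set. Ties are
    broken toward the lower column index; the result is deterministic.
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be forward or backward, got {direction!r}")
    d2 = squared_gaps(ds)
    p = d2.size
    names = ds.metabolite_names

    if direction == "forward":
        chosen: list[int] = []
        total = 0.0
        score = 0.0
        remaining = np.ones(p, dtype=bool)
        while remaining.any():
            cand = np.flatnonzero(remaining)
            cand_scores = np.array(
                [_score(total + d2[j], len(chosen) + 1, normalization) for j in cand]
            )
            best = cand[int(np.argmax(cand_scores))]
            best_score = float(cand_scores.max())
            if chosen and best_score <= score:
                break
            chosen.append(int(best))
            total += float(d2[best])
            score = best_score if chosen[1:] else _score(total, 1, normalization)
            remaining[best] = False
        return FeatureSet(tuple(names[j] for j in chosen), score)

    # backward: delete while some deletion strictly increases the score
    kept = list(range(p))
    total = float(d2.sum())
    score = _score(total, p, normalization)
    while len(kept) > 1:
        cand_scores = np.array(
            [_score(total - d2[j], len(kept) - 1, normalization) for j in kept]
        )
        i = int(np.argmax(cand_scores))
        if float(cand_scores[i]) <= score:
            break
        total -= float(d2[kept[i]])
        score = float(cand_scores[i])
        del kept[i]
    return FeatureSet(tuple(names[j] for j in kept), score)


# ---------------------------------------------------------------------------
# genetic search
# ---------------------------------------------------------------------------

def selection_probabilities(fitness: np.ndarray) -> np.ndarray:
    """Roulette-wheel probabilities ``p_i = f_i / Σ f``."""
    f = np.asarray(fitness, dtype=float)
    if f.size == 0 or (f < 0).any():
        raise ValueError("fitness must be non-negative and non-empty")
    total = f.sum()
    if total <= 0:
        raise ValueError("all-zero fitness: roulette selection is degenerate")
    return f / total


def roulette_select(probabilities: np.ndarray, r: float) -> int:
    """Index of the first chromosome whose cumulative probability exceeds ``r``."""
    if not 0 <= r <= 1:
        raise ValueError(f"r must lie in [0, 1], got {r}")
    q = np.cumsum(np.asarray(probabilities, dtype=float))
    if abs(q[-1] - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    idx = int(np.searchsorted(q, r, side="right"))
    return min(idx, len(q) - 1)


def genetic_search(
    ds: MetabolomicsDataset,
    params: GaParams | None = None,
    normalization: str = DEFAULT_NORMALIZATION,
) -> FeatureSet:
    """Generational GA over feature-presence bitstrings.

    Phases per generation: fitness evaluation (class-separation score of
    each chromosome's subset, 0 for the empty chromosome), roulette
    selection repeated ``population_size`` times, single-point crossover
    of randomly paired chromosomes with probability ``p_crossover``,
    independent bit flips with probability ``p_mutation``, full
    generational replacement. The best chromosome ever evaluated is
    returned; its per-generation record is available as ``trace``.
    """
    params = params or GaParams()
    rng = np.random.default_rng(params.seed)
    d2 = squared_gaps(ds)
    p = d2.size
    names = ds.metabolite_names

    def fitness_of(pop: np.ndarray) -> np.ndarray:
        k = pop.sum(axis=1)
        total = pop @ d2
        out = np.zeros(len(pop))
        nz = k > 0
        if normalization == "rms":
            out[nz] = np.sqrt(total[nz] / k[nz])
        elif normalization == "energy":
            out[nz] = total[nz] / np.sqrt(k[nz])
        else:
            out[nz] = np.sqrt(total[nz])
        return out

    n_pop = params.population_size
    population = rng.integers(0, 2, size=(n_pop, p), dtype=np.int8)
    fitness = fitness_of(population)

    best_bits = population[int(np.argmax(fitness))].copy()
    best_fit = float(fitness.max())
    trace = [best_fit]

    for _ in range(params.generations):
        # selection
        if fitness.sum() > 0:
            probs = selection_probabilities(fitness)
        else:
            probs = np.full(n_pop, 1.0 / n_pop)
        picks = [roulette_select(probs, rng.random()) for _ in range(n_pop)]
        new = population[picks].copy()

        # recombination: shuffle, pair adjacent; odd leftover passes unchanged
        order = rng.permutation(n_pop)
        for i in range(0, n_pop - 1, 2):
            if rng.random() < params.p_crossover and p > 1:
                point = int(rng.integers(1, p))
                a, b = order[i], order[i + 1]
                tail_a = new[a, point:].copy()
                new[a, point:] = new[b, point:]
                new[b, point:] = tail_a

        # mutation
        flips = rng.random((n_pop, p)) < params.p_mutation
        new[flips] ^= 1

        population = new
        fitness = fitness_of(population)
        gen_best = int(np.argmax(fitness))
        if float(fitness[gen_best]) > best_fit:
            best_fit = float(fitness[gen_best])
            best_bits = population[gen_best].copy()
        trace.append(best_fit)

    chosen = tuple(names[j] for j in np.flatnonzero(best_bits))
    return FeatureSet(chosen, best_fit, trace=tuple(trace))
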