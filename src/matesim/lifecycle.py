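"""One generation of the life cycle: mate selection, reproduction,
mutation, and density-dependent culling.

Mate selection is greedy on mutual attraction: the globally most mutually
attracted couple pairs first and leaves the market; every agent still on
the market then pays a small search cost, so agents who pair late pay the
most. Paired couples produce offspring in proportion to their pooled
fitness; offspring inherit trait values and preferences from their parents
(same-sex parent for dimorphic traits, a coin flip per value otherwise),
mutate, and are culled down to the population cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .population import FEMALE, MALE, Population

__all__ = [
    "PairSet",
    "mutual_attraction",
    "pair_agents",
    "count_offspring",
    "make_offspring",
    "reproduce",
    "mutate",
    "cull",
]


@dataclass
class PairSet:
    """Disjoint female-male pairs in the order they formed.

    ``females`` and ``males`` are row/column indices of the mutual
    attraction matrix; ``pairing_rank`` is the 0-based iteration at which
    each pair formed (rank r means both members paid r search-cost
    deductions before pairing).
    """

    females: np.ndarray
    males: np.ndarray
    pairing_rank: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.females) == len(self.males) == len(self.pairing_rank)):
            raise ValueError("pair arrays must share length")
        if len(set(self.females.tolist())) != len(self.females):
            raise ValueError("a female appears in two pairs")
        if len(set(self.males.tolist())) != len(self.males):
            raise ValueError("a male appears in two pairs")

    def __len__(self) -> int:
        return len(self.females)


def mutual_attraction(f_to_m: np.ndarray, m_to_f: np.ndarray) -> np.ndarray:
    """Element-wise product of the two directed attraction matrices.

    Pairing requires desire from both sides: a zero in either direction
    zeroes the couple's mutual attraction.
    """
    f_to_m = np.asarray(f_to_m, dtype=float)
    m_to_f = np.asarray(m_to_f, dtype=float)
    if f_to_m.shape != m_to_f.T.shape:
        raise ValueError(
            f"shape mismatch: f_to_m {f_to_m.shape} vs m_to_f {m_to_f.shape}"
        )
    return f_to_m * m_to_f.T


def pair_agents(mutual: np.ndarray, fitness_f: np.ndarray, fitness_m: np.ndarray,
                search_cost: float,
                ) -> tuple[PairSet, np.ndarray, np.ndarray]:
    """Greedy pairing by mutual attraction with iterative search costs.

    Repeatedly takes the global argmax cell of the mutual attraction matrix,
    records the pair, removes its row and column, and deducts
    ``search_cost`` fitness points from every still-unpaired agent of both
    sexes — until one sex is exhausted. Ties at the argmax break to the
    smallest (row, column) index. Returns the pairs plus updated fitness
    vectors; agents of the longer sex that never pair still pay every
    deduction (they die without reproducing).
    """
    if search_cost < 0:
        raise ValueError("search_cost must be non-negative")
    mutual = np.asarray(mutual, dtype=float)
    F, M = mutual.shape
    if len(fitness_f) != F or len(fitness_m) != M:
        raise ValueError("fitness vectors do not match matrix shape")
    n_pairs = min(F, M)
    females = np.empty(n_pairs, dtype=np.int64)
    males = np.empty(n_pairs, dtype=np.int64)
    if n_pairs:
        work = mutual.copy()
        for it in range(n_pairs):
            flat = int(np.argmax(work))  # first max in C order = smallest (row, col)
            i, j = divmod(flat, M)
            females[it] = i
            males[it] = j
            work[i, :] = -np.inf
            work[:, j] = -np.inf
    ranks = np.arange(n_pairs, dtype=np.int64)

    # A pair formed at rank r paid r deductions; unpaired agents paid one
    # per pairing event, n_pairs in total.
    paid_f = np.full(F, n_pairs, dtype=float)
    paid_m = np.full(M, n_pairs, dtype=float)
    paid_f[females] = ranks
    paid_m[males] = ranks
    new_f = np.asarray(fitness_f, dtype=float) - search_cost * paid_f
    new_m = np.asarray(fitness_m, dtype=float) - search_cost * paid_m
    return PairSet(females=females, males=males, pairing_rank=ranks), new_f, new_m


def count_offspring(fit_f: float, fit_m: float, reproduction_cost: float) -> int:
    """floor of the couple's pooled fitness over the reproduction cost,
    clamped at zero (search costs can erode fitness below one unit)."""
    if reproduction_cost <= 0:
        raise ValueError("reproduction_cost must be positive")
    return max(0, int(np.floor((fit_f + fit_m) / reproduction_cost)))


def _inherit(mother_vals: np.ndarray, father_vals: np.ndarray,
             sex: np.ndarray, dim: np.ndarray, config: ModelConfig,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-offspring trait and preference inheritance.

    ``mother_vals``/``father_vals`` are ((n, T) traits, (n, T, 4) prefs)
    already expanded to one row per offspring.
    """
    m_traits, m_prefs = mother_vals
    f_traits, f_prefs = father_vals
    n, T = m_traits.shape
    pick_t = rng.integers(0, 2, size=(n, T), dtype=np.int8)
    pick_p = rng.integers(0, 2, size=m_prefs.shape, dtype=np.int8)
    if len(dim):
        # dimorphic trait values and their four preference slots come from
        # the same-sex parent (sex coding matches pick coding: 0 = mother)
        pick_t[:, dim] = sex[:, None]
        pick_p[:, dim, :] = sex[:, None, None]
    traits = np.where(pick_t == 0, m_traits, f_traits)
    prefs = np.where(pick_p == 0, m_prefs, f_prefs)
    return traits, prefs


def make_offspring(mother: Population, father: Population, n_offspring: int,
                   config: ModelConfig, rng: np.random.Generator) -> Population:
    """Offspring of a single couple, pre-mutation.

    ``mother`` and ``father`` are single-agent populations. Each offspring
    draws a random sex; dimorphic traits (values and all four preference
    slots) copy from the same-sex parent, monomorphic values copy
    independently from a uniformly chosen parent, as does the algorithm
    label.
    """
    if not (len(mother) == len(father) == 1):
        raise ValueError("make_offspring expects single-agent parents")
    if mother.sex[0] != FEMALE or father.sex[0] != MALE:
        raise ValueError("couple must be (female, male)")
    n = int(n_offspring)
    sex = rng.integers(0, 2, size=n).astype(np.int8)
    dim = np.array(sorted(config.dimorphic_indices), dtype=np.int64)
    rep = np.zeros(n, dtype=np.int64)
    traits, prefs = _inherit(
        (mother.traits[rep], mother.prefs[rep]),
        (father.traits[rep], father.prefs[rep]),
        sex, dim, config, rng,
    )
    pick_a = rng.integers(0, 2, size=n)
    algorithm = np.where(pick_a == 0, mother.algorithm[rep], father.algorithm[rep])
    return Population(sex=sex, algorithm=algorithm, traits=traits, prefs=prefs,
                      fitness=np.zeros(n))


def reproduce(pop: Population, females: np.ndarray, males: np.ndarray,
              fitness_f: np.ndarray, fitness_m: np.ndarray,
              config: ModelConfig, rng: np.random.Generator) -> Population:
    """Offspring of all couples at once, pre-mutation.

    ``females``/``males`` index into ``pop``; ``fitness_f``/``fitness_m``
    are the couples' post-search-cost fitness values, which set offspring
    counts.
    """
    counts = np.maximum(
        0, np.floor((fitness_f + fitness_m) / config.reproduction_cost)
    ).astype(np.int64)
    moms = np.repeat(females, counts)
    dads = np.repeat(males, counts)
    n = len(moms)
    dim = np.array(sorted(config.dimorphic_indices), dtype=np.int64)
    sex = rng.integers(0, 2, size=n).astype(np.int8)
    traits, prefs = _inherit(
        (pop.traits[moms], pop.prefs[moms]),
        (pop.traits[dads], pop.prefs[dads]),
        sex, dim, config, rng,
    )
    pick_a = rng.integers(0, 2, size=n)
    algorithm = np.where(pick_a == 0, pop.algorithm[moms], pop.algorithm[dads])
    return Population(sex=sex, algorithm=algorithm, traits=traits, prefs=prefs,
                      fitness=np.zeros(n))


def mutate(pop: Population, config: ModelConfig,
           rng: np.random.Generator) -> Population:
    """Add independent normal noise to every trait and preference value.

    Traits are clamped back into bounds; preferences drift freely. Sex and
    algorithm never mutate.
    """
    if config.mutation_sd == 0:
        return pop
    lo, hi = config.trait_bounds
    traits = pop.traits + rng.normal(0.0, config.mutation_sd, size=pop.traits.shape)
    np.clip(traits, lo, hi, out=traits)
    prefs = pop.prefs + rng.normal(0.0, config.mutation_sd, size=pop.prefs.shape)
    return Population(sex=pop.sex, algorithm=pop.algorithm, traits=traits,
                      prefs=prefs, fitness=pop.fitness)


def cull(pop: Population, pop_cap: int, rng: np.random.Generator) -> Population:
    """Uniform random down-sampling to the population cap.

    Survival ignores sex, fitness, and algorithm — the cap introduces
    drift, nothing more.
    """
    if pop_cap <= 0:
        raise ValueError("pop_cap must be positive")
    if len(pop) <= pop_cap:
        return pop
    keep = np.sort(rng.choice(len(pop), size=pop_cap, replace=False))
    return pop.subset(keep)
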