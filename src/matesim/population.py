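"""Agent populations and the randomized fitness landscapes they evolve on.

Agents carry a sex, an attraction algorithm label, a vector of continuous
trait values on a 1-7 rating scale, and four unbounded preference
parameters per trait. Fitness is earned from a per-trait lookup table
mapping the seven integer trait levels to 1-7 fitness points; a handful of
sexually dimorphic traits get independent tables per sex.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, ModelConfig

__all__ = [
    "FEMALE",
    "MALE",
    "Population",
    "FitnessMaps",
    "init_population",
    "generate_fitness_maps",
    "score_fitness",
    "trait_levels",
]

FEMALE = 0
MALE = 1

_N_LEVELS = 7
_CURVILINEAR_BASE = np.array([1, 3, 5, 7, 5, 3, 1])


@dataclass
class Population:
    """Parallel arrays describing one generation of agents.

    ``sex`` holds 0 (female) / 1 (male); ``algorithm`` holds registry names;
    ``traits`` is (n, T) in trait bounds; ``prefs`` is (n, T, 4) and
    unbounded; ``fitness`` is (n,).
    """

    sex: np.ndarray
    algorithm: np.ndarray
    traits: np.ndarray
    prefs: np.ndarray
    fitness: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sex)
        if not (
            len(self.algorithm) == n
            and self.traits.shape[0] == n
            and self.prefs.shape[0] == n
            and len(self.fitness) == n
        ):
            raise ValueError("population arrays must share their first dimension")

    def __len__(self) -> int:
        return len(self.sex)

    @property
    def n_traits(self) -> int:
        return self.traits.shape[1]

    def subset(self, idx: np.ndarray) -> "Population":
        return Population(
            sex=self.sex[idx],
            algorithm=self.algorithm[idx],
            traits=self.traits[idx],
            prefs=self.prefs[idx],
            fitness=self.fitness[idx],
        )

    def sex_counts(self) -> tuple[int, int]:
        return int(np.sum(self.sex == FEMALE)), int(np.sum(self.sex == MALE))

    def to_frame(self) -> pd.DataFrame:
        """Snapshot as one row per agent (sex, algorithm, fitness, traits,
        preference slots)."""
        T = self.n_traits
        data: dict = {
            "sex": np.where(self.sex == FEMALE, "female", "male"),
            "algorithm": self.algorithm,
            "fitness": self.fitness,
        }
        for t in range(T):
            data[f"trait_{t + 1}"] = self.traits[:, t]
        for t in range(T):
            for s in range(self.prefs.shape[2]):
                data[f"pref_{t + 1}_{s + 1}"] = self.prefs[:, t, s]
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class FitnessMaps:
    """Per-trait, per-sex lookup from integer trait level to fitness points.

    ``points`` has shape (T, 2, 7): ``points[t, s, v - 1]`` is the fitness
    earned by sex ``s`` at trait level ``v``. Monomorphic traits share one
    table across both sexes.
    """

    points: np.ndarray
    dimorphic_indices: tuple[int, ...]

    @property
    def n_traits(self) -> int:
        return self.points.shape[0]

    def table(self, trait: int, sex: int) -> np.ndarray:
        return self.points[trait, sex]


def trait_levels(traits: np.ndarray, bounds: tuple[float, float] = (1.0, 7.0)) -> np.ndarray:
    """Integer trait levels 1..7 from continuous trait values.

    Rounds to the nearest level with .5 ties rounding up, which reproduces
    the model's printed offspring extremes (161 and 23 summed fitness
    points at the scale's ends).
    """
    levels = np.floor(np.asarray(traits, dtype=float) + 0.5).astype(np.int64)
    return np.clip(levels, int(round(bounds[0])), int(round(bounds[1])))


def init_population(config: ModelConfig, rng: np.random.Generator) -> Population:
    """Generate the parent population.

    Traits are normal draws (mean ``trait_init_mean``, SD ``trait_init_sd``)
    clamped into ``trait_bounds``; preferences are unclamped normal draws.
    Each roster entry contributes equal counts of females and males; fitness
    starts unscored (zero).
    """
    n = config.n_agents
    T = config.n_traits
    lo, hi = config.trait_bounds

    sexes = []
    algorithms = []
    for name, per_sex in config.algorithm_roster:
        sexes.extend([FEMALE] * per_sex + [MALE] * per_sex)
        algorithms.extend([name] * (2 * per_sex))
    sex = np.array(sexes, dtype=np.int8)
    algorithm = np.array(algorithms, dtype=object)
    if len(sex) != n:  # guarded already by ModelConfig, kept as a cheap invariant
        raise ConfigError("roster inconsistent with n_agents")

    traits = rng.normal(config.trait_init_mean, config.trait_init_sd, size=(n, T))
    np.clip(traits, lo, hi, out=traits)
    prefs = rng.normal(
        config.pref_init_mean, config.pref_init_sd, size=(n, T, config.n_pref_slots)
    )
    fitness = np.zeros(n)
    return Population(sex=sex, algorithm=algorithm, traits=traits, prefs=prefs,
                      fitness=fitness)


def _scrambled_block(n_rows: int, rng: np.random.Generator) -> np.ndarray:
    """Stack of per-row permutations of 1..7, then a global shuffle of all
    entries across rows — per-row totals end up unequal."""
    block = np.stack([rng.permutation(_N_LEVELS) + 1 for _ in range(n_rows)])
    flat = block.ravel()
    rng.shuffle(flat)
    return flat.reshape(n_rows, _N_LEVELS)


def generate_fitness_maps(config: ModelConfig, rng: np.random.Generator) -> FitnessMaps:
    """Draw a fresh fitness landscape for one model run.

    Modes:

    - ``random`` — independent uniform permutation of (1..7) per trait, so no
      two trait levels share a fitness value.
    - ``linear`` — per trait a random sign; positive maps levels to
      (1, 2, ..., 7), negative to (7, 6, ..., 1).
    - ``curvilinear`` — the tent (1, 3, 5, 7, 5, 3, 1) circularly shifted
      right by a random per-trait offset.
    - ``unequal`` — fitness points scrambled within and between traits, so
      per-trait totals differ (bijectivity per trait is not guaranteed).

    Dimorphic traits get independently drawn tables per sex; monomorphic
    traits share one table.
    """
    T = config.n_traits
    dim = np.array(sorted(config.dimorphic_indices), dtype=np.int64)
    mode = config.fitness_mode

    def draw_tables(n_rows: int) -> np.ndarray:
        if mode == "random":
            return np.stack([rng.permutation(_N_LEVELS) + 1 for _ in range(n_rows)])
        if mode == "linear":
            up = np.arange(1, _N_LEVELS + 1)
            signs = rng.integers(0, 2, size=n_rows)
            return np.stack([up if s else up[::-1] for s in signs])
        if mode == "curvilinear":
            shifts = rng.integers(0, _N_LEVELS, size=n_rows)
            return np.stack([np.roll(_CURVILINEAR_BASE, k) for k in shifts])
        if mode == "unequal":
            return _scrambled_block(n_rows, rng)
        raise ConfigError(f"unknown fitness_mode {mode!r}")

    shared = draw_tables(T)
    points = np.repeat(shared[:, None, :], 2, axis=1)
    if len(dim):
        # independent redraw per sex for the dimorphic traits
        points[dim, FEMALE, :] = draw_tables(len(dim))
        points[dim, MALE, :] = draw_tables(len(dim))
    return FitnessMaps(points=points, dimorphic_indices=tuple(int(i) for i in dim))


def score_fitness(pop: Population, maps: FitnessMaps,
                  bounds: tuple[float, float] = (1.0, 7.0)) -> np.ndarray:
    """Sum each agent's per-trait fitness points under the current landscape.

    Continuous trait values are scored at their nearest integer level.
    """
    if maps.n_traits != pop.n_traits:
        raise ValueError("fitness maps do not cover the population's traits")
    lo, hi = bounds
    if np.any(pop.traits < lo - 1e-12) or np.any(pop.traits > hi + 1e-12):
        raise ValueError("trait values outside bounds; clamp before scoring")
    levels = trait_levels(pop.traits, bounds)
    t_idx = np.arange(pop.n_traits)[None, :]
    per_trait = maps.points[t_idx, pop.sex[:, None], levels - 1]
    return per_trait.sum(axis=1).astype(float)
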