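"""Orchestration: generations, runs, and multi-run experiment summaries.

A *run* draws a fresh random fitness landscape, initializes a population,
and iterates the life cycle for a fixed number of generations, recording
each algorithm's population size along the way. An *experiment* repeats
runs with independent seed streams and aggregates dominance / fixation /
extinction proportions and mean trajectories with 95% confidence
intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lifecycle
from .algorithms import compute_attraction_matrices
from .config import ModelConfig
from .population import (
    FEMALE,
    MALE,
    FitnessMaps,
    Population,
    generate_fitness_maps,
    init_population,
    score_fitness,
)

__all__ = [
    "RunTrace",
    "ExperimentSummary",
    "run_generation",
    "run_model",
    "run_experiment",
]

logger = logging.getLogger(__name__)


@dataclass
class RunTrace:
    """Record of a single model run.

    ``sizes`` holds one row per generation (0 = initial population) and one
    column per algorithm. ``final_parents`` and ``final_pairs`` are the
    population that entered the last completed mate-selection stage and the
    pairs it formed — the "final generation couples" used by the
    couples-level analyses. ``final_population`` is the offspring
    population after the last generation.
    """

    sizes: pd.DataFrame
    final_population: Population
    final_parents: Population | None
    final_pairs: lifecycle.PairSet | None
    final_pair_indices: tuple[np.ndarray, np.ndarray] | None
    extinct_at: int | None = None


@dataclass
class ExperimentSummary:
    """Aggregates across independent runs of one configuration.

    Proportions are over runs: *dominant* = strictly largest final
    population (ties credit every tied algorithm), *fixed* = all competitors
    extinct, *extinct* = own final size zero.
    """

    algorithms: tuple[str, ...]
    n_runs: int
    dominant: dict[str, float]
    fixed: dict[str, float]
    extinct: dict[str, float]
    final_mean: dict[str, float]
    final_ci: dict[str, tuple[float, float]]
    trajectories: pd.DataFrame
    mean_trajectory: pd.DataFrame
    traces: list[RunTrace] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.algorithms:
            lo, hi = self.final_ci[name]
            rows.append(
                {
                    "algorithm": name,
                    "dominant": self.dominant[name],
                    "fixed": self.fixed[name],
                    "extinct": self.extinct[name],
                    "final_mean": self.final_mean[name],
                    "final_ci_lo": lo,
                    "final_ci_hi": hi,
                }
            )
        return pd.DataFrame(rows)


def _algorithm_sizes(pop: Population, names: tuple[str, ...]) -> dict[str, int]:
    return {name: int(np.sum(pop.algorithm == name)) for name in names}


def run_generation(pop: Population, maps: FitnessMaps, config: ModelConfig,
                   rng: np.random.Generator,
                   ) -> tuple[Population, lifecycle.PairSet | None,
                              tuple[np.ndarray, np.ndarray] | None]:
    """One full life cycle.

    Attraction -> within-algorithm scaling -> mutual attraction -> greedy
    pairing with search costs -> reproduction -> mutation -> fitness
    scoring -> culling. Returns the offspring population, the pairs formed,
    and the pairs as indices into ``pop``.
    """
    n_f, n_m = pop.sex_counts()
    if n_f == 0 or n_m == 0:
        logger.info("a sex is extinct (%d females, %d males); run ends", n_f, n_m)
        empty = pop.subset(np.array([], dtype=np.int64))
        return empty, None, None

    f_to_m, m_to_f, f_idx, m_idx = compute_attraction_matrices(pop, config, rng)
    mutual = lifecycle.mutual_attraction(f_to_m, m_to_f)
    pairs, fit_f, fit_m = lifecycle.pair_agents(
        mutual, pop.fitness[f_idx], pop.fitness[m_idx], config.search_cost
    )
    offspring = lifecycle.reproduce(
        pop,
        f_idx[pairs.females],
        m_idx[pairs.males],
        fit_f[pairs.females],
        fit_m[pairs.males],
        config,
        rng,
    )
    offspring = lifecycle.mutate(offspring, config, rng)
    if len(offspring):
        offspring.fitness = score_fitness(offspring, maps, config.trait_bounds)
    offspring = lifecycle.cull(offspring, config.pop_cap, rng)
    return offspring, pairs, (f_idx[pairs.females], m_idx[pairs.males])


def run_model(config: ModelConfig,
              rng: np.random.Generator | int | None = None) -> RunTrace:
    """One run: fresh fitness landscape, then ``n_generations`` life cycles.

    If a sex dies out the run terminates early; all later generation sizes
    are recorded as zero.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    names = tuple(dict.fromkeys(config.algorithm_names))
    maps = generate_fitness_maps(config, rng)
    pop = init_population(config, rng)
    pop.fitness = score_fitness(pop, maps, config.trait_bounds)

    size_rows = [_algorithm_sizes(pop, names)]
    final_parents: Population | None = None
    final_pairs: lifecycle.PairSet | None = None
    final_pair_idx: tuple[np.ndarray, np.ndarray] | None = None
    extinct_at: int | None = None

    for gen in range(1, config.n_generations + 1):
        parents = pop
        pop, pairs, pair_idx = run_generation(pop, maps, config, rng)
        if pairs is None:
            extinct_at = gen
            zero = {name: 0 for name in names}
            size_rows.extend([zero] * (config.n_generations - gen + 1))
            break
        final_parents, final_pairs, final_pair_idx = parents, pairs, pair_idx
        size_rows.append(_algorithm_sizes(pop, names))

    sizes = pd.DataFrame(size_rows, columns=list(names))
    sizes.index.name = "generation"
    return RunTrace(
        sizes=sizes,
        final_population=pop,
        final_parents=final_parents,
        final_pairs=final_pairs,
        final_pair_indices=final_pair_idx,
        extinct_at=extinct_at,
    )


def run_experiment(config: ModelConfig, n_runs: int, seed: int | None = None,
                   keep_traces: bool = False) -> ExperimentSummary:
    """Independent runs with per-run seed streams, aggregated.

    Per-run generators are spawned from a single seed sequence, so each run
    is individually reproducible. Mean trajectories average over all runs,
    including runs in which an algorithm has already gone extinct (zeros
    count).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    names = tuple(dict.fromkeys(config.algorithm_names))
    children = np.random.SeedSequence(seed).spawn(n_runs)
    traces = [run_model(config, np.random.default_rng(c)) for c in children]

    traj_rows = []
    for run_id, trace in enumerate(traces):
        long = trace.sizes.reset_index().melt(
            id_vars="generation", var_name="algorithm", value_name="size"
        )
        long.insert(0, "run", run_id)
        traj_rows.append(long)
    trajectories = pd.concat(traj_rows, ignore_index=True)

    grouped = trajectories.groupby(["generation", "algorithm"])["size"]
    mean_traj = grouped.agg(["mean", "std"]).reset_index()
    mean_traj["std"] = mean_traj["std"].fillna(0.0)
    half = 1.96 * mean_traj["std"] / np.sqrt(n_runs)
    mean_traj["ci_lo"] = mean_traj["mean"] - half
    mean_traj["ci_hi"] = mean_traj["mean"] + half

    finals = np.array(
        [[trace.sizes.iloc[-1][name] for name in names] for trace in traces],
        dtype=float,
    )
    dominant = {name: 0.0 for name in names}
    fixed = {name: 0.0 for name in names}
    extinct = {name: 0.0 for name in names}
    for row in finals:
        top = row.max()
        for i, name in enumerate(names):
            if row[i] == top and top > 0:
                dominant[name] += 1
            if row[i] > 0 and np.sum(row > 0) == 1:
                fixed[name] += 1
            if row[i] == 0:
                extinct[name] += 1
    for d in (dominant, fixed, extinct):
        for name in names:
            d[name] /= n_runs

    final_mean = {name: float(finals[:, i].mean()) for i, name in enumerate(names)}
    final_ci = {}
    for i, name in enumerate(names):
        sd = float(finals[:, i].std(ddof=1)) if n_runs > 1 else 0.0
        h = 1.96 * sd / np.sqrt(n_runs)
        final_ci[name] = (final_mean[name] - h, final_mean[name] + h)

    return ExperimentSummary(
        algorithms=names,
        n_runs=n_runs,
        dominant=dominant,
        fixed=fixed,
        extinct=extinct,
        final_mean=final_mean,
        final_ci=final_ci,
        trajectories=trajectories,
        mean_trajectory=mean_traj,
        traces=traces if keep_traces else [],
    )
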