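"""Model configuration: every tunable of the evolutionary simulation.

The defaults reproduce the full-scale competitive model (700 agents, seven
attraction algorithms with 50 agents per sex each, 200 generations). The
single-algorithm variants used for couples-level analyses start from 100
agents with a population cap of 200; use :func:`single_algorithm_config`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "ConfigError",
    "ModelConfig",
    "ALGORITHM_NAMES",
    "THRESHOLD_ALGORITHMS",
    "study_roster",
    "single_algorithm_config",
    "load_config",
]

#: Canonical registry keys for the seven preference-integration algorithms.
ALGORITHM_NAMES = (
    "regression",
    "threshold_regression",
    "polynomial",
    "euclidean",
    "threshold_euclidean",
    "aspiration",
    "random",
)

#: Algorithms whose attraction is zero for mates failing a threshold check.
#: Their zeros are preserved by within-algorithm scaling.
THRESHOLD_ALGORITHMS = frozenset(
    {"threshold_regression", "threshold_euclidean", "aspiration"}
)


class ConfigError(ValueError):
    """Raised for inconsistent or unknown configuration values."""


def study_roster(n_per_sex: int = 50) -> tuple[tuple[str, int], ...]:
    """Roster with all seven algorithms, ``n_per_sex`` agents per sex each."""
    return tuple((name, n_per_sex) for name in ALGORITHM_NAMES)


@dataclass(frozen=True)
class ModelConfig:
    """All tunables of the agent-based mate-choice model.

    Parameters
    ----------
    n_agents
        Initial population size (two sexes combined).
    pop_cap
        Maximum offspring population per generation; excess offspring are
        culled uniformly at random.
    n_traits
        Number of trait dimensions per agent (ratings on a 1-7 scale).
    n_pref_slots
        Preference parameters per trait (fixed at 4; what each slot means
        depends on the algorithm).
    trait_init_mean, trait_init_sd
        Initial trait distribution, normal draws clamped to ``trait_bounds``.
    pref_init_mean, pref_init_sd
        Initial preference distribution; preferences are never clamped.
    n_dimorphic, dimorphic_indices
        Number and identity (0-based) of sexually dimorphic traits, whose
        fitness maps are drawn independently per sex.
    search_cost
        Fitness points deducted from every still-unpaired agent after each
        pairing event.
    reproduction_cost
        Fitness points required per offspring unit; a couple produces
        ``floor((fitness_f + fitness_m) / reproduction_cost)`` offspring.
    mutation_sd
        SD of the normal noise added to every trait and preference value in
        each offspring.
    algorithm_roster
        Sequence of ``(algorithm name, agents per sex)``.
    scale_mean, scale_sd
        Target mean/SD of within-algorithm attraction scaling.
    aspiration_exponent
        Power applied to the count of satisfied aspirations.
    euclidean_epsilon
        Guard added to the squared distance before inversion.
    fitness_mode
        One of ``random``, ``linear``, ``curvilinear``, ``unequal``.
    """

    n_agents: int = 700
    pop_cap: int = 700
    n_traits: int = 23
    n_pref_slots: int = 4
    trait_init_mean: float = 4.0
    trait_init_sd: float = 1.5
    trait_bounds: tuple[float, float] = (1.0, 7.0)
    pref_init_mean: float = 0.0
    pref_init_sd: float = 1.5
    n_dimorphic: int = 5
    dimorphic_indices: tuple[int, ...] | None = None
    search_cost: float = 0.25
    reproduction_cost: float = 40.0
    mutation_sd: float = 0.5
    n_generations: int = 200
    algorithm_roster: tuple[tuple[str, int], ...] = field(
        default_factory=study_roster
    )
    scale_mean: float = 50.0
    scale_sd: float = 15.0
    aspiration_exponent: float = 15.0
    euclidean_epsilon: float = 1e-6
    fitness_mode: str = "random"
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "algorithm_roster", tuple(tuple(x) for x in self.algorithm_roster)
        )
        object.__setattr__(self, "trait_bounds", tuple(self.trait_bounds))
        if self.dimorphic_indices is None:
            object.__setattr__(
                self, "dimorphic_indices", tuple(range(self.n_dimorphic))
            )
        else:
            object.__setattr__(
                self, "dimorphic_indices", tuple(sorted(self.dimorphic_indices))
            )
        self._validate()

    def _validate(self) -> None:
        for name in ("n_agents", "pop_cap", "n_traits", "n_pref_slots",
                     "n_generations"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_pref_slots != 4:
            raise ConfigError("n_pref_slots is fixed at 4")
        lo, hi = self.trait_bounds
        if not lo < hi:
            raise ConfigError("trait_bounds lower must be < upper")
        for sd_name in ("trait_init_sd", "pref_init_sd", "mutation_sd"):
            if getattr(self, sd_name) < 0:
                raise ConfigError(f"{sd_name} must be non-negative")
        if self.search_cost < 0:
            raise ConfigError("search_cost must be non-negative")
        if self.reproduction_cost <= 0:
            raise ConfigError("reproduction_cost must be positive")
        if self.euclidean_epsilon <= 0:
            raise ConfigError("euclidean_epsilon must be positive")
        if self.aspiration_exponent <= 0:
            raise ConfigError("aspiration_exponent must be positive")
        if self.fitness_mode not in ("random", "linear", "curvilinear", "unequal"):
            raise ConfigError(f"unknown fitness_mode {self.fitness_mode!r}")
        if not self.algorithm_roster:
            raise ConfigError("algorithm_roster must not be empty")
        for name, count in self.algorithm_roster:
            if name not in ALGORITHM_NAMES:
                raise ConfigError(f"unknown algorithm {name!r}")
            if count <= 0:
                raise ConfigError(f"roster count for {name!r} must be positive")
        roster_total = 2 * sum(c for _, c in self.algorithm_roster)
        if roster_total != self.n_agents:
            raise ConfigError(
                f"roster implies {roster_total} agents but n_agents={self.n_agents}"
            )
        dim = set(self.dimorphic_indices)
        if len(dim) != self.n_dimorphic:
            raise ConfigError("dimorphic_indices must contain n_dimorphic indices")
        if dim and (min(dim) < 0 or max(dim) >= self.n_traits):
            raise ConfigError("dimorphic_indices out of trait range")

    @property
    def algorithm_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.algorithm_roster)

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["algorithm_roster"] = [list(x) for x in self.algorithm_roster]
        d["trait_bounds"] = list(self.trait_bounds)
        d["dimorphic_indices"] = list(self.dimorphic_indices)
        return d


def single_algorithm_config(algorithm: str, **overrides) -> ModelConfig:
    """Configuration for the small single-algorithm model variants.

    100 initial agents (50 per sex, one algorithm) with a population cap
    of 200; all other tunables as in the full competitive model.
    """
    defaults = dict(
        n_agents=100,
        pop_cap=200,
        algorithm_roster=((algorithm, 50),),
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)


def load_config(path: str | Path) -> ModelConfig:
    """Read a :class:`ModelConfig` from a YAML or JSON file.

    Unknown keys are rejected so that typos cannot silently fall back to
    defaults.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping of config fields")
    known = {f.name for f in dataclasses.fields(ModelConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    return ModelConfig(**data)
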