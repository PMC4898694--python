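"""Extract an ideal-preference point (one value per trait) per agent.

The Euclidean analytics need a single ideal vector per individual.
Euclidean agents carry theirs directly in preference slot 1. Polynomial
agents reveal theirs implicitly: per trait, the trait value that maximizes
their cubic attraction curve over the trait range. Aspiration agents'
ideals are the centers of their acceptable ranges (slot 3).
"""

from __future__ import annotations

import numpy as np

from .population import Population

__all__ = [
    "default_grid",
    "ideal_from_euclidean",
    "ideal_from_polynomial",
    "ideal_from_aspiration",
    "infer_ideals",
    "population_ideals",
]


def default_grid(bounds: tuple[float, float] = (1.0, 7.0),
                 step: float = 0.1) -> np.ndarray:
    """Candidate trait values for the polynomial argmax (default: 1 to 7 in
    steps of 0.1; pass ``step=1`` for a strictly integer reading)."""
    lo, hi = bounds
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def ideal_from_euclidean(prefs: np.ndarray) -> np.ndarray:
    """Slot-1 preferences are the ideal point by construction."""
    return np.asarray(prefs, dtype=float)[..., :, 0]


def ideal_from_polynomial(prefs: np.ndarray,
                          grid: np.ndarray | None = None) -> np.ndarray:
    """Per-trait argmax of p1*v + p2*v^2 + p3*v^3 over the candidate grid.

    The slot-4 intercept shifts the whole curve and cannot move the argmax.
    Ties resolve to the smallest candidate value. Accepts a single (T, 4)
    agent or a stacked (n, T, 4) array.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("candidate grid must be non-empty")
    p = np.asarray(prefs, dtype=float)
    single = p.ndim == 2
    if single:
        p = p[None]
    powers = np.stack([grid, grid**2, grid**3])  # (3, G)
    curves = np.einsum("nts,sg->ntg", p[:, :, :3], powers)
    idx = np.argmax(curves, axis=2)  # first max -> smallest grid value on ties
    ideals = grid[idx]
    return ideals[0] if single else ideals


def ideal_from_aspiration(prefs: np.ndarray) -> np.ndarray:
    """Center of the acceptable range: the slot-3 preferred value."""
    return np.asarray(prefs, dtype=float)[..., :, 2]


def infer_ideals(prefs: np.ndarray, algorithm: str,
                 grid: np.ndarray | None = None) -> np.ndarray:
    """Dispatch on algorithm name; only the three couples-analysis
    algorithms have a defined ideal point."""
    if algorithm == "euclidean":
        return ideal_from_euclidean(prefs)
    if algorithm == "polynomial":
        return ideal_from_polynomial(prefs, grid)
    if algorithm == "aspiration":
        return ideal_from_aspiration(prefs)
    raise ValueError(f"no ideal-point definition for algorithm {algorithm!r}")


def population_ideals(pop: Population, indices: np.ndarray,
                      grid: np.ndarray | None = None) -> np.ndarray:
    """Ideal vectors for the given agents, dispatching per-agent on their
    algorithm label."""
    indices = np.asarray(indices, dtype=np.int64)
    out = np.empty((len(indices), pop.n_traits))
    algs = pop.algorithm[indices]
    for name in np.unique(algs):
        mask = algs == name
        out[mask] = infer_ideals(pop.prefs[indices[mask]], str(name), grid)
    return out
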