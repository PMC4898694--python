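"""The seven preference-integration algorithms and attraction-matrix assembly.

Each algorithm reduces an agent's four preference parameters per trait and a
potential mate's trait vector to a single attraction value:

- ``regression`` — weighted sum: slot 1 is a slope, slot 2 an intercept.
- ``threshold_regression`` — slot 3 is an ideal value, slot 4 an acceptable
  half-range; mates failing any per-trait band check get attraction 0,
  passers are scored by the simple regression.
- ``polynomial`` — cubic: slots 1-3 weight t, t^2, t^3; slot 4 is an
  intercept.
- ``euclidean`` — inverse of the summed squared deviation between slot-1
  ideals and the mate's traits.
- ``threshold_euclidean`` — band check on slots 2 (ideal) and 3 (range),
  then the inverse squared distance to slot-1 ideals.
- ``aspiration`` — count of traits inside the slot-3/slot-4 band, raised to
  a high power, so near-complete satisfaction dominates.
- ``random`` — uniform noise in [0, 1) per potential mate.

Raw outputs live on wildly different scales, so each generation the values
are rescaled within algorithm to mean 50 / SD 15. Threshold algorithms are
scaled on their positive values only: zeros (rejected mates) stay zero.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist

from .config import THRESHOLD_ALGORITHMS, ModelConfig
from .population import FEMALE, MALE, Population

__all__ = [
    "attr_simple_regression",
    "attr_threshold_regression",
    "attr_polynomial",
    "attr_euclidean",
    "attr_threshold_euclidean",
    "attr_aspiration",
    "attr_random",
    "ALGORITHM_REGISTRY",
    "attraction_matrix",
    "compute_attraction_matrices",
    "scale_within_algorithm",
]

DEFAULT_EPSILON = 1e-6
DEFAULT_EXPONENT = 15.0


# ---------------------------------------------------------------------------
# scalar forms (one agent, one potential mate) — the reference definitions
# ---------------------------------------------------------------------------

def attr_simple_regression(prefs: np.ndarray, mate_traits: np.ndarray) -> float:
    """sum_t (p1_t * trait_t + p2_t); slots 3-4 unused."""
    prefs = np.asarray(prefs, dtype=float)
    t = np.asarray(mate_traits, dtype=float)
    return float(np.sum(prefs[:, 0] * t + prefs[:, 1]))


def _band_pass(ideal: np.ndarray, half_range: np.ndarray, t: np.ndarray) -> bool:
    """Inclusive symmetric band check on every trait; half-ranges are taken
    in absolute value since preferences may evolve negative."""
    return bool(np.all(np.abs(t - ideal) <= np.abs(half_range)))


def attr_threshold_regression(prefs: np.ndarray, mate_traits: np.ndarray) -> float:
    """Simple regression for mates inside every slot-3/slot-4 band, else 0."""
    prefs = np.asarray(prefs, dtype=float)
    t = np.asarray(mate_traits, dtype=float)
    if not _band_pass(prefs[:, 2], prefs[:, 3], t):
        return 0.0
    return attr_simple_regression(prefs, t)


def attr_polynomial(prefs: np.ndarray, mate_traits: np.ndarray) -> float:
    """sum_t (p1_t*t + p2_t*t^2 + p3_t*t^3 + p4_t)."""
    prefs = np.asarray(prefs, dtype=float)
    t = np.asarray(mate_traits, dtype=float)
    return float(
        np.sum(prefs[:, 0] * t + prefs[:, 1] * t**2 + prefs[:, 2] * t**3
               + prefs[:, 3])
    )


def attr_euclidean(prefs: np.ndarray, mate_traits: np.ndarray,
                   epsilon: float = DEFAULT_EPSILON) -> float:
    """1 / (sum_t (p1_t - trait_t)^2 + epsilon); slots 2-4 unused."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    prefs = np.asarray(prefs, dtype=float)
    t = np.asarray(mate_traits, dtype=float)
    return float(1.0 / (np.sum((prefs[:, 0] - t) ** 2) + epsilon))


def attr_threshold_euclidean(prefs: np.ndarray, mate_traits: np.ndarray,
                             epsilon: float = DEFAULT_EPSILON) -> float:
    """Inverse squared distance to slot-1 ideals for mates inside every
    slot-2/slot-3 band, else 0."""
    prefs = np.asarray(prefs, dtype=float)
    t = np.asarray(mate_traits, dtype=float)
    if not _band_pass(prefs[:, 1], prefs[:, 2], t):
        return 0.0
    return attr_euclidean(prefs, t, epsilon)


def attr_aspiration(prefs: np.ndarray, mate_traits: np.ndarray,
                    exponent: float = DEFAULT_EXPONENT) -> float:
    """k^exponent where k counts traits inside the slot-3/slot-4 band."""
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    prefs = np.asarray(prefs, dtype=float)
    t = np.asarray(mate_traits, dtype=float)
    k = int(np.sum(np.abs(t - prefs[:, 2]) <= np.abs(prefs[:, 3])))
    return float(k) ** exponent


def attr_random(rng: np.random.Generator) -> float:
    """Uniform attraction in [0, 1), independent per potential mate."""
    return float(rng.random())


ALGORITHM_REGISTRY: dict[str, Callable] = {
    "regression": attr_simple_regression,
    "threshold_regression": attr_threshold_regression,
    "polynomial": attr_polynomial,
    "euclidean": attr_euclidean,
    "threshold_euclidean": attr_threshold_euclidean,
    "aspiration": attr_aspiration,
    "random": attr_random,
}


# ---------------------------------------------------------------------------
# vectorized matrix kernels (a block of same-algorithm raters x all mates)
# ---------------------------------------------------------------------------

def _band_pass_matrix(ideal: np.ndarray, half_range: np.ndarray,
                      traits: np.ndarray) -> np.ndarray:
    # (R, T) ideals/ranges against (M, T) mate traits -> (R, M) bool
    dev = np.abs(traits[None, :, :] - ideal[:, None, :])
    return np.all(dev <= np.abs(half_range)[:, None, :], axis=2)


def attraction_matrix(name: str, prefs: np.ndarray, mate_traits: np.ndarray,
                      rng: np.random.Generator,
                      epsilon: float = DEFAULT_EPSILON,
                      exponent: float = DEFAULT_EXPONENT) -> np.ndarray:
    """Raw attraction of each rater (rows) to each opposite-sex mate
    (columns) under one algorithm.

    ``prefs`` is (R, T, 4); ``mate_traits`` is (M, T). Returns (R, M).
    """
    t = np.asarray(mate_traits, dtype=float)
    p = np.asarray(prefs, dtype=float)
    if name == "regression":
        return p[:, :, 0] @ t.T + p[:, :, 1].sum(axis=1, keepdims=True)
    if name == "threshold_regression":
        base = p[:, :, 0] @ t.T + p[:, :, 1].sum(axis=1, keepdims=True)
        passed = _band_pass_matrix(p[:, :, 2], p[:, :, 3], t)
        return np.where(passed, base, 0.0)
    if name == "polynomial":
        return (
            p[:, :, 0] @ t.T
            + p[:, :, 1] @ (t**2).T
            + p[:, :, 2] @ (t**3).T
            + p[:, :, 3].sum(axis=1, keepdims=True)
        )
    if name == "euclidean":
        sq = cdist(p[:, :, 0], t, metric="sqeuclidean")
        return 1.0 / (sq + epsilon)
    if name == "threshold_euclidean":
        sq = cdist(p[:, :, 0], t, metric="sqeuclidean")
        passed = _band_pass_matrix(p[:, :, 1], p[:, :, 2], t)
        return np.where(passed, 1.0 / (sq + epsilon), 0.0)
    if name == "aspiration":
        dev = np.abs(t[None, :, :] - p[:, None, :, 2])
        k = np.sum(dev <= np.abs(p[:, None, :, 3]), axis=2)
        return k.astype(float) ** exponent
    if name == "random":
        return rng.random((p.shape[0], t.shape[0]))
    raise KeyError(f"unknown algorithm {name!r}")


def scale_within_algorithm(f_to_m: np.ndarray, m_to_f: np.ndarray,
                           f_algorithms: np.ndarray, m_algorithms: np.ndarray,
                           scale_mean: float = 50.0, scale_sd: float = 15.0,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Rescale attraction values to mean ``scale_mean`` / SD ``scale_sd``
    within each algorithm, pooling that algorithm's rows of both matrices.

    Threshold-style algorithms are fitted on their strictly positive values
    only and their zeros (rejected mates) are preserved exactly. Degenerate
    pools (fewer than two values, or zero variance) map to the target mean.
    Values driven negative by the linear transform are clamped to 0 so the
    mutual-attraction product can never turn two rejections into a large
    positive.
    """
    f_out = f_to_m.astype(float).copy()
    m_out = m_to_f.astype(float).copy()
    names = set(np.unique(f_algorithms)) | set(np.unique(m_algorithms))
    for name in names:
        f_rows = np.flatnonzero(f_algorithms == name)
        m_rows = np.flatnonzero(m_algorithms == name)
        vals = np.concatenate([f_out[f_rows].ravel(), m_out[m_rows].ravel()])
        if vals.size == 0:
            continue
        preserve_zeros = name in THRESHOLD_ALGORITHMS
        fit_vals = vals[vals > 0] if preserve_zeros else vals
        if fit_vals.size < 2 or np.std(fit_vals, ddof=1) == 0:
            slope, intercept = 0.0, scale_mean
        else:
            sd = np.std(fit_vals, ddof=1)
            slope = scale_sd / sd
            intercept = scale_mean - slope * float(np.mean(fit_vals))

        def transform(block: np.ndarray) -> np.ndarray:
            scaled = slope * block + intercept
            if preserve_zeros:
                scaled = np.where(block == 0.0, 0.0, scaled)
            return np.maximum(scaled, 0.0)

        f_out[f_rows] = transform(f_out[f_rows])
        m_out[m_rows] = transform(m_out[m_rows])
    return f_out, m_out


def compute_attraction_matrices(pop: Population, config: ModelConfig,
                                rng: np.random.Generator,
                                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scaled female->male and male->female attraction matrices.

    Returns ``(f_to_m, m_to_f, f_idx, m_idx)`` where the index arrays map
    matrix rows/columns back to positions in ``pop``.
    """
    f_idx = np.flatnonzero(pop.sex == FEMALE)
    m_idx = np.flatnonzero(pop.sex == MALE)
    f_to_m = np.zeros((len(f_idx), len(m_idx)))
    m_to_f = np.zeros((len(m_idx), len(f_idx)))
    f_alg = pop.algorithm[f_idx]
    m_alg = pop.algorithm[m_idx]

    for name in dict.fromkeys(config.algorithm_names):  # stable order
        for rows_alg, rows_idx, out, targets in (
            (f_alg, f_idx, f_to_m, m_idx),
            (m_alg, m_idx, m_to_f, f_idx),
        ):
            rows = np.flatnonzero(rows_alg == name)
            if rows.size == 0:
                continue
            out[rows] = attraction_matrix(
                name,
                pop.prefs[rows_idx[rows]],
                pop.traits[targets],
                rng,
                epsilon=config.euclidean_epsilon,
                exponent=config.aspiration_exponent,
            )
    f_to_m, m_to_f = scale_within_algorithm(
        f_to_m, m_to_f, f_alg, m_alg, config.scale_mean, config.scale_sd
    )
    return f_to_m, m_to_f, f_idx, m_idx
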