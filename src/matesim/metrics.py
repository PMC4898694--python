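"""Euclidean analytics for couples: preference fulfillment and mate value.

Every metric lives in the same k-dimensional trait space (ratings on a 1-7
scale). *Absolute* preference fulfillment is the Euclidean distance between
a participant's ideal-preference point and their partner's trait point —
lower is better fulfilled. *Relative* fulfillment is the percentage of
opposite-sex alternatives in the sample lying strictly further from the
ideals than the actual partner. *Mate value* is the (inverse) distance
between one's own traits and the opposite sex's average ideal point.

All table-level functions operate on the couples-table schema defined in
:mod:`matesim.couples_data` (one row per participant; the ``partner``
block of a row describes that participant's opposite-sex partner).
"""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from . import couples_data

__all__ = [
    "euclidean_distance",
    "rescale_dimensions",
    "relative_fulfillment",
    "mate_value",
    "fulfillment_records",
    "mv_fulfillment_correlation",
    "bootstrap_summary",
    "mean_absolute_distance",
    "mean_relative_fulfillment",
    "model_fulfillment_summary",
]

logger = logging.getLogger(__name__)


def euclidean_distance(prefs: np.ndarray, traits: np.ndarray) -> float:
    """Straight-line distance between an ideal point and a trait point."""
    p = np.asarray(prefs, dtype=float)
    t = np.asarray(traits, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError(f"vectors must be 1-D and equal length, got {p.shape} vs {t.shape}")
    bad = np.flatnonzero(np.isnan(p) | np.isnan(t))
    if bad.size:
        raise ValueError(f"missing values in dimensions {bad.tolist()}")
    return float(np.sqrt(np.sum((p - t) ** 2)))


def rescale_dimensions(d: float | np.ndarray, k_from: int, k_to: int):
    """Map a distance measured in ``k_from`` dimensions to its equivalent in
    ``k_to`` dimensions, preserving the expected squared deviation per
    dimension: ``d * sqrt(k_to / k_from)``."""
    if k_from < 1 or k_to < 1:
        raise ValueError("dimension counts must be >= 1")
    return d * np.sqrt(k_to / k_from)


def relative_fulfillment(ideal: np.ndarray, partner_traits: np.ndarray,
                         alternative_traits: np.ndarray) -> float:
    """Percentage of alternatives strictly further from the ideals than the
    actual partner.

    Equidistant alternatives do not count as further. ``alternative_traits``
    is (n_alt, k) and must exclude the partner themselves.
    """
    alts = np.atleast_2d(np.asarray(alternative_traits, dtype=float))
    if alts.shape[0] < 1:
        raise ValueError("at least one alternative is required")
    own = euclidean_distance(ideal, partner_traits)
    alt_d = np.sqrt(np.sum((alts - np.asarray(ideal, dtype=float)) ** 2, axis=1))
    return 100.0 * float(np.sum(alt_d > own)) / alts.shape[0]


def mate_value(self_traits: np.ndarray, opposite_sex_ideals: np.ndarray,
               transform: str = "negate") -> float:
    """Inverse distance between own traits and the opposite sex's mean ideal.

    ``transform='negate'`` returns the negated distance (default; bounded
    and correlation-stable); ``'reciprocal'`` returns ``1 / distance``.
    Both are strictly decreasing in distance, so rankings agree.
    """
    ideals = np.atleast_2d(np.asarray(opposite_sex_ideals, dtype=float))
    if ideals.shape[0] < 1:
        raise ValueError("need at least one opposite-sex ideal vector")
    d = euclidean_distance(self_traits, ideals.mean(axis=0))
    if transform == "negate":
        return -d
    if transform == "reciprocal":
        return float(1.0 / d) if d > 0 else np.inf
    raise ValueError(f"unknown mate-value transform {transform!r}")


def fulfillment_records(table: pd.DataFrame, rescale_to: int | None = None,
                        mv_transform: str = "negate") -> pd.DataFrame:
    """Per-participant fulfillment (and, when self-ratings exist, mate value).

    For each participant the alternatives are every opposite-sex individual
    in the sample except their own partner; each such individual is
    represented by the ``partner`` block of their own spouse's row, so all
    trait descriptions come from the same rating source. Returns one row
    per participant with ``absolute_distance``, ``relative_percentile``,
    and ``mate_value`` (NaN when self-ratings are absent).
    """
    ideal = couples_data.block(table, "ideal")
    partner = couples_data.block(table, "partner")
    has_self = couples_data.has_block(table, "self")
    selfs = couples_data.block(table, "self") if has_self else None
    k = ideal.shape[1]
    sex = table["sex"].to_numpy()

    n = len(table)
    absolute = np.sqrt(np.sum((ideal - partner) ** 2, axis=1))
    relative = np.full(n, np.nan)
    mv = np.full(n, np.nan)

    for s, opp in (("female", "male"), ("male", "female")):
        rows = np.flatnonzero(sex == s)
        opp_rows = np.flatnonzero(sex == opp)
        if rows.size == 0:
            continue
        # partner vectors of same-sex rows describe the opposite-sex pool
        pool = partner[rows]
        if rows.size < 2:
            logger.warning("no alternatives for sex=%s; relative fulfillment undefined", s)
        else:
            D = cdist(ideal[rows], pool)
            own = absolute[rows]
            further = np.sum(D > own[:, None], axis=1)
            # own partner is one column of the pool; never strictly further
            relative[rows] = 100.0 * further / (rows.size - 1)
        if has_self and opp_rows.size:
            mean_ideal = ideal[opp_rows].mean(axis=0)
            d_self = np.sqrt(np.sum((selfs[rows] - mean_ideal) ** 2, axis=1))
            if mv_transform == "negate":
                mv[rows] = -d_self
            elif mv_transform == "reciprocal":
                with np.errstate(divide="ignore"):
                    mv[rows] = 1.0 / d_self
            else:
                raise ValueError(f"unknown mate-value transform {mv_transform!r}")

    if rescale_to is not None and rescale_to != k:
        absolute = rescale_dimensions(absolute, k, rescale_to)

    return pd.DataFrame(
        {
            "participant_id": table["participant_id"].to_numpy(),
            "couple_id": table["couple_id"].to_numpy(),
            "sex": sex,
            "absolute_distance": absolute,
            "relative_percentile": relative,
            "mate_value": mv,
        }
    )


def mv_fulfillment_correlation(records: pd.DataFrame) -> float:
    """Pearson correlation between mate value and ideal-to-partner distance.

    Fulfillment enters as the raw distance, so under the negated-distance
    mate-value transform a *negative* r means high-mate-value individuals
    hold partners closer to their ideals.
    """
    sub = records[["mate_value", "absolute_distance"]].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete records")
    x = sub["mate_value"].to_numpy()
    y = sub["absolute_distance"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: a column has zero variance")
    return float(pearsonr(x, y).statistic)


def bootstrap_summary(table: pd.DataFrame, statistic: Callable[[pd.DataFrame], float],
                      n_boot: int, rng: np.random.Generator,
                      ) -> tuple[float, tuple[float, float] | None]:
    """Percentile bootstrap over couples.

    Couples (both partners together) are resampled with replacement
    ``n_boot`` times; the point estimate is the mean of the statistic over
    bootstrap samples and the CI cuts off the most extreme 2.5% in both
    directions. ``n_boot=0`` returns the plain statistic with no CI.
    """
    if n_boot == 0:
        return float(statistic(table)), None
    if n_boot < 0:
        raise ValueError("n_boot must be >= 0")
    couples = table["couple_id"].unique()
    by_couple = {c: table[table["couple_id"] == c] for c in couples}
    stats = np.empty(n_boot)
    for b in range(n_boot):
        draw = rng.choice(couples, size=len(couples), replace=True)
        sample = pd.concat([by_couple[c] for c in draw], ignore_index=True)
        stats[b] = statistic(sample)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(stats.mean()), (float(lo), float(hi))


def mean_absolute_distance(table: pd.DataFrame,
                           rescale_to: int | None = None) -> float:
    """Sample mean of ideal-to-partner distances."""
    return float(fulfillment_records(table, rescale_to)["absolute_distance"].mean())


def mean_relative_fulfillment(table: pd.DataFrame) -> float:
    """Sample mean of relative-fulfillment percentiles."""
    return float(fulfillment_records(table)["relative_percentile"].mean())


def model_fulfillment_summary(tables: Sequence[pd.DataFrame], metric: str,
                              mv_transform: str = "negate",
                              ) -> tuple[float, tuple[float, float], np.ndarray]:
    """Across-run summary of a fulfillment metric on final-generation couples.

    ``metric`` is ``absolute`` (mean distance), ``relative`` (mean
    percentile), or ``correlation`` (mate value x distance Pearson r).
    Each run contributes one number; runs with no surviving couples are
    excluded with a log message. Returns (mean across runs, 95% CI from the
    across-run SD, per-run values).
    """
    per_run = []
    for i, t in enumerate(tables):
        if t is None or len(t) == 0:
            logger.warning("run %d has no surviving couples; excluded", i)
            continue
        recs = fulfillment_records(t, mv_transform=mv_transform)
        if metric == "absolute":
            per_run.append(recs["absolute_distance"].mean())
        elif metric == "relative":
            per_run.append(recs["relative_percentile"].mean())
        elif metric == "correlation":
            per_run.append(mv_fulfillment_correlation(recs))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    if len(per_run) < 2:
        raise ValueError("need at least 2 runs with surviving couples")
    vals = np.asarray(per_run, dtype=float)
    mean = float(vals.mean())
    half = 1.96 * float(vals.std(ddof=1)) / np.sqrt(len(vals))
    return mean, (mean - half, mean + half), vals
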