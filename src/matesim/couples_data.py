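"""Couples tables: I/O, validation, synthesis, and model export.

The common input of every metric is a *couples table*: one row per
participant with columns ``couple_id, participant_id, sex, ideal_1..k,
partner_1..k[, self_1..k]``. Each couple id maps to exactly one female and
one male row; all ratings live on the 1-7 scale. The ``partner`` block of
a row describes that participant's partner, so a given individual's traits
appear in their spouse's row.

The synthetic generator emulates the statistical structure the analyses
assume — ideal points, partner traits scattered around them, and an
optional planted gradient linking mate value to match quality — so the
full metrics pipeline is testable without any external data.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ideal_inference import population_ideals
from .population import FEMALE

__all__ = [
    "CouplesDataError",
    "SynthConfig",
    "block",
    "has_block",
    "read_couples_csv",
    "write_couples_csv",
    "validate_couples",
    "synth_couples",
    "couples_from_final_generation",
]

logger = logging.getLogger(__name__)

_ID_COLS = ["couple_id", "participant_id", "sex"]
_SCALE = (1.0, 7.0)


class CouplesDataError(ValueError):
    """Raised for malformed couples tables."""


def _block_cols(table: pd.DataFrame, name: str) -> list[str]:
    pat = re.compile(rf"^{name}_(\d+)$")
    cols = [(int(m.group(1)), c) for c in table.columns if (m := pat.match(c))]
    cols.sort()
    return [c for _, c in cols]


def has_block(table: pd.DataFrame, name: str) -> bool:
    return bool(_block_cols(table, name))


def block(table: pd.DataFrame, name: str) -> np.ndarray:
    """The (n, k) rating matrix for one block (``ideal``, ``partner``,
    ``self``)."""
    cols = _block_cols(table, name)
    if not cols:
        raise CouplesDataError(f"table has no {name!r} columns")
    return table[cols].to_numpy(dtype=float)


def validate_couples(table: pd.DataFrame, check_scale: bool = True) -> int:
    """Validate schema and couple structure; returns the dimension k."""
    missing = [c for c in _ID_COLS if c not in table.columns]
    if missing:
        raise CouplesDataError(f"missing required columns {missing}")
    ideal_cols = _block_cols(table, "ideal")
    partner_cols = _block_cols(table, "partner")
    if not ideal_cols or not partner_cols:
        raise CouplesDataError("table needs ideal_1..k and partner_1..k columns")
    k = len(ideal_cols)
    if len(partner_cols) != k:
        raise CouplesDataError(
            f"ideal block has {k} dimensions but partner block has {len(partner_cols)}"
        )
    self_cols = _block_cols(table, "self")
    if self_cols and len(self_cols) != k:
        raise CouplesDataError(
            f"self block has {len(self_cols)} dimensions, expected {k}"
        )
    expected = {f"ideal_{i+1}" for i in range(k)} | {f"partner_{i+1}" for i in range(k)}
    if not expected <= set(table.columns):
        raise CouplesDataError("ideal/partner columns are not contiguous 1..k")

    bad_sex = set(table["sex"].unique()) - {"female", "male"}
    if bad_sex:
        raise CouplesDataError(f"unknown sex labels {sorted(bad_sex)}")
    for cid, grp in table.groupby("couple_id"):
        sexes = sorted(grp["sex"].tolist())
        if sexes != ["female", "male"]:
            raise CouplesDataError(
                f"couple {cid!r} must have exactly one female and one male row, "
                f"got {sexes}"
            )
    if table["participant_id"].duplicated().any():
        raise CouplesDataError("participant ids must be unique")
    if check_scale:
        for name in ("ideal", "partner", "self"):
            if has_block(table, name):
                vals = block(table, name)
                if np.nanmin(vals) < _SCALE[0] - 1e-9 or np.nanmax(vals) > _SCALE[1] + 1e-9:
                    raise CouplesDataError(f"{name} ratings outside the 1-7 scale")
    return k


def read_couples_csv(path: str | Path, check_scale: bool = True) -> pd.DataFrame:
    """Read and validate a couples CSV.

    Rows with any missing ideal or partner cell are dropped (with their
    partner's row, to keep couples intact) and counted in the log.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except ValueError as exc:
        raise CouplesDataError(f"{path}: cannot parse ({exc})") from exc
    for c in [c for c in table.columns if c not in _ID_COLS]:
        if not pd.api.types.is_numeric_dtype(table[c]):
            raise CouplesDataError(f"{path}: non-numeric values in column {c!r}")

    ideal_cols = _block_cols(table, "ideal")
    partner_cols = _block_cols(table, "partner")
    if ideal_cols and partner_cols:
        incomplete = table[ideal_cols + partner_cols].isna().any(axis=1)
        if incomplete.any():
            bad_couples = set(table.loc[incomplete, "couple_id"])
            n_before = len(table)
            table = table[~table["couple_id"].isin(bad_couples)].reset_index(drop=True)
            logger.warning(
                "%s: dropped %d rows (%d couples) with missing ideal/partner ratings",
                path, n_before - len(table), len(bad_couples),
            )
    validate_couples(table, check_scale=check_scale)
    return table


def write_couples_csv(table: pd.DataFrame, path: str | Path) -> None:
    validate_couples(table, check_scale=False)
    table.to_csv(path, index=False)


@dataclass(frozen=True)
class SynthConfig:
    """Tunables of the synthetic couples generator.

    ``match_noise_sd`` sets the per-dimension scatter of partner traits
    around ideals; ``mv_coupling`` in [0, 1] plants a mate-value gradient:
    at 0 the scatter is independent of mate value, at 1 the least desirable
    participants' partners scatter with twice the average SD while the most
    desirable scatter near zero.
    """

    n_couples: int = 100
    k_dims: int = 23
    pref_mean: float = 4.0
    pref_sd: float = 1.5
    match_noise_sd: float = 1.0
    mv_coupling: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_couples < 1 or self.k_dims < 1:
            raise ValueError("n_couples and k_dims must be positive")
        if self.pref_sd < 0 or self.match_noise_sd < 0:
            raise ValueError("SDs must be non-negative")
        if not 0.0 <= self.mv_coupling <= 1.0:
            raise ValueError("mv_coupling must lie in [0, 1]")


def synth_couples(cfg: SynthConfig,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate a synthetic couples table with known structure.

    Ideals and self traits are clamped normal draws. Each participant's
    partner-description equals their own ideals plus noise; the noise SD
    rises with the participant's mate-value distance rank in proportion to
    ``mv_coupling``, planting a negative mate-value x fulfillment-distance
    dependence that the correlation machinery should recover.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_couples, cfg.k_dims
    lo, hi = _SCALE

    def draw(shape):
        return np.clip(rng.normal(cfg.pref_mean, cfg.pref_sd, shape), lo, hi)

    ideals = {s: draw((n, k)) for s in ("female", "male")}
    selfs = {s: draw((n, k)) for s in ("female", "male")}

    # mate-value distance of each participant to the opposite sex's mean ideal
    noise_scale = {}
    for s, opp in (("female", "male"), ("male", "female")):
        mean_opp_ideal = ideals[opp].mean(axis=0)
        d = np.sqrt(np.sum((selfs[s] - mean_opp_ideal) ** 2, axis=1))
        if n > 1:
            u = np.argsort(np.argsort(d)) / (n - 1)  # 0 = highest mate value
        else:
            u = np.zeros(1)
        noise_scale[s] = cfg.match_noise_sd * (1.0 + cfg.mv_coupling * (2.0 * u - 1.0))

    rows = []
    for s in ("female", "male"):
        partner = np.clip(
            ideals[s] + rng.normal(0.0, 1.0, (n, k)) * noise_scale[s][:, None],
            lo, hi,
        )
        for i in range(n):
            row: dict = {
                "couple_id": f"c{i:05d}",
                "participant_id": f"{s[0]}{i:05d}",
                "sex": s,
            }
            row.update({f"ideal_{j+1}": ideals[s][i, j] for j in range(k)})
            row.update({f"partner_{j+1}": partner[i, j] for j in range(k)})
            row.update({f"self_{j+1}": selfs[s][i, j] for j in range(k)})
            rows.append(row)
    table = pd.DataFrame(rows)
    validate_couples(table)
    return table


def couples_from_final_generation(trace, grid: np.ndarray | None = None) -> pd.DataFrame:
    """Couples table from the final mate-selection stage of a model run.

    One row per paired agent: ideals inferred from the agent's algorithm
    (direct slot for Euclidean, per-trait argmax for polynomial, band
    center for aspiration), partner block = the partner's trait vector,
    self block = the agent's own traits. Unpaired agents are excluded.
    Ratings are *not* scale-checked: inferred ideals are grid-bounded but
    partner traits are exact continuous values.
    """
    pop = trace.final_parents
    if pop is None or trace.final_pair_indices is None or len(trace.final_pairs) == 0:
        logger.warning("run has no final couples; returning empty table")
        return pd.DataFrame(columns=_ID_COLS)
    f_idx, m_idx = trace.final_pair_indices
    T = pop.n_traits
    n_c = len(f_idx)

    agents = np.concatenate([f_idx, m_idx])
    partners = np.concatenate([m_idx, f_idx])
    ideals = population_ideals(pop, agents, grid)
    data: dict = {
        "couple_id": [f"c{c:05d}" for c in range(n_c)] * 2,
        "participant_id": [f"a{int(a):05d}" for a in agents],
        "sex": ["female"] * n_c + ["male"] * n_c,
    }
    for j in range(T):
        data[f"ideal_{j+1}"] = ideals[:, j]
    for j in range(T):
        data[f"partner_{j+1}"] = pop.traits[partners, j]
    for j in range(T):
        data[f"self_{j+1}"] = pop.traits[agents, j]
    table = pd.DataFrame(data)
    validate_couples(table, check_scale=False)
    return table
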