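"""Demographic framework: from a suppressed census cross-tab to persons.

Three preparation steps precede expansion: ethnicity prioritization,
resolution of disclosure-suppressed cells, and proportional reallocation of
Unknown ethnicity / deprivation strata.  Expansion then materializes one
synthetic person per counted individual, with age drawn Uniform[Y, Y+1)
within each one-year band and the remaining demographics copied
deterministically from the stratum.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import ETHNICITY_PRIORITY, SMOKING_LEVELS, UNKNOWN
from .errors import FeasibilityError, ValidationError
from .io import CENSUS_COUNT_COLUMNS, CENSUS_STRATUM_COLUMNS, POPULATION_COLUMNS

logger = logging.getLogger(__name__)


def prioritize_ethnicity(reported: set[str]) -> str:
    """Collapse multiple reported ethnicities to one by the fixed priority order.

    The order runs Maori, Pacific, Indian, Chinese, OtherAsian, Other,
    European: a person reporting both Maori and European is recorded Maori.
    """
    if not reported:
        raise ValidationError("cannot prioritize an empty ethnicity set")
    unknown = reported - set(ETHNICITY_PRIORITY)
    if unknown:
        raise ValidationError(f"unknown ethnicity categories {sorted(unknown)}")
    for eth in ETHNICITY_PRIORITY:
        if eth in reported:
            return eth
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class SuppressionResolutionPolicy:
    """How to replace disclosure-suppressed counts (always integers in 1..5).

    ``uniform_1_5`` draws each suppressed cell independently and uniformly
    from {1..5} — the censoring rule bounds the truth, so a bounded uniform
    draw is the least-assumption fill.  ``total_constrained`` additionally
    conditions on a known row total when one is supplied, drawing uniformly
    from the feasible fill combinations.
    """

    strategy: str = "uniform_1_5"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("uniform_1_5", "total_constrained"):
            raise ValidationError(f"unknown suppression strategy {self.strategy!r}")


def resolve_suppressed_cells(
    strata: pd.DataFrame,
    policy: SuppressionResolutionPolicy | None = None,
    rng: np.random.Generator | None = None,
    row_totals: pd.Series | None = None,
) -> pd.DataFrame:
    """Replace every suppressed smoking count with an integer in [1, 5].

    Under ``total_constrained``, ``row_totals`` gives (for any subset of row
    indices) the known total count of the stratum; the suppressed cells of
    such a row are drawn uniformly from the fill combinations in {1..5}^k
    whose sum closes the gap to the total.  Rows without a supplied total
    fall back to independent uniform draws.
    """
    policy = policy or SuppressionResolutionPolicy()
    if rng is None:
        rng = np.random.default_rng(policy.rng_seed)
    out = strata.copy()
    counts = out[CENSUS_COUNT_COLUMNS]
    suppressed = counts.isna()
    if not suppressed.any().any():
        return out

    for idx in out.index[suppressed.any(axis=1)]:
        cols = [c for c in CENSUS_COUNT_COLUMNS if suppressed.at[idx, c]]
        k = len(cols)
        known_total = None
        if policy.strategy == "total_constrained" and row_totals is not None:
            if idx in row_totals.index and not pd.isna(row_totals.loc[idx]):
                known_total = int(row_totals.loc[idx])
        if known_total is None:
            fills = rng.integers(1, 6, size=k)
        else:
            numeric_sum = int(counts.loc[idx].dropna().sum())
            need = known_total - numeric_sum
            feasible = [
                combo
                for combo in itertools.product(range(1, 6), repeat=k)
                if sum(combo) == need
            ]
            if not feasible:
                raise FeasibilityError(
                    f"row {idx}: cannot fill {k} suppressed cell(s) with values "
                    f"in [1,5] summing to {need} (total {known_total})"
                )
            fills = feasible[rng.integers(len(feasible))]
        for col, val in zip(cols, fills):
            out.at[idx, col] = int(val)
    out[CENSUS_COUNT_COLUMNS] = out[CENSUS_COUNT_COLUMNS].astype("Int64")
    return out


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` over targets proportionally to ``weights``.

    Largest-remainder rounding: exact conservation of the total, ties broken
    by position (canonical category order).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValidationError("largest-remainder apportionment needs positive weights")
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    # stable sort => ties go to the earlier (canonical-order) category
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def redistribute_unknowns(strata: pd.DataFrame) -> pd.DataFrame:
    """Reallocate Unknown-ethnicity / Unknown-deprivation strata counts.

    Within each age-band x sex margin, counts held by Unknown rows are moved
    to the known-category rows of that margin in proportion to their known
    counts (largest-remainder rounding per smoking column, so the grand
    total is conserved exactly).  A margin whose known counts are all zero
    falls back to the overall known proportions, with a log entry.

    Requires suppression to be resolved first (integer counts only).
    """
    counts = strata[CENSUS_COUNT_COLUMNS]
    if counts.isna().any().any():
        raise ValidationError("resolve suppressed cells before redistributing unknowns")
    out = strata.copy()
    out[CENSUS_COUNT_COLUMNS] = counts.astype(np.int64)

    for var in ("ethnicity", "nzdep_quintile"):
        unknown_mask = out[var] == UNKNOWN
        if not unknown_mask.any():
            continue
        known = out[~unknown_mask]
        for (band, sex), grp in out[unknown_mask].groupby(
            ["age_band_low", "sex"], sort=False
        ):
            margin = known[(known["age_band_low"] == band) & (known["sex"] == sex)]
            pool = margin
            if margin.empty or margin[CENSUS_COUNT_COLUMNS].to_numpy().sum() == 0:
                logger.warning(
                    "margin (%s, %s) has no known %s counts; using overall proportions",
                    band, sex, var,
                )
                pool = known
                if pool[CENSUS_COUNT_COLUMNS].to_numpy().sum() == 0:
                    raise ValidationError(f"no known {var} counts anywhere")
            for col in CENSUS_COUNT_COLUMNS:
                moved = int(grp[col].sum())
                if moved == 0:
                    continue
                weights = pool[col].to_numpy(dtype=float)
                if weights.sum() == 0:  # keep column totals: spread over row totals
                    weights = pool[CENSUS_COUNT_COLUMNS].sum(axis=1).to_numpy(float)
                alloc = _largest_remainder(weights, moved)
                out.loc[pool.index, col] += alloc
        out = out[out[var] != UNKNOWN].copy()
    return out.reset_index(drop=True)


def expand_strata(
    strata: pd.DataFrame,
    rng: np.random.Generator,
    smoking_mode: str = "monte_carlo",
    id_prefix: str = "p",
) -> pd.DataFrame:
    """Expand a resolved cross-tab into one row per synthetic person.

    Ages are drawn Uniform[Y, Y+1) within each stratum's one-year band; sex,
    ethnicity and deprivation are copied deterministically.  Smoking is
    either copied from the count column each person originated in
    (``deterministic``, giving cell-exact smoking margins) or redrawn per
    person from the stratum's smoking proportions (``monte_carlo``, which
    treats self-reported smoking as the one census variable with real
    measurement variability).  Person count always equals the sum of counts.
    """
    if smoking_mode not in ("monte_carlo", "deterministic"):
        raise ValidationError(f"unknown smoking_mode {smoking_mode!r}")
    counts = strata[CENSUS_COUNT_COLUMNS]
    if counts.isna().any().any():
        raise ValidationError("cannot expand strata with suppressed cells")
    if (counts.to_numpy() < 0).any():
        raise ValidationError("negative count in cross-tab")
    if (strata["ethnicity"] == UNKNOWN).any() or (
        strata["nzdep_quintile"] == UNKNOWN
    ).any():
        raise ValidationError("cannot expand strata with Unknown categories")

    long = strata.melt(
        id_vars=CENSUS_STRATUM_COLUMNS,
        value_vars=CENSUS_COUNT_COLUMNS,
        var_name="smoking",
        value_name="n",
    )
    # preserve file order: strata in row order, smoking categories per stratum
    long["_row"] = np.tile(np.arange(len(strata)), len(CENSUS_COUNT_COLUMNS))
    long = long.sort_values(
        ["_row", "smoking"],
        key=lambda s: s.map({c: i for i, c in enumerate(CENSUS_COUNT_COLUMNS)})
        if s.name == "smoking"
        else s,
        kind="stable",
    )
    long["n"] = long["n"].astype(np.int64)
    reps = long["n"].to_numpy()
    total = int(reps.sum())

    pop = pd.DataFrame(
        {
            col: np.repeat(long[col].to_numpy(), reps)
            for col in CENSUS_STRATUM_COLUMNS + ["smoking"]
        }
    )
    pop["age"] = pop["age_band_low"].astype(float) + rng.random(total)

    if smoking_mode == "monte_carlo":
        # redraw smoking per person from the stratum's category proportions
        row_idx = np.repeat(long["_row"].to_numpy(), reps)
        probs = counts.to_numpy(dtype=float)
        row_sums = probs.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(row_sums > 0, probs / row_sums, 0.0)
        cdf = np.cumsum(probs, axis=1)[row_idx]
        u = rng.random(total)
        cat = (u[:, None] > cdf).sum(axis=1)
        pop["smoking"] = np.asarray(SMOKING_LEVELS, dtype=object)[cat]

    pop["person_id"] = [f"{id_prefix}{i:08d}" for i in range(total)]
    pop["nzdep_quintile"] = pop["nzdep_quintile"].astype(int)
    for col in ("diabetes", "prior_cvd", "ll_med", "bpl_med", "fam_hx"):
        pop[col] = pd.NA
    pop["sbp"] = np.nan
    pop["tc_hdl"] = np.nan
    return pop[POPULATION_COLUMNS]
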