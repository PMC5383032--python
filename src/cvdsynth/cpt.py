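"""Conditional probability tables and Monte Carlo assignment of risk factors.

A :class:`ConditionalProbabilityTable` maps combinations of conditioning
variables (age band, sex, ethnicity, deprivation, prior CVD ...) to a
categorical outcome distribution estimated by observed relative frequency.
Sparse cells — fewer than ``min_cell`` records — are re-estimated after
dropping the last conditioning variable, recursively, so that every
combination present in a target population resolves to a row; each row
records how many conditioning variables were dropped (``pooling_level``).

Outcomes are assigned per person by inverse-CDF sampling of a single
uniform draw against the row's cumulative distribution, with category order
fixed by the canonical lists in :mod:`cvdsynth.categories`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import (
    DISEASE_STATES,
    MEDICATION_STATES,
    SMOKING_LEVELS,
    age_band_label,
    disease_flags,
    medication_flags,
)
from .errors import SchemaError, ValidationError

_CANONICAL_OUTCOMES = {
    "smoking": list(SMOKING_LEVELS),
    "disease_state": list(DISEASE_STATES),
    "medication_state": list(MEDICATION_STATES),
}

#: Probability vectors must sum to one within this tolerance.
PROB_TOL = 1e-12


def _conditioning_frame(pop: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Materialize conditioning columns from a population.

    ``age_band`` is derived from continuous age; every other variable is
    taken as-is (booleans are compared as booleans).
    """
    out = pd.DataFrame(index=pop.index)
    for var in variables:
        if var == "age_band":
            out[var] = age_band_label(pop["age"]).to_numpy()
        elif var in pop.columns:
            out[var] = pop[var].to_numpy()
        else:
            raise SchemaError(f"conditioning variable {var!r} not in population")
    return out


@dataclass
class ConditionalProbabilityTable:
    conditioning_vars: list[str]
    outcome_var: str
    categories: list[str]
    #: per pooling level d (0 = full conditioning), a mapping from the
    #: truncated conditioning tuple to (probability vector, n records)
    levels: list[dict[tuple, tuple[np.ndarray, int]]] = field(repr=False)
    min_cell: int = 20

    def __post_init__(self) -> None:
        for level in self.levels:
            for key, (probs, _n) in level.items():
                probs = np.asarray(probs, dtype=float)
                if probs.min() < 0 or abs(probs.sum() - 1.0) > PROB_TOL:
                    raise ValidationError(
                        f"row {key}: probabilities must be non-negative and "
                        f"sum to 1 (got sum {probs.sum()!r})"
                    )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_probabilities(
        cls,
        conditioning_vars: list[str],
        outcome_var: str,
        categories: list[str],
        rows: dict[tuple, "np.ndarray | list[float]"],
        min_cell: int = 20,
        normalize: bool = False,
    ) -> "ConditionalProbabilityTable":
        """Build a table directly from known probabilities (no pooling levels).

        ``normalize`` rescales each row to sum to exactly 1 — intended for
        rows transcribed from rounded published percentages.
        """
        def _vec(v):
            v = np.asarray(v, dtype=float)
            return v / v.sum() if normalize else v

        level0 = {
            tuple(k) if isinstance(k, tuple) else (k,): (_vec(v), 0)
            for k, v in rows.items()
        }
        n_levels = len(conditioning_vars) + 1
        levels: list[dict] = [level0] + [{} for _ in range(n_levels - 1)]
        return cls(list(conditioning_vars), outcome_var, list(categories),
                   levels, min_cell)

    # -- resolution & sampling --------------------------------------------

    def resolve(self, combo: tuple) -> tuple[np.ndarray, int]:
        """Return (probability vector, pooling level) for one combination.

        Walks up the pooling hierarchy until a row with at least
        ``min_cell`` records is found; the topmost (unconditional) row is
        used regardless of size.  Raises if no level can resolve the
        combination.
        """
        n_vars = len(self.conditioning_vars)
        for depth in range(n_vars + 1):
            key = tuple(combo[: n_vars - depth])
            entry = self.levels[depth].get(key)
            if entry is None:
                continue
            probs, n = entry
            if n >= self.min_cell or n == 0 or depth == n_vars:
                return probs, depth
            # directly-specified rows (n recorded as 0) always resolve above
        # fall back to any coarser row even if sparse, before giving up
        for depth in range(n_vars + 1):
            key = tuple(combo[: n_vars - depth])
            if key in self.levels[depth]:
                return self.levels[depth][key][0], depth
        raise ValidationError(
            f"combination {combo!r} of {self.conditioning_vars} is not "
            "resolvable in the CPT even after full pooling"
        )

    def as_frame(self) -> pd.DataFrame:
        """All rows at all pooling levels as one tidy frame.

        Dropped conditioning variables are left empty; ``pooling_level``
        counts how many were dropped.
        """
        records = []
        n_vars = len(self.conditioning_vars)
        for depth, level in enumerate(self.levels):
            for key, (probs, n) in level.items():
                rec: dict = {"pooling_level": depth, "n": n}
                for i, var in enumerate(self.conditioning_vars):
                    rec[var] = key[i] if i < n_vars - depth else ""
                for cat, p in zip(self.categories, probs):
                    rec[f"p_{cat}"] = p
                records.append(rec)
        cols = (self.conditioning_vars
                + [f"p_{c}" for c in self.categories]
                + ["n", "pooling_level"])
        return pd.DataFrame.from_records(records)[cols]

    def write(self, path: str | os.PathLike) -> None:
        frame = self.as_frame()
        frame.insert(0, "outcome_var", self.outcome_var)
        frame.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read(cls, path: str | os.PathLike) -> "ConditionalProbabilityTable":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        prob_cols = [c for c in df.columns if c.startswith("p_")]
        categories = [c[2:] for c in prob_cols]
        conditioning = [
            c for c in df.columns
            if c not in {"outcome_var", "n", "pooling_level", *prob_cols}
        ]
        outcome_var = df["outcome_var"].iloc[0]
        n_vars = len(conditioning)
        levels: list[dict] = [{} for _ in range(n_vars + 1)]
        for _, row in df.iterrows():
            depth = int(row["pooling_level"])
            key = tuple(_parse_key(row[v]) for v in conditioning[: n_vars - depth])
            probs = np.array([float(row[c]) for c in prob_cols])
            levels[depth][key] = (probs, int(row["n"]))
        return cls(conditioning, outcome_var, categories, levels)


def _parse_key(value: str):
    """Recover typed conditioning values from serialized strings."""
    if value in ("True", "False"):
        return value == "True"
    try:
        return int(value)
    except ValueError:
        return value


def estimate_cpt(
    records: pd.DataFrame,
    conditioning_vars: list[str],
    outcome_var: str,
    categories: list[str] | None = None,
    min_cell: int = 20,
) -> ConditionalProbabilityTable:
    """Estimate a CPT by observed relative frequency, with recursive pooling.

    Frequency tables are computed at every pooling level (full conditioning
    down to the unconditional distribution); a combination whose full-depth
    cell holds fewer than ``min_cell`` records resolves to the nearest
    ancestor meeting the threshold.
    """
    if len(records) == 0:
        raise ValidationError("cannot estimate a CPT from zero records")
    if categories is None:
        categories = _CANONICAL_OUTCOMES.get(outcome_var)
    if categories is None:
        categories = sorted(records[outcome_var].unique())
    cond = _conditioning_frame(records, conditioning_vars)
    outcome = records[outcome_var]
    bad = ~outcome.isin(categories)
    if bad.any():
        raise SchemaError(
            f"outcome {outcome_var!r} has values outside {categories}: "
            f"{sorted(outcome[bad].unique())}"
        )
    present = set(outcome.unique())
    absent = [c for c in categories if c not in present]
    if absent:
        raise ValidationError(
            f"outcome category {absent} absent from all records"
        )

    n_vars = len(conditioning_vars)
    levels: list[dict] = []
    for depth in range(n_vars + 1):
        keys = conditioning_vars[: n_vars - depth]
        if keys:
            grouped = (
                pd.crosstab([cond[k] for k in keys], outcome)
                .reindex(columns=categories, fill_value=0)
            )
            level = {}
            for key, row in grouped.iterrows():
                key = key if isinstance(key, tuple) else (key,)
                n = int(row.sum())
                level[key] = (row.to_numpy(dtype=float) / n, n)
        else:
            counts = outcome.value_counts().reindex(categories, fill_value=0)
            n = int(counts.sum())
            level = {(): (counts.to_numpy(dtype=float) / n, n)}
        levels.append(level)
    return ConditionalProbabilityTable(
        list(conditioning_vars), outcome_var, list(categories), levels, min_cell
    )


def assign_categorical(
    pop: pd.DataFrame,
    cpt: ConditionalProbabilityTable,
    rng: np.random.Generator,
) -> pd.Series:
    """Draw one outcome category per person from the person's CPT row.

    One uniform is drawn per person (in person order) and inverted through
    the row's cumulative distribution, so the draw stream is independent of
    how persons group into rows.
    """
    cond = _conditioning_frame(pop, cpt.conditioning_vars)
    u = rng.random(len(pop))
    combos = list(map(tuple, cond.itertuples(index=False, name=None)))
    # resolve each distinct combination once
    cdf_by_combo: dict[tuple, np.ndarray] = {}
    for combo in combos:
        if combo not in cdf_by_combo:
            probs, _ = cpt.resolve(combo)
            cdf_by_combo[combo] = np.cumsum(probs)
    cdfs = np.stack([cdf_by_combo[c] for c in combos]) if combos else np.empty((0, 1))
    idx = (u[:, None] > cdfs).sum(axis=1)
    idx = np.minimum(idx, len(cpt.categories) - 1)
    cats = np.asarray(cpt.categories, dtype=object)[idx]
    return pd.Series(cats, index=pop.index, name=cpt.outcome_var)


def assign_smoking(
    pop: pd.DataFrame,
    cpt_smoking: ConditionalProbabilityTable,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assign smoking status (never / ex / current) by Monte Carlo sampling."""
    out = pop.copy()
    out["smoking"] = assign_categorical(pop, cpt_smoking, rng)
    return out


def assign_disease_state(
    pop: pd.DataFrame,
    cpt_disease: ConditionalProbabilityTable,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Jointly assign diabetes and prior-CVD from the four-state disease CPT.

    The two flags are decoded from one sampled joint category, never drawn
    independently, so their association in the source data is preserved.
    """
    out = pop.copy()
    states = assign_categorical(pop, cpt_disease, rng)
    diab, cvd = disease_flags(states)
    out["diabetes"] = diab
    out["prior_cvd"] = cvd
    return out


def assign_medication_state(
    pop: pd.DataFrame,
    cpt_meds: ConditionalProbabilityTable,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Jointly assign lipid-lowering and BP-lowering medication flags.

    Requires the disease state to be assigned first when the CPT conditions
    on prior CVD (the default pipeline ordering).
    """
    if "prior_cvd" in cpt_meds.conditioning_vars and pop["prior_cvd"].isna().any():
        raise ValidationError(
            "medication CPT conditions on prior_cvd but the disease state "
            "has not been assigned yet"
        )
    out = pop.copy()
    states = assign_categorical(pop, cpt_meds, rng)
    ll, bpl = medication_flags(states)
    out["ll_med"] = ll
    out["bpl_med"] = bpl
    return out
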