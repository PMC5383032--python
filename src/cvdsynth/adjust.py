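"""Post-hoc adjustment of continuous variables toward external targets.

When two consistent external sources disagree with the imputed synthetic
distribution, the stratum-specific means are shifted additively onto the
external targets.  An additive shift preserves the within-stratum spread
developed during imputation exactly; a physiological floor clamp guards
against impossible values after large negative shifts (clamped counts are
reported, and a clamped stratum's mean may land slightly above its target).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import age_band_label
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: Default physiological lower clamps per variable.
DEFAULT_FLOORS = {"sbp": 60.0, "tc_hdl": 1.0}

#: Default stratification of the adjustment: age band x sex.
DEFAULT_STRATA = ("age_band", "sex")


def _strata_frame(pop: pd.DataFrame, strata_def: tuple[str, ...]) -> pd.DataFrame:
    out = pd.DataFrame(index=pop.index)
    for var in strata_def:
        if var == "age_band":
            out[var] = age_band_label(pop["age"]).to_numpy()
        else:
            out[var] = pop[var].to_numpy()
    return out


def stratum_key(values: tuple) -> str:
    """Canonical serialized form of a stratum, e.g. ``"30-44|female"``."""
    return "|".join(str(v) for v in values)


@dataclass
class AdjustmentSpec:
    """Per-stratum additive shifts bringing a variable's means onto targets."""

    variable: str
    strata_def: tuple[str, ...]
    target_mean: dict[str, float]
    delta: dict[str, float]
    floor: float

    def __post_init__(self) -> None:
        for key, d in self.delta.items():
            if not np.isfinite(d):
                raise ValidationError(f"non-finite delta for stratum {key!r}")
        for key, t in self.target_mean.items():
            if self.floor >= t:
                raise ValidationError(
                    f"floor {self.floor} not below target mean {t} ({key!r})"
                )

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"variable": self.variable, "stratum": k,
             "target_mean": self.target_mean[k], "delta": self.delta[k]}
            for k in self.target_mean
        ]
        return pd.DataFrame(rows)

    def write(self, path: str | os.PathLike) -> None:
        self.as_frame().to_csv(path, index=False, float_format="%.17g")


def compute_adjustment(
    pop: pd.DataFrame,
    reference: pd.DataFrame,
    variable: str,
    strata_def: tuple[str, ...] = DEFAULT_STRATA,
    floor: float | None = None,
) -> AdjustmentSpec:
    """Delta per stratum = external reference mean - current synthetic mean.

    ``reference`` is a reference table whose ``stratum`` column uses the
    canonical serialized stratum keys.  Every stratum present in the
    population must have a reference row.
    """
    if floor is None:
        floor = DEFAULT_FLOORS.get(variable, -np.inf)
    strata = _strata_frame(pop, strata_def)
    keys = strata.apply(lambda row: stratum_key(tuple(row)), axis=1)
    current = pop[variable].astype(float).groupby(keys.to_numpy()).mean()
    ref_means = reference.set_index("stratum")["estimate"]
    missing = sorted(set(current.index) - set(ref_means.index))
    if missing:
        raise ValidationError(f"no reference estimate for strata {missing}")
    target = {k: float(ref_means[k]) for k in current.index}
    delta = {k: float(ref_means[k] - current[k]) for k in current.index}
    return AdjustmentSpec(variable, tuple(strata_def), target, delta, float(floor))


def apply_mean_shift(pop: pd.DataFrame, spec: AdjustmentSpec) -> pd.DataFrame:
    """Shift each person's value by its stratum delta, clamped at the floor.

    For clamp-free strata the post-shift mean equals the target and the
    standard deviation is unchanged (the shift is purely additive).  Only
    the named variable changes; every other column is returned untouched.
    """
    strata = _strata_frame(pop, spec.strata_def)
    keys = strata.apply(lambda row: stratum_key(tuple(row)), axis=1)
    missing = sorted(set(keys.unique()) - set(spec.delta))
    if missing:
        raise ValidationError(f"adjustment spec lacks strata {missing}")
    deltas = keys.map(spec.delta).to_numpy(dtype=float)
    out = pop.copy()
    shifted = out[spec.variable].astype(float).to_numpy() + deltas
    clamped = shifted < spec.floor
    if clamped.any():
        logger.warning(
            "%s: %d value(s) clamped at floor %.1f after shifting",
            spec.variable, int(clamped.sum()), spec.floor,
        )
    out[spec.variable] = np.maximum(shifted, spec.floor)
    return out
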