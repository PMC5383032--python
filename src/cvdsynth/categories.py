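"""Canonical category labels, age-band conventions and joint-state codings.

Every module in the package refers to these single definitions so that
category order (which fixes inverse-CDF sampling order and therefore
reproducibility) is never duplicated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# Ethnicity labels in prioritization order: when a person reports several
# ethnicities the highest-priority one (lowest index) is kept.
ETHNICITY_PRIORITY: tuple[str, ...] = (
    "Maori",
    "Pacific",
    "Indian",
    "Chinese",
    "OtherAsian",
    "Other",
    "European",
)
UNKNOWN = "Unknown"

SEXES: tuple[str, ...] = ("female", "male")

# Smoking categories; the census coding is never=0, ex=1, current=2.
SMOKING_LEVELS: tuple[str, ...] = ("never", "ex", "current")
SMOKING_CODE = {lab: i for i, lab in enumerate(SMOKING_LEVELS)}

NZDEP_QUINTILES: tuple[int, ...] = (1, 2, 3, 4, 5)

# Adult age range covered by the population: [30, 85).
AGE_MIN = 30
AGE_MAX_EXCL = 85

# The five analysis age bands (closed on both ends, in band-lower-bound years).
AGE_BANDS: tuple[tuple[int, int], ...] = (
    (30, 44),
    (45, 54),
    (55, 64),
    (65, 74),
    (75, 84),
)
AGE_BAND_LABELS: tuple[str, ...] = tuple(f"{lo}-{hi}" for lo, hi in AGE_BANDS)

# Joint disease state: one categorical encoding the (diabetes, prior_cvd) pair.
DISEASE_STATES: tuple[str, ...] = ("neither", "diabetes_only", "cvd_only", "both")
_DISEASE_TO_FLAGS = {
    "neither": (False, False),
    "diabetes_only": (True, False),
    "cvd_only": (False, True),
    "both": (True, True),
}

# Joint medication state encoding (ll_med, bpl_med).
MEDICATION_STATES: tuple[str, ...] = ("neither", "ll_only", "bpl_only", "both")
_MEDICATION_TO_FLAGS = {
    "neither": (False, False),
    "ll_only": (True, False),
    "bpl_only": (False, True),
    "both": (True, True),
}


def age_band_label(age: "pd.Series | np.ndarray") -> pd.Series:
    """Map continuous ages (or integer band lower bounds) onto the five bands."""
    edges = [lo for lo, _ in AGE_BANDS] + [AGE_MAX_EXCL]
    out = pd.cut(
        np.asarray(age, dtype=float),
        bins=edges,
        right=False,
        labels=AGE_BAND_LABELS,
    )
    return pd.Series(out.astype(str))


def disease_flags(states: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Decode joint disease categories to (diabetes, prior_cvd) booleans."""
    diab = states.map(lambda s: _DISEASE_TO_FLAGS[s][0])
    cvd = states.map(lambda s: _DISEASE_TO_FLAGS[s][1])
    return diab.astype(bool), cvd.astype(bool)


def disease_state(diabetes: pd.Series, prior_cvd: pd.Series) -> pd.Series:
    """Encode (diabetes, prior_cvd) booleans as the joint category."""
    lut = {v: k for k, v in _DISEASE_TO_FLAGS.items()}
    return pd.Series(
        [lut[(bool(d), bool(c))] for d, c in zip(diabetes, prior_cvd)],
        index=diabetes.index,
    )


def medication_flags(states: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Decode joint medication categories to (ll_med, bpl_med) booleans."""
    ll = states.map(lambda s: _MEDICATION_TO_FLAGS[s][0])
    bpl = states.map(lambda s: _MEDICATION_TO_FLAGS[s][1])
    return ll.astype(bool), bpl.astype(bool)


def medication_state(ll_med: pd.Series, bpl_med: pd.Series) -> pd.Series:
    lut = {v: k for k, v in _MEDICATION_TO_FLAGS.items()}
    return pd.Series(
        [lut[(bool(l), bool(b))] for l, b in zip(ll_med, bpl_med)],
        index=ll_med.index,
    )
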