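"""Configurable ground-truth world and the pipeline inputs derived from it.

Real national data of this kind (census cross-tabs, linked hospital /
dispensing records, a primary-care cohort) are access-restricted, so the
package ships a generator that simulates a "true" national adult
population from a :class:`WorldConfig` and then derives every input the
pipeline consumes: a suppressed census cross-tabulation, individual-level
administrative records, a risk-biased complete-case cohort with
digit-preference rounding of blood pressure, and survey-style reference
tables with 95% confidence intervals.  Because the truth is retained, the
whole pipeline can be tested by parameter recovery.

The default configuration carries the published 2013 New Zealand
census-based marginal distributions of the adult (30-84) population: band
sizes, sex, ethnicity, deprivation, smoking, diabetes, prior CVD,
medication use, SBP and TC:HDL moments, and family-history prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from statsmodels.stats.proportion import proportion_confint

from .adjust import stratum_key
from .categories import (
    AGE_BANDS,
    AGE_BAND_LABELS,
    ETHNICITY_PRIORITY,
    SEXES,
    SMOKING_LEVELS,
    UNKNOWN,
    age_band_label,
)
from .errors import ValidationError
from .io import (
    ADMIN_COLUMNS,
    CENSUS_COLUMNS,
    CENSUS_COUNT_COLUMNS,
    POPULATION_COLUMNS,
)

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Published national marginal distributions (2013 NZ adult population, five
# age bands 30-44 / 45-54 / 55-64 / 65-74 / 75-84).  Percent rows are
# normalized on use; the band counts sum to the national total 2,451,278.
# --------------------------------------------------------------------------

NZ_BAND_COUNTS = (828_518, 600_532, 491_463, 344_559, 186_206)
NZ_TOTAL_ADULTS = 2_451_278

NZ_MALE_PCT = (47.3, 48.0, 48.7, 48.4, 45.3)

NZ_ETHNICITY_PCT = {
    "Maori":      (13.9, 12.0, 9.5, 6.8, 4.5),
    "Pacific":    (6.1, 4.8, 3.6, 2.7, 1.9),
    "Indian":     (5.0, 3.1, 2.4, 1.6, 0.9),
    "Chinese":    (4.6, 3.6, 3.6, 2.6, 2.2),
    "OtherAsian": (4.9, 3.5, 2.0, 0.8, 0.4),
    "Other":      (1.6, 0.8, 0.5, 0.2, 0.1),
    "European":   (63.9, 72.3, 78.5, 85.2, 90.0),
}

NZ_NZDEP_PCT = {
    1: (20.9, 25.1, 24.5, 22.5, 19.2),
    2: (21.2, 22.0, 21.9, 21.6, 20.5),
    3: (20.7, 19.6, 19.9, 20.4, 20.9),
    4: (19.5, 17.4, 18.1, 19.3, 22.2),
    5: (17.6, 15.9, 15.7, 16.2, 17.2),
}

NZ_SMOKING_PCT = {
    "current": (18.9, 17.7, 13.8, 9.9, 6.6),
    "ex":      (22.3, 25.3, 30.1, 35.1, 35.0),
    "never":   (58.9, 57.0, 56.0, 55.0, 58.5),
}

NZ_DIABETES_PCT = (4.1, 8.2, 13.8, 19.4, 22.6)
NZ_PRIOR_CVD_PCT = (0.6, 2.5, 6.1, 12.6, 22.4)
NZ_LL_MED_PCT = (1.6, 8.2, 20.5, 34.8, 41.3)
NZ_BPL_MED_PCT = (3.1, 12.7, 28.5, 47.4, 60.6)

NZ_SBP_MEAN_SD = ((122.7, 17.3), (127.9, 17.2), (132.5, 17.3),
                  (136.9, 17.4), (140.4, 17.5))
NZ_TCHDL_MEAN_SD = ((4.0, 1.4), (4.2, 1.2), (4.1, 1.2), (4.0, 1.1), (3.8, 1.1))
NZ_FAM_HX_PCT = (16.5, 13.5, 12.1, 10.6, 8.5)

#: Adjusted odds ratios for prior CVD by ethnicity (vs the rest of the
#: population) embedded in the default world's disease model.
NZ_CVD_ETHNICITY_OR = {"Maori": 1.58, "Pacific": 1.85,
                       "Chinese": 0.43, "OtherAsian": 0.43}


def _norm(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v / v.sum()


def joint_from_margins(p_a: float, p_b: float, odds_ratio: float) -> np.ndarray:
    """Joint 2x2 cell probabilities from two margins and an odds ratio.

    Plackett construction: the probability of (A and B) solves
    ``OR = p11 p00 / (p10 p01)`` for the given margins.  Returns the vector
    (neither, A only, B only, both).
    """
    return _joint_from_margins_vec(np.atleast_1d(p_a), np.atleast_1d(p_b),
                                   odds_ratio)[0]


def _joint_from_margins_vec(
    p_a: np.ndarray, p_b: np.ndarray, odds_ratio: float
) -> np.ndarray:
    p_a = np.asarray(p_a, float)
    p_b = np.asarray(p_b, float)
    if odds_ratio <= 0:
        raise ValidationError("odds ratio must be positive")
    if abs(odds_ratio - 1.0) < 1e-12:
        p11 = p_a * p_b
    else:
        th = odds_ratio
        s = 1.0 + (p_a + p_b) * (th - 1.0)
        p11 = (s - np.sqrt(s * s - 4.0 * th * (th - 1.0) * p_a * p_b)) / (
            2.0 * (th - 1.0)
        )
    p10 = p_a - p11
    p01 = p_b - p11
    p00 = 1.0 - p11 - p10 - p01
    out = np.stack([p00, p10, p01, p11], axis=-1)
    if out.min() < -1e-9:
        raise ValidationError("margins and odds ratio are incompatible")
    return np.clip(out, 0.0, 1.0)


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class WorldConfig:
    """Parameters of the simulated ground-truth national population.

    Band-level probability rows default to the published national
    marginals.  Conditional structure beyond the printed margins —
    ethnicity and sex log-odds offsets, the diabetes x CVD association, the
    medication coupling, the cohort's selection bias and blood-pressure
    digit preference — is configurable, with defaults chosen as realistic
    for this population (see the methods note).  Intercepts of the disease
    and medication models are calibrated so the configured band margins
    hold exactly in expectation despite the offsets.
    """

    n_truth: int = 200_000
    band_weights: tuple = NZ_BAND_COUNTS
    male_pct: tuple = NZ_MALE_PCT
    ethnicity_pct: dict = field(default_factory=lambda: dict(NZ_ETHNICITY_PCT))
    nzdep_pct: dict = field(default_factory=lambda: dict(NZ_NZDEP_PCT))
    smoking_pct: dict = field(default_factory=lambda: dict(NZ_SMOKING_PCT))
    # smoking conditional structure (log-odds on 'current', redistributed
    # proportionally over ex/never)
    smoking_male_logit: float = 0.25
    smoking_maori_logit: float = 0.8
    smoking_dep_logit: float = 0.15  # per quintile step from quintile 3
    diabetes_pct: tuple = NZ_DIABETES_PCT
    prior_cvd_pct: tuple = NZ_PRIOR_CVD_PCT
    diabetes_eth_logit: dict = field(default_factory=lambda: {
        "Maori": 0.6, "Pacific": 0.9, "Indian": 0.9})
    diabetes_male_logit: float = 0.2
    cvd_eth_logit: dict = field(default_factory=lambda: {
        k: float(np.log(v)) for k, v in NZ_CVD_ETHNICITY_OR.items()})
    cvd_male_logit: float = 0.4
    diabetes_cvd_or: float = 4.0
    ll_med_pct: tuple = NZ_LL_MED_PCT
    bpl_med_pct: tuple = NZ_BPL_MED_PCT
    med_cvd_logit: float = 1.5     # prior CVD raises both medication odds
    med_or: float = 6.0            # LL x BPL co-prescription association
    sbp_mean_sd: tuple = NZ_SBP_MEAN_SD
    sbp_sex_diff: float = 6.0      # male minus female mean, mmHg
    sbp_bounds: tuple = (70.0, 250.0)
    tc_hdl_mean_sd: tuple = NZ_TCHDL_MEAN_SD
    tc_hdl_sex_diff: float = 0.4
    tc_hdl_bounds: tuple = (1.0, 15.0)
    fam_hx_pct: tuple = NZ_FAM_HX_PCT
    # cohort selection bias (multiplicative sampling weights)
    cohort_band_bias: tuple = (0.4, 1.0, 1.8, 2.6, 3.0)
    cohort_diabetes_bias: float = 3.0
    cohort_ethnicity_bias: float = 2.0   # Maori / Pacific / Indian
    cohort_young_female_bias: float = 0.15
    p_round: float = 0.7                 # digit-preference probability
    survey_n: int = 5_000
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name, table in (("ethnicity_pct", self.ethnicity_pct),
                            ("nzdep_pct", self.nzdep_pct),
                            ("smoking_pct", self.smoking_pct)):
            sums = np.sum([np.asarray(v, float) for v in table.values()], axis=0)
            if np.any(np.abs(sums - 100.0) > 0.5):
                raise ValidationError(f"{name} columns must sum to ~100%")
        for mean_sd in (self.sbp_mean_sd, self.tc_hdl_mean_sd):
            if any(sd <= 0 for _, sd in mean_sd):
                raise ValidationError("standard deviations must be positive")
        if not 0 <= self.p_round <= 1:
            raise ValidationError("p_round must be a probability")


def _calibrate_intercept(target: float, offsets: np.ndarray,
                         weights: np.ndarray) -> float:
    """Intercept c with sum_g w_g expit(c + offset_g) == target."""
    def gap(c):
        return float(weights @ _expit(c + offsets) - target)
    return brentq(gap, -25.0, 10.0, xtol=1e-12)


def make_ground_truth(
    cfg: WorldConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate ``cfg.n_truth`` fully-observed "true" individuals.

    Every conditional distribution is drawn exactly as configured, so the
    returned frame doubles as the oracle for parameter-recovery tests.
    """
    cfg = cfg or WorldConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.master_seed)
    n = cfg.n_truth

    band = rng.choice(len(AGE_BANDS), size=n, p=_norm(cfg.band_weights))
    lo = np.array([b[0] for b in AGE_BANDS], float)[band]
    hi = np.array([b[1] + 1 for b in AGE_BANDS], float)[band]
    age = lo + rng.random(n) * (hi - lo)
    male = rng.random(n) < np.asarray(cfg.male_pct, float)[band] / 100.0
    sex = np.where(male, "male", "female").astype(object)

    eth_levels = list(ETHNICITY_PRIORITY)
    eth_probs = np.column_stack(
        [np.asarray(cfg.ethnicity_pct[e], float) for e in eth_levels])
    eth_probs = eth_probs / eth_probs.sum(axis=1, keepdims=True)
    eth_idx = _draw_rows(eth_probs[band], rng)
    eth = np.asarray(eth_levels, object)[eth_idx]

    dep_levels = [1, 2, 3, 4, 5]
    dep_probs = np.column_stack(
        [np.asarray(cfg.nzdep_pct[q], float) for q in dep_levels])
    dep_probs = dep_probs / dep_probs.sum(axis=1, keepdims=True)
    nzdep = _draw_rows(dep_probs[band], rng) + 1

    # smoking: band baseline, logit offsets on 'current', ex/never rescaled
    smoke_base = np.column_stack(
        [np.asarray(cfg.smoking_pct[s], float) for s in SMOKING_LEVELS])
    smoke_base = smoke_base / smoke_base.sum(axis=1, keepdims=True)
    base = smoke_base[band]
    offset = (cfg.smoking_male_logit * male
              + cfg.smoking_maori_logit * (eth == "Maori")
              + cfg.smoking_dep_logit * (nzdep - 3))
    p_cur = _expit(_logit(base[:, 2]) + offset)
    rest = 1.0 - p_cur
    rest_base = base[:, :2] / base[:, :2].sum(axis=1, keepdims=True)
    smoke_probs = np.column_stack([rest_base * rest[:, None], p_cur])
    smoking = np.asarray(SMOKING_LEVELS, object)[_draw_rows(smoke_probs, rng)]

    # joint disease state: calibrated per-band intercepts + offsets, coupled
    # by the configured diabetes x CVD odds ratio
    p_diab = _conditional_probability(
        band, cfg.diabetes_pct, cfg.diabetes_eth_logit, cfg.diabetes_male_logit,
        eth, male, cfg)
    p_cvd = _conditional_probability(
        band, cfg.prior_cvd_pct, cfg.cvd_eth_logit, cfg.cvd_male_logit,
        eth, male, cfg)
    joint = _joint_from_margins_vec(p_diab, p_cvd, cfg.diabetes_cvd_or)
    state = _draw_rows(joint, rng)
    diabetes = np.isin(state, (1, 3))
    prior_cvd = np.isin(state, (2, 3))

    # joint medication state: margins calibrated per band over the CVD mix
    p_ll = _med_probability(band, cfg.ll_med_pct, prior_cvd, p_cvd, cfg)
    p_bpl = _med_probability(band, cfg.bpl_med_pct, prior_cvd, p_cvd, cfg)
    med_joint = _joint_from_margins_vec(p_ll, p_bpl, cfg.med_or)
    med_state = _draw_rows(med_joint, rng)
    ll_med = np.isin(med_state, (1, 3))
    bpl_med = np.isin(med_state, (2, 3))

    sbp = _truncated_normal(
        np.array([m for m, _ in cfg.sbp_mean_sd])[band]
        + np.where(male, cfg.sbp_sex_diff / 2, -cfg.sbp_sex_diff / 2),
        np.array([s for _, s in cfg.sbp_mean_sd])[band],
        cfg.sbp_bounds, rng)
    tc_hdl = _truncated_normal(
        np.array([m for m, _ in cfg.tc_hdl_mean_sd])[band]
        + np.where(male, cfg.tc_hdl_sex_diff / 2, -cfg.tc_hdl_sex_diff / 2),
        np.array([s for _, s in cfg.tc_hdl_mean_sd])[band],
        cfg.tc_hdl_bounds, rng)
    fam_hx = rng.random(n) < np.asarray(cfg.fam_hx_pct, float)[band] / 100.0

    return pd.DataFrame({
        "person_id": [f"t{i:08d}" for i in range(n)],
        "age": age, "sex": sex, "ethnicity": eth,
        "nzdep_quintile": nzdep.astype(int), "smoking": smoking,
        "diabetes": diabetes, "prior_cvd": prior_cvd,
        "ll_med": ll_med, "bpl_med": bpl_med,
        "sbp": sbp, "tc_hdl": tc_hdl, "fam_hx": fam_hx,
    })[POPULATION_COLUMNS]


def _draw_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draw of one category per row of a probability matrix."""
    cdf = np.cumsum(probs, axis=1)
    u = rng.random(len(probs))
    idx = (u[:, None] > cdf).sum(axis=1)
    return np.minimum(idx, probs.shape[1] - 1)


def _conditional_probability(band, band_pct, eth_logit, male_logit,
                             eth, male, cfg: WorldConfig) -> np.ndarray:
    """Per-person probability with per-band intercepts calibrated so the
    configured band margin holds in expectation over the sex/ethnicity mix."""
    eth_levels = list(ETHNICITY_PRIORITY)
    eth_off = np.array([eth_logit.get(e, 0.0) for e in eth_levels])
    intercepts = np.empty(len(AGE_BANDS))
    for b in range(len(AGE_BANDS)):
        p_male = cfg.male_pct[b] / 100.0
        eth_w = _norm([cfg.ethnicity_pct[e][b] for e in eth_levels])
        offsets = (eth_off[None, :] +
                   np.array([[0.0], [male_logit]])).ravel()
        weights = (eth_w[None, :] *
                   np.array([[1 - p_male], [p_male]])).ravel()
        intercepts[b] = _calibrate_intercept(band_pct[b] / 100.0, offsets, weights)
    person_eth_off = np.array(
        [eth_logit.get(e, 0.0) for e in eth]) if eth_logit else np.zeros(len(eth))
    return _expit(intercepts[band] + person_eth_off + male_logit * male)


def _med_probability(band, band_pct, prior_cvd, p_cvd, cfg: WorldConfig
                     ) -> np.ndarray:
    """Medication probability with a prior-CVD log-odds boost, intercepts
    calibrated over each band's expected CVD mix."""
    intercepts = np.empty(len(AGE_BANDS))
    for b in range(len(AGE_BANDS)):
        mean_cvd = float(np.mean(p_cvd[band == b])) if np.any(band == b) else \
            cfg.prior_cvd_pct[b] / 100.0
        offsets = np.array([0.0, cfg.med_cvd_logit])
        weights = np.array([1 - mean_cvd, mean_cvd])
        intercepts[b] = _calibrate_intercept(band_pct[b] / 100.0, offsets, weights)
    return _expit(intercepts[band] + cfg.med_cvd_logit * prior_cvd)


def _truncated_normal(mean, sd, bounds, rng) -> np.ndarray:
    lo, hi = bounds
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    u = rng.random(len(mean))
    cdf_a = stats.norm.cdf(a)
    cdf_b = stats.norm.cdf(b)
    return mean + sd * stats.norm.ppf(cdf_a + u * (cdf_b - cdf_a))


# --------------------------------------------------------------------------
# derived pipeline inputs
# --------------------------------------------------------------------------

def derive_census_crosstab(
    truth: pd.DataFrame,
    suppression_threshold: int = 6,
    unknown_ethnicity_rate: float = 0.0,
    unknown_nzdep_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exact cross-tab of the truth with disclosure-control suppression.

    Strata are one-year age band x sex x ethnicity x deprivation quintile
    with one count per smoking category; counts in [1, threshold-1] are
    suppressed (NA).  Optional unknown rates move a random share of counts
    into Unknown-ethnicity / Unknown-deprivation strata, emulating census
    non-response.
    """
    if (unknown_ethnicity_rate or unknown_nzdep_rate) and rng is None:
        raise ValidationError("unknown rates require an rng")
    work = truth.copy()
    work["age_band_low"] = np.floor(work["age"]).astype(int)
    work["nzdep_quintile"] = work["nzdep_quintile"].astype(object)
    if unknown_ethnicity_rate:
        mask = rng.random(len(work)) < unknown_ethnicity_rate
        work.loc[mask, "ethnicity"] = UNKNOWN
    if unknown_nzdep_rate:
        mask = rng.random(len(work)) < unknown_nzdep_rate
        work.loc[mask, "nzdep_quintile"] = UNKNOWN

    tab = (
        work.groupby(
            ["age_band_low", "sex", "ethnicity", "nzdep_quintile", "smoking"],
            sort=True, observed=True)
        .size()
        .unstack("smoking", fill_value=0)
        .reindex(columns=list(SMOKING_LEVELS), fill_value=0)
        .reset_index()
    )
    tab.columns.name = None
    tab["nzdep_quintile"] = tab["nzdep_quintile"].astype(str)
    for col in CENSUS_COUNT_COLUMNS:
        vals = tab[col].astype("Int64")
        small = (vals >= 1) & (vals <= suppression_threshold - 1)
        tab[col] = vals.mask(small)
    return tab[CENSUS_COLUMNS]


def derive_admin_records(truth: pd.DataFrame) -> pd.DataFrame:
    """Project the truth onto the linked administrative record schema."""
    admin = truth[ADMIN_COLUMNS].copy()
    admin["person_id"] = ["a" + pid[1:] for pid in truth["person_id"]]
    return admin


def derive_biased_cohort(
    truth: pd.DataFrame,
    cfg: WorldConfig,
    n_cohort: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample a complete-case cohort biased toward high-risk groups.

    Sampling weights multiply the configured factors for older bands,
    diabetes, and Maori / Pacific / Indian ethnicity, and down-weight young
    women (who rarely qualify for risk assessment).  Recorded SBP then
    suffers digit preference: with probability ``p_round`` a reading is
    rounded to the nearest 10 mmHg.
    """
    if n_cohort > len(truth):
        raise ValidationError("cohort cannot exceed the truth population")
    band = pd.cut(
        truth["age"],
        bins=[b[0] for b in AGE_BANDS] + [AGE_BANDS[-1][1] + 1],
        right=False, labels=False,
    ).to_numpy()
    w = np.asarray(cfg.cohort_band_bias, float)[band]
    w = w * np.where(truth["diabetes"], cfg.cohort_diabetes_bias, 1.0)
    w = w * np.where(
        truth["ethnicity"].isin(["Maori", "Pacific", "Indian"]),
        cfg.cohort_ethnicity_bias, 1.0)
    w = w * np.where(
        (truth["sex"] == "female") & (truth["age"] < 45),
        cfg.cohort_young_female_bias, 1.0)
    idx = rng.choice(len(truth), size=n_cohort, replace=False, p=w / w.sum())
    cohort = truth.iloc[np.sort(idx)].copy().reset_index(drop=True)
    cohort["person_id"] = [f"c{i:07d}" for i in range(len(cohort))]
    rounded = rng.random(len(cohort)) < cfg.p_round
    sbp = cohort["sbp"].to_numpy(dtype=float)
    sbp[rounded] = np.round(sbp[rounded] / 10.0) * 10.0
    cohort["sbp"] = sbp
    return cohort


def derive_reference_survey(
    truth: pd.DataFrame,
    n_sample: int,
    strata_def: tuple[str, ...],
    variable: str,
    category: str | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Survey-style stratum estimates with 95% CIs from a random sample.

    Proportions get Wilson intervals, means get t-based intervals.  Strata
    absent from the sample are omitted with a warning.
    """
    rng = rng or np.random.default_rng(0)
    idx = rng.choice(len(truth), size=min(n_sample, len(truth)), replace=False)
    sample = truth.iloc[np.sort(idx)]
    keys = _stratum_keys(sample, strata_def)
    rows = []
    expected = set(_stratum_keys(truth, strata_def).unique())
    for stratum, grp in sample.groupby(keys.to_numpy()):
        vals = grp[variable]
        if category is not None:
            vals = (vals == category).astype(float)
        elif vals.dtype == object or str(vals.dtype) == "boolean":
            vals = vals.astype(float)
        vals = vals.astype(float)
        n = len(vals)
        if category is not None or truth[variable].dtype != float:
            k = int(vals.sum())
            lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            est = k / n
        else:
            est = float(vals.mean())
            se = float(vals.std(ddof=1)) / np.sqrt(n) if n > 1 else 0.0
            t = stats.t.ppf(0.975, max(n - 1, 1))
            lo, hi = est - t * se, est + t * se
        rows.append({"stratum": stratum, "estimate": est,
                     "ci_low": lo, "ci_high": hi, "n": n})
    seen = {r["stratum"] for r in rows}
    for missing in sorted(expected - seen):
        logger.warning("stratum %s absent from the survey sample; omitted",
                       missing)
    return pd.DataFrame(rows)


def _stratum_keys(df: pd.DataFrame, strata_def: tuple[str, ...]) -> pd.Series:
    parts = []
    for var in strata_def:
        if var == "age_band":
            parts.append(age_band_label(df["age"]).astype(str))
        else:
            parts.append(df[var].astype(str))
    key = parts[0].reset_index(drop=True)
    for p in parts[1:]:
        key = key.str.cat(p.reset_index(drop=True), sep="|")
    key.index = df.index
    return key


def reference_from_moments(
    moments: dict[str, tuple[float, float]], n: int = 10_000
) -> pd.DataFrame:
    """Reference table built directly from known stratum means (and sds).

    Used when external targets are known as published summary moments
    rather than as a sampled survey; the CI is the mean's t-free normal
    interval at the given nominal n.
    """
    rows = []
    for stratum, (mean, sd) in moments.items():
        se = sd / np.sqrt(n)
        rows.append({"stratum": stratum, "estimate": mean,
                     "ci_low": mean - 1.96 * se, "ci_high": mean + 1.96 * se,
                     "n": n})
    return pd.DataFrame(rows)


__all__ = [
    "WorldConfig", "make_ground_truth", "derive_census_crosstab",
    "derive_admin_records", "derive_biased_cohort", "derive_reference_survey",
    "reference_from_moments", "joint_from_margins",
    "NZ_BAND_COUNTS", "NZ_TOTAL_ADULTS", "NZ_MALE_PCT", "NZ_ETHNICITY_PCT",
    "NZ_NZDEP_PCT", "NZ_SMOKING_PCT", "NZ_DIABETES_PCT", "NZ_PRIOR_CVD_PCT",
    "NZ_LL_MED_PCT", "NZ_BPL_MED_PCT", "NZ_SBP_MEAN_SD", "NZ_TCHDL_MEAN_SD",
    "NZ_FAM_HX_PCT", "NZ_CVD_ETHNICITY_OR",
]
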