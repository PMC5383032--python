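"""Imputation-based synthesis of SBP, TC:HDL ratio and family history.

The synthetic persons are appended to a complete-case donor cohort with the
three biological variables treated as missing, and a chained-equations pass
fills them in: predictive mean matching (PMM) for the continuous targets,
so every imputed value is an observed donor value, and posterior-predictive
logistic draws for the binary family-history flag.  The cohort rows are
never modified — they supply the conditional distributions, the synthetic
rows receive them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import SchemaError, ValidationError
from .io import POPULATION_COLUMNS, validate_population

logger = logging.getLogger(__name__)

#: Chained-update order of the imputation targets (fixed for reproducibility).
TARGETS = ("sbp", "tc_hdl", "fam_hx")

_SHARED_VARS = [
    "age", "sex", "ethnicity", "nzdep_quintile", "smoking",
    "diabetes", "prior_cvd", "ll_med", "bpl_med",
]


@dataclass(frozen=True)
class ImputationConfig:
    """Settings of the chained-equations synthesis step.

    ``n_iterations`` chained passes are made over the targets in the fixed
    order sbp, tc_hdl, fam_hx; each continuous target is filled by PMM with
    ``pmm_donors`` nearest donors; ``m`` independent completed tables can be
    produced per run.  Predictors default to all shared variables plus the
    other two targets (current values).
    """

    n_iterations: int = 10
    continuous_method: str = "pmm"
    pmm_donors: int = 5
    binary_method: str = "logistic"
    predictors: dict[str, list[str]] = field(default_factory=dict)
    m: int = 1
    seed: int = 0
    shard_size: int = 250_000

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if self.pmm_donors < 1:
            raise ValidationError("pmm_donors must be >= 1")
        allowed = set(_SHARED_VARS) | set(TARGETS)
        for target, preds in self.predictors.items():
            extra = set(preds) - (allowed - {target})
            if extra:
                raise ValidationError(
                    f"invalid predictors {sorted(extra)} for target {target!r}"
                )

    def predictors_for(self, target: str) -> list[str]:
        if target in self.predictors:
            return list(self.predictors[target])
        return _SHARED_VARS + [t for t in TARGETS if t != target]


def stack_for_imputation(cohort: pd.DataFrame, pop: pd.DataFrame) -> pd.DataFrame:
    """Append the synthetic population to the donor cohort.

    Returns one table with a ``source`` flag; the three imputation targets
    are missing exactly on the synthetic rows (any values they carried are
    cleared, with a log entry).  Categories present in the population but
    absent from the cohort are warned about — such strata have no donors at
    full conditioning and will be served by the regression fit instead.
    """
    for name, df in (("cohort", cohort), ("population", pop)):
        missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{name} is missing columns {missing}")
    if cohort[list(TARGETS)].isna().any().any():
        raise ValidationError("cohort must be complete-case on all targets")

    for var in ("sex", "ethnicity", "smoking"):
        orphan = set(pop[var].unique()) - set(cohort[var].unique())
        if orphan:
            n = int(pop[var].isin(orphan).sum())
            logger.warning(
                "population %s level(s) %s have no cohort donors (%d persons)",
                var, sorted(orphan), n,
            )

    cohort_part = cohort[POPULATION_COLUMNS].copy()
    cohort_part["source"] = "cohort"
    pop_part = pop[POPULATION_COLUMNS].copy()
    carried = pop_part[list(TARGETS)].notna().sum().sum()
    if carried:
        logger.info("clearing %d pre-existing target values on synthetic rows",
                    int(carried))
    pop_part["sbp"] = np.nan
    pop_part["tc_hdl"] = np.nan
    pop_part["fam_hx"] = pd.NA
    pop_part["source"] = "synthetic"
    return pd.concat([cohort_part, pop_part], ignore_index=True)


def _design_matrix(table: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    """Numeric design matrix with intercept; categoricals one-hot encoded.

    Reference levels (female, European, never-smoker) are absorbed into the
    intercept.  Constant columns are dropped with a log entry.
    """
    cols = [np.ones(len(table))]
    names = ["const"]
    for var in predictors:
        vals = table[var]
        if var == "sex":
            cols.append((vals == "male").to_numpy(float)); names.append("male")
        elif var == "ethnicity":
            for lev in sorted(vals.unique()):
                if lev == "European":
                    continue
                cols.append((vals == lev).to_numpy(float)); names.append(lev)
        elif var == "smoking":
            for lev in ("ex", "current"):
                cols.append((vals == lev).to_numpy(float)); names.append(lev)
        elif vals.dtype == object or str(vals.dtype) == "boolean":
            cols.append(vals.astype(float).to_numpy()); names.append(var)
        else:
            cols.append(vals.to_numpy(dtype=float)); names.append(var)
    X = np.column_stack(cols)
    keep = [0] + [
        j for j in range(1, X.shape[1]) if not np.allclose(X[:, j], X[0, j])
    ]
    if len(keep) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        logger.info("dropping constant predictor column(s) %s", dropped)
    return X[:, keep]


def _draw_ols_beta(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """OLS fit plus a posterior draw of (beta, sigma) for proper imputation."""
    n, p = X.shape
    beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_hat
    df_resid = max(n - p, 1)
    ssr = float(resid @ resid)
    sigma2_draw = ssr / stats.chi2.rvs(df_resid, random_state=np.random.default_rng(
        rng.integers(2**31)))
    xtx_inv = np.linalg.pinv(X.T @ X)
    cov = sigma2_draw * xtx_inv
    # eigen-based square root: robust to the near-singular fits that exact
    # Cholesky rejects
    w, v = np.linalg.eigh((cov + cov.T) / 2)
    root = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    beta_draw = beta_hat + root @ rng.standard_normal(p)
    return beta_hat, beta_draw


def _pmm_match(
    donor_hat: np.ndarray,
    donor_y: np.ndarray,
    target_hat: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """For each target predicted mean, draw one of the k nearest donors.

    Nearness is on the predicted-mean scale; ties are resolved by donor
    order.  Returns observed donor values, so imputations stay inside the
    observed support.
    """
    order = np.argsort(donor_hat, kind="stable")
    sorted_hat = donor_hat[order]
    sorted_y = donor_y[order]
    n_donor = len(donor_y)
    k = min(k, n_donor)
    pos = np.searchsorted(sorted_hat, target_hat)
    # candidate window of 2k donors straddling the insertion point
    offsets = np.arange(-k, k)
    cand = np.clip(pos[:, None] + offsets[None, :], 0, n_donor - 1)
    dist = np.abs(sorted_hat[cand] - target_hat[:, None])
    nearest = np.argpartition(dist, kth=k - 1, axis=1)[:, :k]
    pick = nearest[np.arange(len(target_hat)), rng.integers(k, size=len(target_hat))]
    return sorted_y[cand[np.arange(len(target_hat)), pick]]


def _fit_logistic(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Logistic fit with posterior beta draw; ridge fallback on separation."""
    try:
        with np.errstate(all="ignore"):
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        if not np.all(np.isfinite(params)) or not np.all(np.isfinite(cov)) or \
                np.abs(params).max() > 30:
            raise np.linalg.LinAlgError("separation suspected")
        w, v = np.linalg.eigh((cov + cov.T) / 2)
        root = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
        return params + root @ rng.standard_normal(len(params))
    except Exception:  # noqa: BLE001 - any fit failure routes to the ridge
        logger.warning("logistic step failed (possible separation); "
                       "falling back to a ridge-penalized fit")
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1.0, fit_intercept=False, max_iter=200)
        clf.fit(X, y.astype(int))
        return clf.coef_.ravel()


def _impute_shard(
    table: pd.DataFrame,
    cfg: ImputationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    obs = (table["source"] == "cohort").to_numpy()
    mis = ~obs
    work = table.copy()

    # initial fill: random draws from the observed donor values
    for target in TARGETS:
        donors = work.loc[obs, target].to_numpy()
        draw = donors[rng.integers(len(donors), size=int(mis.sum()))]
        work.loc[mis, target] = draw
    work["fam_hx"] = work["fam_hx"].astype(bool)

    for _ in range(cfg.n_iterations):
        for target in TARGETS:
            X = _design_matrix(work, cfg.predictors_for(target))
            if target == "fam_hx":
                y = work.loc[obs, target].astype(float).to_numpy()
                beta = _fit_logistic(X[obs], y, rng)
                eta = X[mis] @ beta
                p = 1.0 / (1.0 + np.exp(-eta))
                work.loc[mis, target] = rng.random(int(mis.sum())) < p
            else:
                y = work.loc[obs, target].to_numpy(dtype=float)
                beta_hat, beta_draw = _draw_ols_beta(X[obs], y, rng)
                donor_hat = X[obs] @ beta_hat
                target_hat = X[mis] @ beta_draw
                work.loc[mis, target] = _pmm_match(
                    donor_hat, y, target_hat, cfg.pmm_donors, rng
                )
    return work


def run_chained_imputation(
    table: pd.DataFrame,
    cfg: ImputationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame | list[pd.DataFrame]:
    """Fill every missing target cell by chained-equations synthesis.

    Returns one completed table, or a list of ``cfg.m`` independently
    completed tables when ``m > 1``.  Synthetic rows are processed in
    shards, each stacked with the full cohort, so peak memory scales with
    the shard, not the population.  A table with no missing cells is
    returned unchanged.
    """
    cfg = cfg or ImputationConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.m > 1:
        children = rng.spawn(cfg.m)
        return [
            run_chained_imputation(table, replace(cfg, m=1), child)
            for child in children
        ]

    target_na = table[list(TARGETS)].isna()
    if not target_na.any().any():
        return table
    synth = (table["source"] == "synthetic").to_numpy()
    if target_na.to_numpy().any(axis=1)[~synth].any():
        raise ValidationError("missingness outside the synthetic rows")

    cohort_part = table[~synth]
    synth_part = table[synth]
    shards = []
    for start in range(0, len(synth_part), cfg.shard_size):
        chunk = synth_part.iloc[start:start + cfg.shard_size]
        stacked = pd.concat([cohort_part, chunk], ignore_index=True)
        done = _impute_shard(stacked, cfg, rng)
        shards.append(done.iloc[len(cohort_part):])
    out = pd.concat([cohort_part] + shards, ignore_index=True)
    assert not out[list(TARGETS)].isna().any().any()
    return out


def extract_synthetic(table: pd.DataFrame) -> pd.DataFrame:
    """Return the completed synthetic rows as a population frame."""
    resid = table.loc[table["source"] == "synthetic", list(TARGETS)].isna()
    if resid.any().any():
        raise ValidationError("residual missingness in synthetic rows")
    pop = (
        table[table["source"] == "synthetic"]
        .drop(columns=["source"])
        .reset_index(drop=True)
    )
    pop["fam_hx"] = pop["fam_hx"].astype(bool)
    validate_population(pop)
    return pop[POPULATION_COLUMNS]
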