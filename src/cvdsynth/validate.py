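"""Internal and external validation of a synthetic population.

Internal validation compares the population against the sources it was
generated from: deterministic stages must match exactly, Monte Carlo stages
within quantified sampling error (a 4-standard-error criterion automates
what the field usually judges from overlaid plots).  External validation
compares stratum summaries against independent reference estimates and
counts how many fall inside the references' 95% confidence intervals.
Adjusted odds ratios and replicate-population variability complete the
toolkit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .categories import age_band_label
from .errors import ValidationError

#: Monte Carlo acceptance threshold, in standard errors of the source value.
SE_THRESHOLD = 4.0


def _strata_frame(pop: pd.DataFrame, strata_def: tuple[str, ...]) -> pd.Series:
    parts = []
    for var in strata_def:
        if var == "age_band":
            parts.append(age_band_label(pop["age"]).astype(str))
        else:
            parts.append(pop[var].astype(str))
    key = parts[0]
    for p in parts[1:]:
        key = key.str.cat(p, sep="|")
    return key


def summarize(
    pop: pd.DataFrame,
    variable: str,
    strata_def: tuple[str, ...],
    category: str | None = None,
) -> pd.DataFrame:
    """Per-stratum mean (continuous) or proportion (boolean / category).

    For a categorical variable, ``category`` selects the level whose
    proportion is reported.  Returns columns stratum, value, n.
    """
    keys = _strata_frame(pop, strata_def)
    vals = pop[variable]
    if category is not None:
        vals = (vals == category).astype(float)
    elif vals.dtype == object or str(vals.dtype) == "boolean":
        vals = vals.astype(float)
    grouped = vals.astype(float).groupby(keys.to_numpy())
    out = grouped.agg(["mean", "size"]).reset_index()
    out.columns = ["stratum", "value", "n"]
    return out


def internal_compare(
    pop: pd.DataFrame,
    source_summary: pd.DataFrame,
    variable: str,
    strata_def: tuple[str, ...],
    kind: str = "proportion",
    category: str | None = None,
    exact: bool = False,
    source_sd: pd.Series | None = None,
) -> pd.DataFrame:
    """Compare the population against the summary of a generating source.

    ``source_summary`` has columns stratum, value and (for Monte Carlo
    stages) n, the source count used for the standard error.  ``exact``
    marks deterministically-copied variables, for which any non-zero
    difference fails.  Strata empty in the population are reported with a
    flag rather than dropped.
    """
    synth = summarize(pop, variable, strata_def, category=category)
    synth = synth.set_index("stratum")
    src = source_summary.set_index("stratum")
    unmatched = sorted(set(src.index) ^ set(synth.index))
    rows = []
    for stratum in src.index:
        ref = float(src.loc[stratum, "value"])
        if stratum not in synth.index:
            rows.append({
                "variable": variable, "stratum": stratum,
                "synthetic_value": np.nan, "reference_value": ref,
                "abs_diff": np.nan, "std_diff": np.nan,
                "passed": False, "empty": True,
            })
            continue
        val = float(synth.loc[stratum, "value"])
        n_syn = float(synth.loc[stratum, "n"])
        diff = abs(val - ref)
        if exact:
            se = 0.0
            passed = diff == 0.0
            std = np.nan if diff == 0 else np.inf
        else:
            if kind == "proportion":
                se = np.sqrt(max(ref * (1 - ref), 1e-12) / n_syn)
            else:
                sd = float(source_sd[stratum]) if source_sd is not None else float(
                    src.loc[stratum].get("sd", np.nan))
                se = sd / np.sqrt(n_syn)
            std = diff / se if se > 0 else np.inf
            passed = bool(std <= SE_THRESHOLD)
        rows.append({
            "variable": variable, "stratum": stratum,
            "synthetic_value": val, "reference_value": ref,
            "abs_diff": diff, "std_diff": std, "passed": passed,
            "empty": False,
        })
    extra = [s for s in unmatched if s not in src.index]
    if extra:
        raise ValidationError(f"population strata {extra} missing from source")
    return pd.DataFrame(rows)


def external_compare(
    pop: pd.DataFrame,
    reference: pd.DataFrame,
    variable: str,
    strata_def: tuple[str, ...],
    category: str | None = None,
    aggregation: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Check which reference confidence intervals cover the synthetic values.

    ``aggregation`` maps a reference stratum key to the list of population
    stratum keys it pools (e.g. merging Chinese and OtherAsian into one
    Asian stratum to match a survey's coarser ethnicity grouping).
    """
    synth = summarize(pop, variable, strata_def, category=category)
    synth = synth.set_index("stratum")
    rows = []
    for _, ref in reference.iterrows():
        stratum = ref["stratum"]
        members = aggregation.get(stratum, [stratum]) if aggregation else [stratum]
        found = [m for m in members if m in synth.index]
        if not found:
            raise ValidationError(
                f"reference stratum {stratum!r} not mappable onto the population"
            )
        n = synth.loc[found, "n"].sum()
        val = float((synth.loc[found, "value"] * synth.loc[found, "n"]).sum() / n)
        within = bool(ref["ci_low"] <= val <= ref["ci_high"])
        scale = (ref["ci_high"] - ref["ci_low"]) / (2 * 1.96)
        diff = abs(val - float(ref["estimate"]))
        rows.append({
            "variable": variable, "stratum": stratum, "synthetic_value": val,
            "reference_value": float(ref["estimate"]),
            "ci_low": float(ref["ci_low"]), "ci_high": float(ref["ci_high"]),
            "within_ci": within, "abs_diff": diff,
            "std_diff": diff / scale if scale > 0 else np.inf,
        })
    out = pd.DataFrame(rows)
    out.attrs["n_within"] = int(out["within_ci"].sum())
    out.attrs["n_total"] = len(out)
    return out


def adjusted_odds_ratio(
    pop: pd.DataFrame,
    outcome: str,
    exposure: pd.Series | str,
    adjusters: tuple[str, ...] = ("age", "sex"),
) -> dict:
    """Adjusted odds ratio by logistic regression with a Wald 95% CI.

    ``exposure`` is a binary indicator (or the name of one), typically an
    ethnicity contrast such as Maori vs non-Maori; the exposure coefficient
    is exponentiated.  On complete separation the fit falls back to an L2
    penalized solution, flagged in the result.
    """
    if isinstance(exposure, str):
        expo = pop[exposure].astype(float).to_numpy()
        name = exposure
    else:
        expo = exposure.astype(float).to_numpy()
        name = exposure.name or "exposure"
    y = pop[outcome].astype(float).to_numpy()
    cols = [np.ones(len(pop)), expo]
    for adj in adjusters:
        if adj == "sex":
            cols.append((pop["sex"] == "male").to_numpy(float))
        else:
            cols.append(pop[adj].astype(float).to_numpy())
    X = np.column_stack(cols)
    flagged = False
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=False, maxiter=100)
        beta, se = res.params[1], res.bse[1]
        if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 30:
            raise np.linalg.LinAlgError("separation suspected")
    except Exception:  # noqa: BLE001 - fall back to a penalized fit
        flagged = True
        res = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=False)
        beta = res.params[1]
        se = np.nan
    or_hat = float(np.exp(beta))
    if np.isfinite(se):
        lo, hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
    else:
        lo = hi = np.nan
    return {
        "exposure": name, "outcome": outcome, "or": or_hat,
        "ci_low": float(lo), "ci_high": float(hi), "penalized": flagged,
    }


def replicate_variability(
    build,
    master_seed: int,
    n_replicates: int,
    summaries: list[dict],
) -> pd.DataFrame:
    """Mean and SD of stratum summaries across replicate populations.

    ``build`` maps a seed to a population; replicate ``r`` uses a seed
    spawned deterministically from the master seed.  Each entry of
    ``summaries`` holds kwargs for :func:`summarize`.  Monte Carlo error
    makes the relative SD shrink as strata grow.
    """
    if n_replicates < 2:
        raise ValidationError("need at least 2 replicates")
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(master_seed).spawn(n_replicates)]
    collected: dict[tuple, list[float]] = {}
    sizes: dict[tuple, float] = {}
    for seed in seeds:
        pop = build(seed)
        for spec in summaries:
            summ = summarize(pop, **spec)
            label = (spec["variable"], spec.get("category"))
            for _, row in summ.iterrows():
                key = label + (row["stratum"],)
                collected.setdefault(key, []).append(float(row["value"]))
                sizes[key] = float(row["n"])
    rows = []
    for (variable, category, stratum), vals in collected.items():
        vals = np.asarray(vals, dtype=float)
        rows.append({
            "variable": variable, "category": category, "stratum": stratum,
            "n": sizes[(variable, category, stratum)],
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "n_replicates": len(vals),
        })
    return pd.DataFrame(rows)
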