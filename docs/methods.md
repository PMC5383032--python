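# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the simulated test world does and
does not capture, and the package's known limitations.

## The generation model

A synthetic population is a draw from a factorised joint distribution

    P(demographics) · P(smoking | demographics)
                    · P(diabetes, CVD | age band, sex, ethnicity)
                    · P(LL, BPL | age band, sex, ethnicity, CVD)
                    · P(SBP, TC:HDL, family history | all of the above)

where each factor is estimated from the richest source that measures it.
The factorisation preserves the correlations that matter for multivariable
risk equations exactly where the conditioning variables overlap between
sources, and assumes conditional independence elsewhere: e.g. smoking and
diabetes are associated only through their shared conditioning on
demographics, because no source links them directly at the individual
level.

### Demographic framework

The census cross-tab is taken as ground truth for age band, sex,
ethnicity and deprivation. Three pre-processing rules:

- **Suppression.** Cells holding 1–5 individuals arrive as a sentinel
  (default `..C`). The default resolution draws an integer uniformly on
  {1..5}: the censoring rule bounds the truth and nothing else is known, so
  a bounded uniform is the least-assumption fill. When a stratum's true
  total is separately published, the `total_constrained` strategy draws
  uniformly from the feasible fill combinations instead (enumeration over
  {1..5}^k; at most three suppressed cells per row, so the space is tiny).
  Resolution inflates totals slightly relative to the unsuppressed sum;
  the manifest records the resolved total.
- **Unknowns.** Unknown-ethnicity and Unknown-deprivation strata are
  reallocated inside each age-band × sex margin proportionally to the known
  counts, with largest-remainder rounding so every total is conserved
  exactly (ties broken in canonical category order). A margin with no
  known counts falls back to the overall proportions, logged.
- **Prioritized ethnicity.** Multiple reported ethnicities collapse to one
  by the fixed national priority order (Maori, Pacific, Indian, Chinese,
  Other Asian, Other, European).

Expansion draws age ~ Uniform[Y, Y+1) within the one-year band (bands run
[30, 85), top band [84, 85)) and copies the other demographics, so the
four-way margins match the resolved cross-tab cell-for-cell. Smoking
defaults to `monte_carlo`: each person's status is redrawn from the
stratum's smoking proportions, treating self-report as the one census
variable with real short-term variability; `deterministic` mode instead
keeps the count-exact assignment, and is what the marginal-exactness
guarantee refers to.

### Conditional probability tables

CPT rows are observed relative frequencies. Cells with fewer than
`min_cell = 20` records are re-estimated after dropping the last
conditioning variable, recursively down to the unconditional distribution;
each resolved row records its pooling level. Twenty is small enough to
keep full conditioning almost everywhere at administrative-register scale
and large enough that a row's worst-case standard error stays near 0.11.
Age conditions through the five analysis bands (30–44, 45–54, 55–64,
65–74, 75–84) rather than single years, to control sparsity.

Disease (diabetes × prior CVD) and medication (LL × BPL) are sampled as
single four-category joint states and decoded into boolean pairs, never as
independent margins. Medication conditions on (age band, sex, ethnicity,
prior CVD) by default; a switch adds diabetes for registers whose linkage
includes it. Per-person sampling inverts one uniform through the row CDF
with category order fixed by the canonical lists, making draws independent
of how persons are grouped.

### Imputation synthesis

The synthetic persons are appended to the complete-case cohort with SBP,
TC:HDL and family history missing, and chained equations run
`n_iterations = 10` passes over the targets in the fixed order
sbp → tc_hdl → fam_hx; each target's predictors are all shared variables
plus the current values of the other two targets. Continuous targets use
predictive mean matching with a posterior draw of the regression
coefficients and `k = 5` donors (the mice-style default): imputed values
stay inside the observed support, which keeps clinically structured
features such as digit preference. The binary target uses logistic
posterior-predictive draws, with a ridge-penalized fallback (logged) if
the fit separates. Ten iterations is a conventional chained-equations
burn-in; no formal convergence diagnostic is applied. Large populations
are processed in shards (default 250,000 synthetic rows) with the full
cohort attached to each shard, so peak memory scales with shard + cohort.
Cohort rows are never modified. `m > 1` returns independently completed
tables; the pipeline instead builds replicate populations at the top
level, which is the natural unit of uncertainty here.

### Post-hoc adjustment

When two consistent external sources disagree with the imputed
distribution, per-stratum (age band × sex) additive deltas
`target mean − current mean` are applied. An additive shift preserves the
within-stratum standard deviation exactly, which is the stated goal of the
adjustment; no higher moments are reshaped. Physiological floors (60 mmHg
for SBP, 1.0 for TC:HDL) clamp impossible values after large negative
shifts; clamped counts are logged and clamped strata may finish slightly
above target. Both adjusted and unadjusted populations are emitted so
downstream simulations can run sensitivity analyses.

### Validation

Internal validation compares against generating sources: deterministic
stages must match exactly; Monte Carlo stages must sit within 4 standard
errors of the source value — a deliberately strict automated stand-in for
the visual overlay judgment usual in this literature. External validation
counts strata inside independent 95% CIs, with explicit re-aggregation
maps where the external grouping is coarser (e.g. Chinese + Other Asian →
Asian). Ethnicity contrasts are summarised as age/sex-adjusted logistic
odds ratios with Wald CIs (closed-form cross-product on a saturated 2×2).
Replicate variability reports the across-replicate mean and SD (ddof = 1)
of stratum summaries, with replicate seeds spawned deterministically from
a master seed; the suppression-resolution stage is seeded from the master
seed alone so replicates share one resolved census frame and hence
identical demographic margins.

## The simulated world

`fixtures.WorldConfig` defines a ground-truth population whose band-level
margins default to the published 2013 New Zealand adult values (band
counts, sex, ethnicity, deprivation, smoking, diabetes, prior CVD,
medication use, SBP and TC:HDL moments, family history). Values the
published tables do not determine were fixed once at realistic levels:

- diabetes × CVD odds ratio 4.0 and LL × BPL odds ratio 6.0 (both
  conditions/drug classes cluster strongly);
- prior-CVD ethnicity log-odds offsets ln(1.58) Maori, ln(1.85) Pacific,
  ln(0.43) Chinese/Other Asian, male offset 0.4; diabetes offsets 0.6–0.9
  for Maori/Pacific/Indian;
- smoking offsets: +0.25 male, +0.8 Maori, +0.15 per deprivation quintile
  step (all on the log-odds of current smoking);
- SBP sex gap 6 mmHg and TC:HDL gap 0.4 (male higher), normal per stratum,
  truncated at 70–250 mmHg and 1–15 respectively;
- cohort selection bias: band weights (0.4, 1.0, 1.8, 2.6, 3.0), ×3 for
  diabetes, ×2 for Maori/Pacific/Indian, ×0.15 for women under 45; digit
  preference probability 0.7 of rounding SBP to the nearest 10 mmHg.

Model intercepts are calibrated by root-finding so the configured band
margins hold in expectation despite the offsets. The generator draws age
uniformly within each analysis band, so it does not reproduce single-year
population structure; nor does it model secular smoking trends, survey
design weights, or any geography. Passing recovery tests
therefore show that the pipeline recovers the statistical structure it is
pointed at, not that any specific real population is matched.

Default problem sizes — 200,000 truth persons, 20,000-record cohort,
5,000-person surveys — were chosen as the package's standard desk-scale
experiment: large enough that Monte Carlo error is small against the
tolerances of interest, small enough to run in seconds. The full national
scale (~2.45 M) is supported via sharded imputation.

## Numerical choices and degenerate inputs

- Probability rows must sum to 1 within 1e-12; rows transcribed from
  rounded published percentages can be renormalized explicitly
  (`normalize=True`).
- Largest-remainder apportionment breaks ties by canonical category order;
  zero-weight targets never receive counts.
- OLS uses `lstsq` with a pinv covariance and an eigenvalue square root
  for the posterior draw, robust to near-singular designs; constant
  predictor columns are dropped with a log entry.
- PMM nearness is measured on the predicted-mean scale with a sorted
  search; ties resolve by donor order, draws by one uniform per target row.
- Logistic fits flag |coefficient| > 30 or non-finite covariance as
  separation and fall back to ridge (C = 1.0), logged.
- Empty strata are reported with a flag, never silently dropped; an
  all-zero smoking row expands to persons only in deterministic mode (the
  Monte Carlo redraw needs positive stratum totals, and zero-count strata
  produce no persons anyway).
- All randomness flows through numpy Generators seeded from explicit
  integers; per-stage streams are spawned via `SeedSequence`, and stream
  consumption order (strata in file order, persons in row order) is fixed,
  so equal seeds give byte-identical outputs.

## Limitations

- Suppression resolution is unbiased only if suppressed cells are truly
  uniform on {1..5}; real censoring is skewed toward 1–2, so resolved
  totals overshoot slightly when suppression is heavy.
- Conditional independence beyond the shared conditioning variables is
  assumed, not tested; associations not carried by a linkage variable
  (e.g. smoking × medication within a stratum) are attenuated to their
  between-stratum component.
- The imputation model is linear/logistic in main effects; strata with
  very few donors (young women, by construction of the cohort bias)
  inherit the model's extrapolation and must be caught by validation
  rather than by the imputation itself.
- The additive adjustment aligns means only; if an external source
  disagrees in spread or shape, that disagreement survives adjustment.
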