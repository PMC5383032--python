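# cvdsynth

Synthetic national adult populations for cardiovascular-disease (CVD) risk
microsimulation.

Policy questions about CVD prevention — who should be offered statins or
blood-pressure-lowering drugs, at what predicted-risk threshold, with what
effect on national event counts — need individual-level data carrying the
*joint* distribution of every risk-equation input for a whole adult
population. No single dataset provides that: censuses publish aggregated
cross-tabulations, hospitalisation and dispensing registers cover diseases
and drugs but not biology, and clinical cohorts measure blood pressure and
lipids but over-represent high-risk patients. `cvdsynth` builds a synthetic
population by combining all three source types so that each generated
person carries the twelve fields of the standard CVD risk equations: age,
sex, ethnicity, deprivation quintile, smoking status, diabetes, prior CVD,
lipid-lowering and blood-pressure-lowering treatment, systolic blood
pressure (SBP), total:HDL cholesterol ratio (TC:HDL), and family history of
premature CVD.

It is intended for epidemiologists and health-policy modellers who need a
privacy-free stand-in population for microsimulation, and for
methodologists studying synthetic-data pipelines; everything is driven from
delimited text files and a plain Python API.

## Method

Generation proceeds in three stages, mirroring how the source data nest:

1. **Demographic framework.** The aggregated census cross-tab (one-year age
   band × sex × ethnicity × deprivation quintile, with smoking-category
   counts) is expanded into individuals. Disclosure-suppressed small cells
   (counts 1–5, coded `..C`) are resolved by a bounded draw, Unknown
   ethnicity/deprivation strata are reallocated proportionally with
   largest-remainder rounding, and each counted person receives an age
   `X ~ Uniform[Y, Y+1)` within their band; sex, ethnicity and deprivation
   are copied deterministically, so the demographic margins are exact.
2. **Conditional probability tables (CPTs).** Smoking is redrawn per person
   from the stratum's census proportions; diabetes and prior CVD are
   assigned as one *joint* four-category state (neither / diabetes only /
   CVD only / both) from a CPT estimated on linked administrative records
   conditional on age band, sex and ethnicity; medication status is the
   analogous joint state conditional additionally on prior CVD. Sparse CPT
   cells (< 20 records) pool recursively over the last conditioning
   variable. Sampling is inverse-CDF on a single uniform per person.
3. **Imputation synthesis.** Synthetic persons are appended to a
   complete-case clinical cohort with SBP, TC:HDL and family history marked
   missing, and chained-equations imputation fills them: predictive mean
   matching (k = 5 donors) for the continuous targets — every imputed value
   is a real observed value — and posterior logistic draws for family
   history.

Where trusted external surveys disagree with the imputed distribution, a
post-hoc additive mean shift moves each age-band × sex stratum onto the
external target while preserving the within-stratum spread, with a
physiological floor clamp. A validation toolkit compares the population to
its generating sources (exact for deterministic stages, a 4-standard-error
criterion for Monte Carlo stages), to external reference tables with 95%
CIs, fits age/sex-adjusted logistic odds ratios for ethnicity contrasts,
and quantifies Monte Carlo variability across replicate populations.

Because the real national inputs are access-restricted, the package ships
a `fixtures` module that simulates a configurable ground-truth world —
defaulting to the published 2013 New Zealand adult marginals — and derives
every pipeline input from it (suppressed census, admin records, a
risk-biased cohort with digit-preference rounding of SBP, survey reference
tables), enabling end-to-end parameter-recovery testing.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/02_conditional_assignment.py` estimates disease and
medication CPTs from simulated administrative records for 100,000 persons
and reassigns the states:

```
disease CPT rows (full conditioning): 70
       diabetes %  prior CVD %  BPL med %
age
30-44         4.3          0.6        3.3
45-54         8.4          2.3       13.0
55-64        13.4          6.1       28.1
65-74        18.6         13.4       46.7
75-84        21.8         21.8       60.0
P(diabetes & CVD) = 0.0208 vs 0.0058 under independence
```

Each row is the prevalence recovered in the regenerated population: the
steep age gradients of the source are reproduced, and the excess of the
joint diabetes-and-CVD probability over the product of its margins shows
that the association survives because the two flags are sampled as one
joint state, never independently.

The command-line interface exposes the same stages
(`cvdsynth make-fixtures | build-framework | estimate-cpt | assign |
impute | adjust | validate | build | replicates`); `cvdsynth build
--config run.yaml` executes the whole pipeline from a YAML config and
writes a manifest with seeds and output checksums.

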