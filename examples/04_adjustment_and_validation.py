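"""Shift stratum SBP means onto an external survey and validate the result,
including an age/sex-adjusted ethnicity odds ratio.
"""

import numpy as np

from cvdsynth.adjust import apply_mean_shift, compute_adjustment
from cvdsynth.fixtures import WorldConfig, derive_reference_survey, make_ground_truth
from cvdsynth.validate import adjusted_odds_ratio, external_compare

cfg = WorldConfig(n_truth=80_000, master_seed=8)
rng = np.random.default_rng(8)
pop = make_ground_truth(cfg, rng)
survey = derive_reference_survey(pop, 5_000, ("age_band", "sex"), "sbp", rng=rng)

spec = compute_adjustment(pop, survey, "sbp")
deltas = {k: round(v, 2) for k, v in sorted(spec.delta.items())[:4]}
print(f"first adjustment deltas (target - current, mmHg): {deltas}")
adjusted = apply_mean_shift(pop, spec)
print(f"sd before {pop['sbp'].std():.2f} vs after {adjusted['sbp'].std():.2f} "
      "(additive shift preserves within-stratum spread)")

report = external_compare(adjusted, survey, "sbp", ("age_band", "sex"))
print(f"{report.attrs['n_within']}/{report.attrs['n_total']} strata inside "
      "the survey 95% CIs after adjustment")

res = adjusted_odds_ratio(
    pop, "prior_cvd", (pop["ethnicity"] == "Maori").rename("maori"))
print(f"Maori vs non-Maori prior-CVD OR {res['or']:.2f} "
      f"(95% CI {res['ci_low']:.2f}-{res['ci_high']:.2f})")
# The OR estimates the ethnicity log-odds offset embedded in the
# generating world (ln 1.58), adjusted for age and sex; at this sample
# size the estimate scatters a few percent around the embedded value.
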