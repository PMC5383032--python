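"""Estimate conditional probability tables and Monte Carlo-assign disease
and medication states, checking that the source prevalences are recovered.
"""

import numpy as np
import pandas as pd

from cvdsynth.cpt import assign_disease_state, assign_medication_state
from cvdsynth.fixtures import WorldConfig, derive_admin_records, make_ground_truth
from cvdsynth.pipeline import estimate_admin_cpts

truth = make_ground_truth(WorldConfig(n_truth=100_000, master_seed=3),
                          np.random.default_rng(3))
admin = derive_admin_records(truth)
cpt_disease, cpt_meds = estimate_admin_cpts(admin)
print(f"disease CPT rows (full conditioning): {len(cpt_disease.levels[0])}")

# a fresh population with the same demographics, diseases still unassigned
pop = truth.copy()
pop[["diabetes", "prior_cvd", "ll_med", "bpl_med"]] = pd.NA
pop = assign_disease_state(pop, cpt_disease, np.random.default_rng(4))
pop = assign_medication_state(pop, cpt_meds, np.random.default_rng(5))

band = pd.cut(pop["age"], [30, 45, 55, 65, 75, 85], right=False,
              labels=["30-44", "45-54", "55-64", "65-74", "75-84"])
table = pd.DataFrame({
    "diabetes %": pop.groupby(band, observed=True)["diabetes"].mean() * 100,
    "prior CVD %": pop.groupby(band, observed=True)["prior_cvd"].mean() * 100,
    "BPL med %": pop.groupby(band, observed=True)["bpl_med"].mean() * 100,
}).round(1)
print(table.to_string())
# Prevalences rise steeply with age, matching the administrative source the
# CPTs were estimated from; diabetes and CVD co-occur more often than
# independence would predict because they are sampled as one joint state.
both = (pop["diabetes"] & pop["prior_cvd"]).mean()
indep = pop["diabetes"].mean() * pop["prior_cvd"].mean()
print(f"P(diabetes & CVD) = {both:.4f} vs {indep:.4f} under independence")
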