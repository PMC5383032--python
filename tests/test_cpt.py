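"""CPT estimation, pooling, and Monte Carlo categorical assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cvdsynth.categories import (
    DISEASE_STATES,
    disease_flags,
    disease_state,
    medication_flags,
    medication_state,
)
from cvdsynth.cpt import (
    ConditionalProbabilityTable,
    assign_categorical,
    assign_disease_state,
    assign_medication_state,
    estimate_cpt,
)
from cvdsynth.errors import ValidationError
from cvdsynth.pipeline import estimate_admin_cpts


def persons_in_band(n, band_low=30.0, band_width=15.0, seed=0, **overrides):
    """Bare demographic frame for assignment tests."""
    rng = np.random.default_rng(seed)
    pop = pd.DataFrame({
        "person_id": [f"x{i}" for i in range(n)],
        "age": band_low + rng.random(n) * band_width,
        "sex": np.where(rng.random(n) < 0.5, "female", "male"),
        "ethnicity": "European",
        "nzdep_quintile": 3,
        "smoking": "never",
        "diabetes": pd.NA, "prior_cvd": pd.NA,
        "ll_med": pd.NA, "bpl_med": pd.NA,
        "sbp": np.nan, "tc_hdl": np.nan, "fam_hx": pd.NA,
    })
    for k, v in overrides.items():
        pop[k] = v
    return pop


class TestEstimateCpt:
    def test_direct_relative_frequency(self):
        rec = pd.DataFrame({
            "age": [35.0] * 10,
            "sex": ["female"] * 10,
            "disease_state": ["diabetes_only"] * 3 + ["neither"] * 7,
        })
        cpt = estimate_cpt(rec, ["age_band", "sex"], "disease_state",
                           categories=["neither", "diabetes_only"], min_cell=5)
        probs, level = cpt.resolve(("30-44", "female"))
        assert level == 0
        assert probs[1] == pytest.approx(0.3)

    def test_sparse_cell_pooled_to_parent(self):
        # 5 records in (30-44, male) < min_cell -> estimate from the parent
        # (30-44) stratum; brute-force pooled frequency is the oracle
        rec = pd.DataFrame({
            "age": [35.0] * 25,
            "sex": ["male"] * 5 + ["female"] * 20,
            "flag": [True] * 5 + [True] * 5 + [False] * 15,
        })
        cpt = estimate_cpt(rec, ["age_band", "sex"], "flag",
                           categories=[False, True], min_cell=20)
        probs, level = cpt.resolve(("30-44", "male"))
        assert level == 1
        assert probs[1] == pytest.approx(10 / 25)

    def test_rows_sum_to_one(self, admin):
        cpt_disease, cpt_meds = estimate_admin_cpts(admin)
        for cpt in (cpt_disease, cpt_meds):
            for level in cpt.levels:
                for probs, _ in level.values():
                    assert abs(probs.sum() - 1.0) < 1e-12

    def test_absent_category_rejected(self):
        rec = pd.DataFrame({"age": [35.0] * 4, "flag": [False] * 4})
        with pytest.raises(ValidationError, match="absent"):
            estimate_cpt(rec, ["age_band"], "flag", categories=[False, True])

    def test_empty_records_rejected(self):
        with pytest.raises(ValidationError):
            estimate_cpt(pd.DataFrame({"age": [], "flag": []}),
                         ["age_band"], "flag")

    def test_serialization_round_trip(self, tmp_path, admin):
        cpt, _ = estimate_admin_cpts(admin)
        path = tmp_path / "cpt.csv"
        cpt.write(path)
        back = ConditionalProbabilityTable.read(path)
        assert back.conditioning_vars == cpt.conditioning_vars
        assert back.categories == cpt.categories
        combo = ("45-54", "female", "Maori")
        np.testing.assert_allclose(back.resolve(combo)[0],
                                   cpt.resolve(combo)[0], atol=1e-14)


class TestAssignCategorical:
    def test_observed_proportion_within_4_se(self):
        pop = persons_in_band(100_000)
        cpt = ConditionalProbabilityTable.from_probabilities(
            ["age_band"], "smoking", ["never", "ex", "current"],
            {("30-44",): [0.589, 0.223, 0.189]}, normalize=True)
        out = assign_categorical(pop, cpt, np.random.default_rng(5))
        p = (out == "current").mean()
        se = np.sqrt(0.189 * 0.811 / 100_000)
        assert abs(p - 0.189) < 4 * se

    def test_degenerate_row_assigns_single_category(self):
        pop = persons_in_band(500)
        cpt = ConditionalProbabilityTable.from_probabilities(
            ["age_band"], "smoking", ["never", "ex", "current"],
            {("30-44",): [0.0, 1.0, 0.0]})
        out = assign_categorical(pop, cpt, np.random.default_rng(1))
        assert (out == "ex").all()

    def test_chi_square_goodness_of_fit(self):
        pop = persons_in_band(50_000)
        probs = [0.5, 0.25, 0.15, 0.1]
        cpt = ConditionalProbabilityTable.from_probabilities(
            ["age_band"], "disease_state", list(DISEASE_STATES),
            {("30-44",): probs})
        out = assign_categorical(pop, cpt, np.random.default_rng(9))
        observed = out.value_counts().reindex(DISEASE_STATES, fill_value=0)
        res = stats.chisquare(observed, np.array(probs) * 50_000)
        assert res.pvalue > 0.001

    def test_unresolvable_combination_raises(self):
        pop = persons_in_band(10)
        cpt = ConditionalProbabilityTable.from_probabilities(
            ["age_band"], "smoking", ["never", "ex", "current"],
            {("75-84",): [1.0, 0.0, 0.0]})
        with pytest.raises(ValidationError, match="30-44"):
            assign_categorical(pop, cpt, np.random.default_rng(0))


class TestJointAssignment:
    def test_zero_both_probability_never_cooccurs(self):
        pop = persons_in_band(5_000)
        cpt = ConditionalProbabilityTable.from_probabilities(
            ["age_band"], "disease_state", list(DISEASE_STATES),
            {("30-44",): [0.7, 0.2, 0.1, 0.0]})
        out = assign_disease_state(pop, cpt, np.random.default_rng(3))
        assert not (out["diabetes"] & out["prior_cvd"]).any()

    def test_disease_association_recovered(self, truth, admin, world_cfg):
        # the generating world couples diabetes and CVD; the CPT-sampled
        # population must reproduce the truth's cross-product odds ratio
        cpt_disease, _ = estimate_admin_cpts(admin)
        pop = persons_in_band(len(truth), seed=2)
        pop["age"] = truth["age"].to_numpy()
        pop["sex"] = truth["sex"].to_numpy()
        pop["ethnicity"] = truth["ethnicity"].to_numpy()
        out = assign_disease_state(pop, cpt_disease, np.random.default_rng(8))

        def cross_or(df):
            a = (df.diabetes & df.prior_cvd).sum()
            b = (df.diabetes & ~df.prior_cvd).sum()
            c = (~df.diabetes & df.prior_cvd).sum()
            d = (~df.diabetes & ~df.prior_cvd).sum()
            return (a * d) / (b * c)

        want = cross_or(truth)
        got = cross_or(out)
        assert want > 1.5  # the fixture really embeds an association
        assert abs(np.log(got) - np.log(want)) < 0.35

    def test_medication_requires_disease_first(self, admin):
        _, cpt_meds = estimate_admin_cpts(admin)
        pop = persons_in_band(10)
        with pytest.raises(ValidationError, match="prior_cvd"):
            assign_medication_state(pop, cpt_meds, np.random.default_rng(0))

    def test_medication_prevalence_tracks_cvd_status(self):
        cpt = ConditionalProbabilityTable.from_probabilities(
            ["age_band", "prior_cvd"], "medication_state",
            ["neither", "ll_only", "bpl_only", "both"],
            {("30-44", False): [0.85, 0.05, 0.05, 0.05],
             ("30-44", True): [0.10, 0.10, 0.20, 0.60]})
        pop = persons_in_band(20_000, diabetes=False)
        pop["prior_cvd"] = np.arange(20_000) % 2 == 0
        out = assign_medication_state(pop, cpt, np.random.default_rng(4))
        p_cvd = out.loc[out["prior_cvd"], "bpl_med"].mean()
        p_no = out.loc[~out["prior_cvd"], "bpl_med"].mean()
        assert p_cvd == pytest.approx(0.8, abs=0.02)
        assert p_no == pytest.approx(0.1, abs=0.02)

    def test_all_zero_medication_probabilities(self):
        cpt = ConditionalProbabilityTable.from_probabilities(
            ["age_band"], "medication_state",
            ["neither", "ll_only", "bpl_only", "both"],
            {("30-44",): [1.0, 0.0, 0.0, 0.0]})
        pop = persons_in_band(300, prior_cvd=False, diabetes=False)
        out = assign_medication_state(pop, cpt, np.random.default_rng(2))
        assert not out["ll_med"].any() and not out["bpl_med"].any()

    def test_order_invariance_of_marginals(self):
        cpt = ConditionalProbabilityTable.from_probabilities(
            ["age_band"], "smoking", ["never", "ex", "current"],
            {("30-44",): [0.6, 0.25, 0.15]})
        pop = persons_in_band(40_000)
        a = assign_categorical(pop, cpt, np.random.default_rng(6))
        perm = pop.sample(frac=1.0, random_state=1)
        b = assign_categorical(perm, cpt, np.random.default_rng(6))
        pa = (a == "current").mean()
        pb = (b == "current").mean()
        assert abs(pa - pb) < 4 * np.sqrt(0.15 * 0.85 / 40_000) * 2


@settings(deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=8))
def test_joint_state_codings_are_bijective(pairs):
    a = pd.Series([p[0] for p in pairs])
    b = pd.Series([p[1] for p in pairs])
    da, db = disease_flags(disease_state(a, b))
    assert list(da) == list(a) and list(db) == list(b)
    ma, mb = medication_flags(medication_state(a, b))
    assert list(ma) == list(a) and list(mb) == list(b)
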