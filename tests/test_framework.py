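"""Demographic framework: prioritization, suppression, unknowns, expansion."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cvdsynth.errors import FeasibilityError, ValidationError
from cvdsynth.framework import (
    SuppressionResolutionPolicy,
    _largest_remainder,
    expand_strata,
    prioritize_ethnicity,
    redistribute_unknowns,
    resolve_suppressed_cells,
)
from cvdsynth.io import CENSUS_COLUMNS, CENSUS_COUNT_COLUMNS


def make_strata(rows):
    df = pd.DataFrame(rows, columns=CENSUS_COLUMNS)
    df[CENSUS_COUNT_COLUMNS] = df[CENSUS_COUNT_COLUMNS].astype("Int64")
    return df


class TestPrioritizeEthnicity:
    @pytest.mark.parametrize(
        "reported, expected",
        [
            ({"European", "Maori"}, "Maori"),
            ({"Chinese", "Indian"}, "Indian"),
            ({"European"}, "European"),
            ({"Other", "OtherAsian", "Pacific"}, "Pacific"),
        ],
    )
    def test_highest_priority_wins(self, reported, expected):
        assert prioritize_ethnicity(reported) == expected

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            prioritize_ethnicity(set())


class TestSuppressionResolution:
    def test_uniform_fill_always_in_1_to_5(self):
        strata = make_strata([[40, "female", "Maori", "3", pd.NA, 7, pd.NA]])
        for seed in range(20):
            out = resolve_suppressed_cells(
                strata, SuppressionResolutionPolicy(rng_seed=seed))
            vals = out.loc[0, ["never", "current"]]
            assert all(1 <= v <= 5 for v in vals)
            assert out.loc[0, "ex"] == 7

    def test_row_without_suppression_unchanged(self):
        strata = make_strata([[40, "female", "Maori", "3", 10, 7, 6]])
        out = resolve_suppressed_cells(strata)
        pd.testing.assert_frame_equal(out, strata)

    def test_total_constrained_fill_matches_known_total(self):
        # two suppressed cells, known row total 47, numeric cell 40:
        # brute-force enumeration says the fills must sum to 7, each in [1,5]
        feasible = {
            c for c in itertools.product(range(1, 6), repeat=2) if sum(c) == 7
        }
        strata = make_strata([[40, "female", "Maori", "3", pd.NA, 40, pd.NA]])
        for seed in range(10):
            out = resolve_suppressed_cells(
                strata,
                SuppressionResolutionPolicy("total_constrained", rng_seed=seed),
                row_totals=pd.Series({0: 47}),
            )
            pair = (int(out.loc[0, "never"]), int(out.loc[0, "current"]))
            assert pair in feasible

    def test_infeasible_total_raises(self):
        strata = make_strata([[40, "female", "Maori", "3", pd.NA, 40, 6]])
        with pytest.raises(FeasibilityError):
            resolve_suppressed_cells(
                strata,
                SuppressionResolutionPolicy("total_constrained"),
                row_totals=pd.Series({0: 60}),  # needs 14 from one cell
            )


class TestRedistributeUnknowns:
    def test_exact_proportional_split(self):
        strata = make_strata([
            [40, "female", "Maori", "3", 60, 0, 0],
            [40, "female", "European", "3", 40, 0, 0],
            [40, "female", "Unknown", "3", 10, 0, 0],
        ])
        out = redistribute_unknowns(strata)
        assert "Unknown" not in set(out["ethnicity"])
        got = out.set_index("ethnicity")["never"]
        assert got["Maori"] == 66 and got["European"] == 44

    def test_no_unknowns_is_identity(self):
        strata = make_strata([[40, "female", "Maori", "3", 10, 7, 6]])
        out = redistribute_unknowns(strata)
        assert out[CENSUS_COUNT_COLUMNS].astype(int).equals(
            strata[CENSUS_COUNT_COLUMNS].astype(int))

    def test_total_conserved_for_uneven_split(self):
        strata = make_strata([
            [40, "male", "Maori", "1", 3, 0, 0],
            [40, "male", "Pacific", "1", 2, 0, 0],
            [40, "male", "European", "1", 2, 0, 0],
            [40, "male", "Unknown", "1", 7, 0, 0],
        ])
        out = redistribute_unknowns(strata)
        assert int(out["never"].sum()) == 14  # 7 known + 7 reallocated

    def test_grand_total_conserved_on_fixture(self, census):
        resolved = resolve_suppressed_cells(
            census, SuppressionResolutionPolicy(rng_seed=5))
        before = int(resolved[CENSUS_COUNT_COLUMNS].sum().sum())
        out = redistribute_unknowns(resolved)
        assert int(out[CENSUS_COUNT_COLUMNS].sum().sum()) == before
        assert "Unknown" not in set(out["ethnicity"])
        assert "Unknown" not in set(out["nzdep_quintile"])


class TestExpandStrata:
    def test_counts_and_age_band(self):
        strata = make_strata([[40, "female", "Maori", "3", 12, 0, 0]])
        pop = expand_strata(strata, np.random.default_rng(0),
                            smoking_mode="deterministic")
        assert len(pop) == 12
        assert ((pop["age"] >= 40) & (pop["age"] < 41)).all()
        assert (pop["sex"] == "female").all()
        assert (pop["smoking"] == "never").all()

    def test_zero_count_yields_no_persons(self):
        strata = make_strata([[40, "female", "Maori", "3", 0, 0, 0]])
        pop = expand_strata(strata, np.random.default_rng(0))
        assert len(pop) == 0

    def test_count_conservation_on_fixture(self, census):
        resolved = redistribute_unknowns(
            resolve_suppressed_cells(census,
                                     SuppressionResolutionPolicy(rng_seed=5)))
        total = int(resolved[CENSUS_COUNT_COLUMNS].sum().sum())
        for seed in (0, 1):
            pop = expand_strata(resolved, np.random.default_rng(seed))
            assert len(pop) == total

    def test_marginal_exactness_deterministic_mode(self, census):
        resolved = redistribute_unknowns(
            resolve_suppressed_cells(census,
                                     SuppressionResolutionPolicy(rng_seed=5)))
        pop = expand_strata(resolved, np.random.default_rng(3),
                            smoking_mode="deterministic")
        pop = pop.assign(age_band_low=np.floor(pop["age"]).astype(int))
        got = (
            pop.groupby(["age_band_low", "sex", "ethnicity", "nzdep_quintile",
                         "smoking"]).size()
        )
        want = resolved.assign(
            nzdep_quintile=resolved["nzdep_quintile"].astype(int)
        ).melt(
            id_vars=["age_band_low", "sex", "ethnicity", "nzdep_quintile"],
            value_vars=CENSUS_COUNT_COLUMNS, var_name="smoking", value_name="n",
        )
        want = want[want["n"] > 0].set_index(
            ["age_band_low", "sex", "ethnicity", "nzdep_quintile", "smoking"]
        )["n"].astype(int)
        assert got.sort_index().equals(want.sort_index())

    def test_ages_uniform_within_band(self):
        strata = make_strata([[52, "male", "European", "2", 3000, 0, 0]])
        pop = expand_strata(strata, np.random.default_rng(7))
        stat = stats.kstest(pop["age"], stats.uniform(loc=52, scale=1).cdf)
        assert stat.pvalue > 0.001
        assert pop["age"].min() >= 52 and pop["age"].max() < 53

    def test_age_range_bounds_on_fixture(self, census):
        resolved = redistribute_unknowns(
            resolve_suppressed_cells(census,
                                     SuppressionResolutionPolicy(rng_seed=5)))
        pop = expand_strata(resolved, np.random.default_rng(1))
        assert pop["age"].min() >= 30 and pop["age"].max() < 85

    def test_identical_seed_identical_output(self, census):
        resolved = redistribute_unknowns(
            resolve_suppressed_cells(census,
                                     SuppressionResolutionPolicy(rng_seed=5)))
        a = expand_strata(resolved, np.random.default_rng(9)).to_csv()
        b = expand_strata(resolved, np.random.default_rng(9)).to_csv()
        assert a == b

    def test_monte_carlo_smoking_matches_stratum_proportions(self):
        strata = make_strata([[45, "female", "European", "1", 5000, 3000, 2000]])
        pop = expand_strata(strata, np.random.default_rng(21),
                            smoking_mode="monte_carlo")
        p = (pop["smoking"] == "current").mean()
        se = np.sqrt(0.2 * 0.8 / 10_000)
        assert abs(p - 0.2) < 4 * se

    def test_negative_count_rejected(self):
        strata = make_strata([[40, "female", "Maori", "3", -1, 0, 0]])
        with pytest.raises(ValidationError):
            expand_strata(strata, np.random.default_rng(0))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    weights=st.lists(st.integers(min_value=0, max_value=1000), min_size=1,
                     max_size=8).filter(lambda w: sum(w) > 0),
    total=st.integers(min_value=0, max_value=500),
)
def test_largest_remainder_conserves_total(weights, total):
    alloc = _largest_remainder(np.array(weights, dtype=float), total)
    assert alloc.sum() == total
    assert (alloc >= 0).all()
    # zero-weight targets never receive anything
    assert all(a == 0 for a, w in zip(alloc, weights) if w == 0)
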