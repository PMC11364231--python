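"""CHE/IMP classification: closed forms, oracles, and nesting invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fintox.errors import JoinError, ValidationError
from fintox.toxicity import (
    Household,
    PovertyLine,
    ToxicityConfig,
    adult_equivalents,
    classify_che,
    classify_imp,
    non_subsistence_expenditure,
    normalize_poverty_line,
    subsistence_expenditure,
    toxicity_table,
)

from conftest import make_costs, make_households

RATE = 2339.0


class TestAdultEquivalents:
    @pytest.mark.parametrize(
        "adults,children,expected",
        [(1, 0, 1.0), (2, 2, 2.1), (2, 0, 1.5), (3, 1, 2.3)],
    )
    def test_oecd_modified_closed_form(self, adults, children, expected):
        assert adult_equivalents(adults, children) == pytest.approx(expected)

    def test_requires_one_adult(self):
        with pytest.raises(ValidationError):
            adult_equivalents(0, 2)

    @settings(derandomize=True, max_examples=60)
    @given(adults=st.integers(1, 20), children=st.integers(0, 20))
    def test_weights_decompose(self, adults, children):
        """Scale is additive: each extra adult adds 0.5, each child 0.3."""
        ha = adult_equivalents(adults, children)
        assert ha == pytest.approx(1 + 0.5 * (adults - 1) + 0.3 * children)
        assert ha >= 1.0


def _sort_and_slice_oracle(te, food, lo=45.0, hi=55.0):
    """Brute-force subsistence: sort by TE, keep rank-percentile window."""
    order = np.argsort(te, kind="stable")
    n = len(te)
    chosen = []
    for rank, idx in enumerate(order, start=1):
        pct = 100.0 * (rank - 0.5) / n
        if lo <= pct <= hi:
            chosen.append(food[idx])
    if not chosen:
        mid = order[np.argmin(np.abs(100.0 * (np.arange(1, n + 1) - 0.5) / n - 50.0))]
        chosen = [food[mid]]
    return float(np.mean(chosen))


class TestSubsistenceExpenditure:
    def test_constant_cohort_returns_common_food_spend(self):
        hh = make_households([(1e6, 8e5, 3e5, 2, 1)] * 10)
        assert subsistence_expenditure(hh) == pytest.approx(3e5)

    def test_matches_sort_and_slice_oracle(self):
        # 100 households, TE = rank, food = rank / 2
        te = np.arange(1, 101, dtype=float)
        food = te / 2
        rng = np.random.default_rng(7)
        perm = rng.permutation(100)
        hh = make_households(
            [(1e6, te[i], food[i], 1, 0) for i in perm]
        )
        expected = _sort_and_slice_oracle(te[perm], food[perm])
        assert subsistence_expenditure(hh) == pytest.approx(expected)
        # window [45, 55] of 100 ranks selects ranks 46..55 -> mean food 25.25
        assert subsistence_expenditure(hh) == pytest.approx(25.25)

    def test_single_household_degenerate_window(self):
        hh = make_households([(1e6, 9e5, 4e5, 1, 0)])
        assert subsistence_expenditure(hh) == pytest.approx(4e5)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            subsistence_expenditure(make_households([]).reindex([]))


class TestNse:
    @pytest.mark.parametrize(
        "te,se,expected",
        [(1_000_000, 400_000, 600_000), (300_000, 400_000, 0), (500_000, 0, 500_000)],
    )
    def test_subtraction_floored_at_zero(self, te, se, expected):
        assert non_subsistence_expenditure(te, se) == expected


class TestClassifyChe:
    def test_zero_oop_never_catastrophic(self):
        flags, any_che = classify_che(0, 1e6, 8e5)
        assert not any_che and not any(flags.values())

    def test_threshold_arithmetic(self):
        flags, any_che = classify_che(110_000, 1_000_000, 800_000)
        assert flags["che_10_te"] is True
        assert flags["che_25_te"] is False
        assert flags["che_40_nse"] is False
        assert any_che

    def test_exact_boundary_flags_under_ge(self):
        flags, _ = classify_che(250_000, 1_000_000, 900_000)
        assert flags["che_25_te"] is True

    def test_gt_comparison_excludes_boundary(self):
        cfg = ToxicityConfig(comparison="gt")
        flags, _ = classify_che(250_000, 1_000_000, 900_000, cfg)
        assert flags["che_25_te"] is False

    def test_zero_nse_flags_only_positive_spending(self):
        flags0, _ = classify_che(0, 0, 0)
        flags1, _ = classify_che(1, 0, 0)
        assert flags0["che_40_nse"] is False
        assert flags1["che_40_nse"] is True


class TestPovertyLines:
    def test_national_monthly_line_annualized(self):
        line = PovertyLine("national", 49_320, "TZS", "per_month")
        assert normalize_poverty_line(line, RATE) == pytest.approx(591_840)

    def test_usd_daily_line_annualized(self):
        line = PovertyLine("usd190", 1.90, "USD", "per_day")
        assert normalize_poverty_line(line, RATE) == pytest.approx(1.90 * 365 * RATE)

    def test_zero_line(self):
        assert normalize_poverty_line(PovertyLine("z", 0, "USD", "per_day")) == 0


def _hh(income, adults=1, children=0, missing=False):
    return Household(
        n_adults=adults,
        n_children=children,
        annual_income=float("nan") if missing else income,
        annual_total_expenditure=income,
        annual_food_expenditure=income * 0.4,
        income_missing=missing,
    )


class TestClassifyImp:
    def test_rich_household_no_flags(self):
        flags, any_imp = classify_imp(_hh(50e6), 0)
        assert not any_imp and not any(flags.values())

    def test_boundary_just_below_national_line(self):
        # post-OOP income of 49,319 TZS/month per AE is below the 49,320 line
        income = 49_319.0 * 12
        flags, any_imp = classify_imp(_hh(income), 0)
        assert flags["imp_national"] is True and any_imp

    def test_oop_at_least_income_floors_to_zero_and_flags_all(self):
        flags, any_imp = classify_imp(_hh(1e6), 2e6)
        assert any_imp and all(flags.values())

    def test_missing_income_excluded_not_crash(self):
        flags, any_imp = classify_imp(_hh(0, missing=True), 1e5)
        assert any_imp is None and all(v is None for v in flags.values())

    def test_newly_poor_mode_requires_pre_oop_above_line(self):
        cfg = ToxicityConfig(imp_mode="newly_poor")
        # already below every line before OOP -> not newly poor
        flags, any_imp = classify_imp(_hh(100_000), 50_000, cfg)
        assert not any_imp


def _literal_oracle(income, ha, te, nse, oop, missing):
    """Brute-force re-evaluation of the two definitions as literal arithmetic."""
    che = (
        oop >= 0.10 * te
        or oop >= 0.25 * te
        or (oop >= 0.40 * nse if nse > 0 else oop > 0)
    )
    if missing:
        return che, None
    remaining = max(income - oop, 0.0) / ha
    lines = [49_320.0 * 12, 1.90 * 365 * RATE, 3.20 * 365 * RATE]
    imp = any(remaining < z for z in lines)
    return che, imp


class TestToxicityTable:
    def test_single_patient_consistent(self):
        hh = make_households([(2e6, 1.5e6, 6e5, 2, 1)])
        out = toxicity_table(hh, make_costs([200_000]))
        assert len(out) == 1
        row = out.iloc[0]
        assert row["any_che"] == (
            row["che_10_te"] or row["che_25_te"] or row["che_40_nse"]
        )
        assert row["h_a"] == pytest.approx(1.8)

    def test_order_invariance(self):
        rng = np.random.default_rng(11)
        hh = make_households(
            [
                (rng.uniform(5e5, 5e6), rng.uniform(4e5, 4e6), rng.uniform(1e5, 3e5), 2, 1)
                for _ in range(30)
            ]
        )
        costs = make_costs(rng.uniform(0, 1e6, size=30))
        base = toxicity_table(hh, costs).set_index("patient_id")
        shuffled = toxicity_table(
            hh.sample(frac=1, random_state=3), costs.sample(frac=1, random_state=4)
        ).set_index("patient_id")
        pd.testing.assert_frame_equal(
            base.sort_index(), shuffled.sort_index(), check_like=True
        )

    def test_unmatched_identifier_raises_join_error(self):
        hh = make_households([(1e6, 8e5, 3e5, 1, 0)])
        costs = make_costs([1e5])
        costs.loc[0, "patient_id"] = "P9999"
        with pytest.raises(JoinError, match="P9999"):
            toxicity_table(hh, costs)

    def test_matches_literal_oracle_on_random_cohort(self):
        """Classifier output equals a brute-force re-evaluation written as
        literal threshold arithmetic, on a 100-patient cohort."""
        rng = np.random.default_rng(23)
        rows = []
        for i in range(100):
            te = rng.uniform(1e5, 5e6)
            rows.append(
                (
                    rng.uniform(1e5, 8e6),  # income
                    te,
                    te * rng.uniform(0.2, 0.7),  # food
                    int(rng.integers(1, 5)),
                    int(rng.integers(0, 5)),
                    bool(rng.random() < 0.05),  # missing income
                )
            )
        hh = make_households(rows)
        oops = rng.uniform(0, 1.5e6, size=100)
        out = toxicity_table(hh, make_costs(oops))
        se = out.attrs["subsistence_expenditure"]
        for i, row in out.iterrows():
            income, te, food, adults, children, missing = rows[i]
            nse = max(te - se, 0.0)
            ha = adult_equivalents(adults, children)
            che, imp = _literal_oracle(income, ha, te, nse, oops[i], missing)
            assert row["any_che"] == che, f"patient {i}"
            assert row["any_imp"] == imp or (missing and row["imp_excluded"])

    def test_threshold_and_line_nesting(self):
        """25%-of-TE positives nest in 10%-of-TE; $1.90 positives nest in
        $3.20; any_* equals the OR of component flags."""
        rng = np.random.default_rng(31)
        hh = make_households(
            [
                (
                    rng.uniform(1e5, 8e6),
                    rng.uniform(1e5, 5e6),
                    rng.uniform(2e4, 1e5),
                    int(rng.integers(1, 4)),
                    int(rng.integers(0, 4)),
                )
                for _ in range(80)
            ]
        )
        out = toxicity_table(hh, make_costs(rng.uniform(0, 2e6, size=80)))
        assert (~out["che_25_te"] | out["che_10_te"]).all()
        assert (~out["imp_usd190"].astype(bool) | out["imp_usd320"].astype(bool)).all()
        assert (
            out["any_che"]
            == (out["che_10_te"] | out["che_25_te"] | out["che_40_nse"])
        ).all()
        imp_or = (
            out["imp_national"].astype(bool)
            | out["imp_usd190"].astype(bool)
            | out["imp_usd320"].astype(bool)
        )
        eligible = ~out["imp_excluded"]
        assert (out.loc[eligible, "any_imp"].astype(bool) == imp_or[eligible]).all()


@settings(derandomize=True, max_examples=80)
@given(
    oop=st.floats(0, 5e6, allow_nan=False),
    extra=st.floats(0, 5e6, allow_nan=False),
    te=st.floats(1e4, 1e7, allow_nan=False),
    nse_frac=st.floats(0, 1, allow_nan=False),
    income=st.floats(0, 2e7, allow_nan=False),
)
def test_flags_monotone_in_oop(oop, extra, te, nse_frac, income):
    """Raising OOP never turns a true CHE or IMP flag false."""
    nse = te * nse_frac
    lo_flags, lo_any = classify_che(oop, te, nse)
    hi_flags, hi_any = classify_che(oop + extra, te, nse)
    for k in lo_flags:
        assert not (lo_flags[k] and not hi_flags[k])
    assert not (lo_any and not hi_any)
    hh = _hh(income)
    lo_i, lo_any_i = classify_imp(hh, oop)
    hi_i, hi_any_i = classify_imp(hh, oop + extra)
    for k in lo_i:
        assert not (lo_i[k] and not hi_i[k])
    assert not (lo_any_i and not hi_any_i)
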