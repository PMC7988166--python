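"""Genotype-count statistics and the AI return-interval mortality contrast."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recscan import (
    GenotypeCounts,
    allele_frequency,
    bin_return_interval,
    classify_mating,
    concordance_rate,
    homozygote_absence_binomial,
    hwe_deficit_chisq,
    hwe_expected,
    mortality_contrast,
    segregation_test,
    simulate_matings,
)
from recscan.stats import mortality_table_from_counts

counts_triples = st.tuples(
    st.integers(0, 5000), st.integers(0, 5000), st.integers(0, 5000)
).filter(lambda t: sum(t) > 0)


@pytest.mark.parametrize(
    "triple, expected",
    [
        ((473, 44, 0), 0.043),
        ((436, 79, 0), 0.077),
        ((435, 82, 0), 0.079),
        ((1840, 140, 0), 0.035),
        ((1382, 211, 0), 0.066),
        ((946, 191, 0), 0.084),
        ((0, 0, 10), 1.000),
    ],
)
def test_allele_frequency_printed_values(triple, expected):
    assert allele_frequency(GenotypeCounts(*triple)) == pytest.approx(expected)


def test_allele_frequency_empty_errors():
    with pytest.raises(ValueError):
        allele_frequency(GenotypeCounts(0, 0, 0))


@pytest.mark.parametrize(
    "triple, rounded",
    [
        ((473, 44, 0), (474, 42, 1)),
        ((436, 79, 0), (439, 73, 3)),
        ((1382, 211, 0), (1389, 197, 7)),
    ],
)
def test_hwe_expected_rounded_triples(triple, rounded):
    assert hwe_expected(GenotypeCounts(*triple))[1] == rounded


def test_hwe_expected_homozygote_class_values():
    exact, _ = hwe_expected(GenotypeCounts(946, 191, 0))
    assert exact[2] == pytest.approx(8.02, abs=0.005)
    exact, _ = hwe_expected(GenotypeCounts(1382, 211, 0))
    assert exact[2] == pytest.approx(6.99, abs=0.005)


def test_hwe_expected_balanced_het():
    exact, _ = hwe_expected(GenotypeCounts(0, 100, 0))
    assert exact == pytest.approx((25.0, 50.0, 25.0))


@settings(derandomize=True, max_examples=100, deadline=None)
@given(counts_triples)
def test_hwe_expected_sums_to_n(triple):
    exact, _ = hwe_expected(GenotypeCounts(*triple))
    assert sum(exact) == pytest.approx(sum(triple))


def test_hwe_deficit_chisq_printed_value():
    chi2, p = hwe_deficit_chisq(GenotypeCounts(946, 191, 0), df=1)
    assert chi2 == pytest.approx(9.56, abs=0.01)
    assert round(p, 3) == 0.002


def test_hwe_deficit_chisq_df_sensitivity():
    chi2, p1 = hwe_deficit_chisq(GenotypeCounts(1382, 211, 0), df=1)
    assert chi2 == pytest.approx(8.01, abs=0.01)
    assert p1 == pytest.approx(0.0046, abs=0.0002)


def test_hwe_deficit_chisq_at_equilibrium():
    chi2, p = hwe_deficit_chisq(GenotypeCounts(25, 50, 25))
    assert chi2 == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(counts_triples.filter(lambda t: t[1] > 0 and t[0] > 0 and t[2] > 0))
def test_hwe_chisq_invariant_under_allele_relabeling(triple):
    a = hwe_deficit_chisq(GenotypeCounts(*triple))[0]
    b = hwe_deficit_chisq(GenotypeCounts(triple[2], triple[1], triple[0]))[0]
    assert a == pytest.approx(b, rel=1e-9)


def test_homozygote_absence_binomial():
    assert homozygote_absence_binomial(GenotypeCounts(100, 0, 0)) == 1.0
    p = homozygote_absence_binomial(GenotypeCounts(1382, 211, 0))
    f = 211 / 3186
    assert p == pytest.approx((1 - f * f) ** 1593, rel=1e-12)
    assert p == pytest.approx(9.10e-4, rel=1e-2)
    assert homozygote_absence_binomial(GenotypeCounts(0, 0, 5)) == 0.0


def test_segregation_test_embryo_counts():
    expected, chi2, p = segregation_test(GenotypeCounts(7, 27, 0), df=1)
    assert expected == pytest.approx((8.5, 17.0, 8.5))
    assert chi2 == pytest.approx(14.65, abs=0.01)
    assert round(p, 4) == 0.0001


def test_segregation_test_df2_documents_sensitivity():
    _, _, p = segregation_test(GenotypeCounts(7, 27, 0), df=2)
    assert p == pytest.approx(6.6e-4, rel=0.01)


def test_segregation_test_at_expectation():
    _, chi2, p = segregation_test(GenotypeCounts(25, 50, 25))
    assert chi2 == 0.0 and p == 1.0


@pytest.mark.parametrize(
    "days, label",
    [(29, "18-29"), (30, "30-60"), (60, "30-60"), (61, "61-90"), (91, "91-140"),
     (141, "141+"), (250, "141+"), (15, "excluded")],
)
def test_bin_return_interval(days, label):
    assert bin_return_interval(days) == label


def test_bin_return_interval_negative_errors():
    with pytest.raises(ValueError):
        bin_return_interval(-1)


@pytest.mark.parametrize(
    "sire, cow, expected",
    [(True, True, "risk"), (True, False, "other"), (False, True, "other"),
     (False, False, "other")],
)
def test_classify_mating(sire, cow, expected):
    assert classify_mating(sire, cow) == expected


@pytest.mark.parametrize(
    "bin_label, cells, pct",
    [
        ("61-90", (120, 39, 74731, 16441), (25, 18)),
        ("30-60", (106, 43, 91732, 23592), (29, 20)),
    ],
)
def test_mortality_percentages_from_published_counts(bin_label, cells, pct):
    table = mortality_table_from_counts(bin_label, *cells)
    assert (table.mortality_risk_pct, table.mortality_other_pct) == pct
    assert 0 <= table.p <= 1


def test_mortality_chi2_without_correction():
    table = mortality_table_from_counts("30-60", 106, 43, 91732, 23592)
    assert table.chi2 == pytest.approx(6.45, abs=0.01)
    assert table.p == pytest.approx(0.011, abs=0.001)


def test_mortality_contrast_from_records():
    records = pd.DataFrame(
        {
            "cow_id": [f"c{i}" for i in range(8)],
            "sire_id": ["b1"] * 8,
            "ai_date": ["2020-01-01"] * 8,
            # risk matings: one 45-day return, one non-return;
            # other matings: one 45-day return, one 75-day return, rest non-return
            "days_to_2nd_ai": [45, None, 45, 75, None, None, None, None],
            "sire_carrier": [True, True, False, True, False, False, True, None],
            "cow_carrier": [True, True, True, False, False, True, False, True],
        }
    )
    table = mortality_contrast(records, "30-60")
    assert table.n_dropped_unknown == 1
    assert (table.risk_non_return, table.risk_second_ai) == (1, 1)
    # the 75-day return is excluded from the 30-60 contrast
    assert (table.other_non_return, table.other_second_ai) == (3, 1)
    assert table.mortality_risk_pct == 50
    assert table.mortality_other_pct == 25


def test_mortality_contrast_degenerate_skips_test():
    records = pd.DataFrame(
        {
            "cow_id": ["a", "b"],
            "sire_id": ["s", "s"],
            "ai_date": ["2020-01-01"] * 2,
            "days_to_2nd_ai": [None, None],
            "sire_carrier": [True, False],
            "cow_carrier": [True, False],
        }
    )
    with pytest.warns(UserWarning):
        table = mortality_contrast(records, "30-60")
    assert np.isnan(table.p)
    assert table.mortality_risk_pct == 0 and table.mortality_other_pct == 0


BASELINE = {"18-29": 0.10, "30-60": 0.08, "61-90": 0.05, "91-140": 0.03, "141+": 0.02}


def test_mortality_power_on_simulated_excess():
    """A 7% excess early loss in carrier x carrier matings is detected in
    >=95% of replicates at alpha=0.05 with 50k records."""
    rejections = 0
    n_rep = 100
    for rep in range(n_rep):
        records = simulate_matings(50_000, 0.095, BASELINE, 0.07, seed=7_000 + rep)
        table = mortality_contrast(records, "30-60")
        rejections += table.p < 0.05
    assert rejections >= 95


def test_mortality_type_i_error_calibrated():
    """With zero excess loss the 2x2 test rejects at ~ the nominal rate.

    Run with enough carrier x carrier matings (carrier_freq 0.3 -> ~9% of
    4,000 records) that the chi-square's asymptotics hold; with very few
    risk matings the discrete 2x2 is conservative by construction.
    """
    rejections = 0
    n_rep = 400
    for rep in range(n_rep):
        records = simulate_matings(4_000, 0.3, BASELINE, 0.0, seed=40_000 + rep)
        table = mortality_contrast(records, "30-60")
        if not np.isnan(table.p):
            rejections += table.p < 0.05
    assert 0.02 <= rejections / n_rep <= 0.09


def test_concordance_rate():
    a = pd.DataFrame(np.zeros((4, 5)))
    assert concordance_rate(a, a) == 100.0
    b = a.copy()
    b.iloc[0, 0] = 1
    assert concordance_rate(a, b) == 95.0
    # 105 entries: 5 mismatches, 5 missing -> 95 matches / 100 compared
    a = pd.DataFrame(np.zeros((5, 21)))
    b = a.copy()
    b.iloc[0, :5] = 1
    b.iloc[1, :5] = np.nan
    assert concordance_rate(a, b) == 95.0


def test_concordance_rate_all_missing_errors():
    a = pd.DataFrame([[np.nan]])
    with pytest.raises(ValueError):
        concordance_rate(a, a)
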