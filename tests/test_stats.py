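"""Statistical battery: closed forms, design arithmetic, calibration."""

import numpy as np
import pandas as pd
import pytest

from waveconn.stats import (
    familywise_correct,
    paired_t_test,
    rm_anova_from_wide,
    rm_anova_length,
    sensitivity_surface,
    sign_test,
    two_sample_t_test,
    variation_over_lengths,
)


# -- variation statistic -----------------------------------------------------

@pytest.mark.parametrize("values,expected", [
    ([1, 3, 2], 3.0),
    ([5, 5, 5, 5], 0.0),
    ([1, 2, 4, 7], 6.0),  # monotone: telescopes to |last - first|
])
def test_variation_over_lengths(values, expected):
    assert variation_over_lengths(values) == pytest.approx(expected)


def test_variation_shift_and_scale_properties(rng):
    v = rng.standard_normal(8)
    base = variation_over_lengths(v)
    assert variation_over_lengths(v + 11.3) == pytest.approx(base)
    assert variation_over_lengths(2.5 * v) == pytest.approx(2.5 * base)


def test_variation_needs_two_lengths():
    with pytest.raises(ValueError):
        variation_over_lengths([1.0])


# -- t-tests -----------------------------------------------------------------

def test_paired_t_textbook_example():
    # d = (1, 2, 3): mean 2, sd 1, t = 2 / (1/sqrt(3)) = 2*sqrt(3)
    a = np.array([3.0, 5.0, 7.0])
    b = np.array([2.0, 3.0, 4.0])
    res = paired_t_test(a, b)
    assert res.statistic == pytest.approx(2.0 * np.sqrt(3.0))
    assert res.df == 2


def test_paired_t_study_degrees_of_freedom(rng):
    res = paired_t_test(rng.standard_normal(29), rng.standard_normal(29))
    assert res.df == 28


def test_paired_t_degenerate_on_identical_samples():
    a = np.arange(5.0)
    res = paired_t_test(a, a)
    assert res.degenerate
    assert np.isnan(res.statistic)


def test_two_sample_t_design():
    rng = np.random.default_rng(1)
    res = two_sample_t_test(rng.standard_normal(29), rng.standard_normal(29))
    assert res.df == 56
    a = np.arange(6.0)
    same = two_sample_t_test(a, a)
    assert same.statistic == pytest.approx(0.0)
    assert same.p_value == pytest.approx(1.0)


def test_two_sample_t_power_sanity(rng):
    a = rng.standard_normal(400)
    res = two_sample_t_test(a, rng.standard_normal(400) + 1.0)
    assert res.p_value < 1e-6


def test_two_sample_t_matches_pooled_closed_form():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = np.array([3.0, 5.0, 4.0])
    res = two_sample_t_test(a, b)
    sp2 = (3 * np.var(a, ddof=1) + 2 * np.var(b, ddof=1)) / 5
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 3))
    assert res.statistic == pytest.approx(t)
    assert res.df == 5


# -- sign test ---------------------------------------------------------------

def test_sign_test_closed_forms():
    res = sign_test(np.arange(8) + 1.0, np.zeros(8))
    assert res.p_value == pytest.approx(2.0 * 0.5**8)
    balanced = sign_test(np.array([1.0, 2, 3, 4, -1, -2, -3, -4]),
                         np.zeros(8))
    assert balanced.p_value == pytest.approx(1.0)
    degenerate = sign_test(np.ones(4), np.ones(4))
    assert degenerate.degenerate


def test_sign_test_drops_zero_differences():
    a = np.array([1.0, 1.0, 2.0, 3.0, 4.0])
    b = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
    res = sign_test(a, b)
    assert res.df == 3  # three non-zero differences
    assert res.p_value == pytest.approx(2.0 * 0.5**3)


# -- repeated-measures ANOVA -------------------------------------------------

@pytest.mark.parametrize("k,expected_df", [
    (10, (9, 252)),  # the full Daubechies length sweep
    (7, (6, 168)),   # Least Asymmetric
    (4, (3, 84)),    # Coiflet
])
def test_rm_anova_study_design_df(k, expected_df, rng):
    res = rm_anova_from_wide(rng.standard_normal((29, k)))
    assert res.df == expected_df


def test_rm_anova_matches_statsmodels_oracle(rng):
    from statsmodels.stats.anova import AnovaRM

    y = rng.standard_normal((12, 5)) + np.linspace(0, 1, 5)
    res = rm_anova_from_wide(y)
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(12), 5),
        "cond": np.tile(np.arange(5), 12),
        "y": y.ravel(),
    })
    sm = AnovaRM(long, "y", "subject", within=["cond"]).fit()
    assert res.statistic == pytest.approx(
        float(sm.anova_table["F Value"].iloc[0]), rel=1e-10)
    assert res.p_value == pytest.approx(
        float(sm.anova_table["Pr > F"].iloc[0]), rel=1e-8)


def test_rm_anova_length_requires_complete_grid(rng):
    rows = []
    for s in range(4):
        for L in (2, 4, 8):
            if s == 2 and L == 8:
                continue  # hole in the grid
            rows.append({"subject_id": f"s{s}", "group": "control",
                         "method": "MODWT", "family": "D", "length": L,
                         "scale": 2, "mean_corr": rng.standard_normal()})
    table = pd.DataFrame(rows)
    with pytest.raises(ValueError, match="missing"):
        rm_anova_length(table, "mean_corr", "D", 2)


# -- family-wise correction --------------------------------------------------

def test_familywise_correct():
    np.testing.assert_array_equal(familywise_correct([0.04], 0.05), [True])
    np.testing.assert_array_equal(
        familywise_correct([0.01, 0.04], 0.05), [True, False])
    assert not familywise_correct(np.ones(5), 0.05).any()
    with pytest.raises(ValueError):
        familywise_correct([1.5], 0.05)


# -- sensitivity surface -----------------------------------------------------

def _toy_table(effect, rng, n=12):
    rows = []
    for grp, shift in (("control", 0.0), ("patient", effect)):
        for s in range(n):
            rows.append({"subject_id": f"{grp}{s}", "group": grp,
                         "method": "MODWT", "family": "D", "length": 8,
                         "scale": 2,
                         "mean_corr": rng.standard_normal() + shift})
    return pd.DataFrame(rows)


def test_sensitivity_surface_transform(rng):
    surf = sensitivity_surface(_toy_table(3.0, rng), scale=2,
                               metrics=("mean_corr",))
    row = surf.iloc[0]
    assert row["neg_log10_p"] > 2.0  # strong effect: p well below 0.01
    null = sensitivity_surface(_toy_table(0.0, rng), scale=2,
                               metrics=("mean_corr",))
    assert null.iloc[0]["neg_log10_p"] < 2.0


def test_sensitivity_surface_identical_groups_gives_zero(rng):
    table = _toy_table(0.0, rng)
    patients = table[table["group"] == "control"].copy()
    patients["group"] = "patient"
    table = pd.concat([table[table["group"] == "control"], patients])
    surf = sensitivity_surface(table, scale=2, metrics=("mean_corr",))
    assert surf.iloc[0]["neg_log10_p"] == pytest.approx(0.0, abs=1e-12)


# -- type-I calibration (reduced reps; the acceptance suite runs 1000) -------

def test_type_one_error_quick_calibration():
    rng = np.random.default_rng(7)
    reps = 300
    rej = {"paired": 0, "two_sample": 0, "anova": 0}
    for _ in range(reps):
        rej["paired"] += paired_t_test(rng.standard_normal(20),
                                       rng.standard_normal(20)).p_value <= 0.05
        rej["two_sample"] += two_sample_t_test(
            rng.standard_normal(20), rng.standard_normal(20)).p_value <= 0.05
        rej["anova"] += rm_anova_from_wide(
            rng.standard_normal((15, 4))).p_value <= 0.05
    for name, count in rej.items():
        rate = count / reps
        assert 0.02 <= rate <= 0.09, (name, rate)
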