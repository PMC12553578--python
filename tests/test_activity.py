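"""Activity patterns, diel periods, alignment scoring, logistic summary."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import logit

from obsbias.activity import (
    ACTIVITY_PATTERNS,
    alignment_summary,
    classify_period,
    derive_pattern,
    fit_alignment_glm,
    is_aligned,
)
import pandas as pd


@pytest.mark.parametrize(
    "flags, pattern",
    [
        ((1, 0, 0), "diurnal"),
        ((0, 1, 0), "nocturnal"),
        ((0, 0, 1), "crepuscular"),
        ((1, 1, 0), "cathemeral"),
        ((1, 0, 1), "diurnal_crepuscular"),
        ((0, 1, 1), "nocturnal_crepuscular"),
        ((1, 1, 1), "flexible"),
        ((0, 0, 0), "unknown"),
    ],
)
def test_pattern_bijection(flags, pattern):
    assert derive_pattern(*flags) == pattern


def test_pattern_rejects_non_binary():
    with pytest.raises(ValueError):
        derive_pattern(2, 0, 0)


@pytest.mark.parametrize(
    "hour, policy, expected",
    [
        (12.0, "crepuscular_priority", {"diurnal"}),
        (6.5, "crepuscular_priority", {"crepuscular"}),
        (6.5, "overlapping", {"diurnal", "crepuscular"}),
        (23.0, "crepuscular_priority", {"nocturnal"}),
        (23.0, "overlapping", {"nocturnal"}),
        (17.0, "crepuscular_priority", {"crepuscular"}),
        (5.0, "overlapping", {"nocturnal", "crepuscular"}),
        (0.0, "crepuscular_priority", {"nocturnal"}),
    ],
)
def test_period_windows(hour, policy, expected):
    assert classify_period(hour, policy) == frozenset(expected)


def test_period_rejects_out_of_range():
    for h in (-0.1, 24.0, 25.0):
        with pytest.raises(ValueError):
            classify_period(h)


@given(st.floats(min_value=0.0, max_value=24.0, exclude_max=True))
@settings(max_examples=500, deadline=None)
def test_priority_periods_partition_the_clock(hour):
    assert len(classify_period(hour, "crepuscular_priority")) == 1


@given(st.floats(min_value=0.0, max_value=24.0, exclude_max=True))
@settings(max_examples=300, deadline=None)
def test_overlapping_periods_cover_every_hour(hour):
    periods = classify_period(hour, "overlapping")
    assert 1 <= len(periods) <= 2


@pytest.mark.parametrize(
    "pattern, period, expected",
    [
        ("diurnal", "diurnal", True),
        ("diurnal", "nocturnal", False),
        ("cathemeral", "diurnal", True),
        ("cathemeral", "nocturnal", True),
        ("cathemeral", "crepuscular", False),
        ("flexible", "nocturnal", True),
        ("flexible", "crepuscular", True),
        ("nocturnal_crepuscular", "crepuscular", True),
        ("nocturnal_crepuscular", "diurnal", False),
    ],
)
def test_alignment_rules(pattern, period, expected):
    assert is_aligned(pattern, period) is expected


def test_cathemeral_vetoed_by_overlapping_crepuscular_window():
    periods = classify_period(6.5, "overlapping")  # {diurnal, crepuscular}
    assert is_aligned("cathemeral", periods) is False
    assert is_aligned("diurnal", periods) is True


def test_unknown_pattern_is_an_error():
    with pytest.raises(ValueError):
        is_aligned("unknown", "diurnal")


def test_flexible_always_aligned_over_the_full_clock():
    for hour in np.arange(0, 24, 0.25):
        assert is_aligned("flexible", classify_period(hour))


def test_summary_strictly_diurnal_at_noon():
    res = alignment_summary([12.0] * 50, ["diurnal"] * 50, fit_glm=False)
    assert res.per_pattern.loc["diurnal", "prop_aligned"] == 1.0


def test_summary_counts_excluded_records():
    hours = [12.0, np.nan, 3.0, 12.0]
    patterns = ["diurnal", "diurnal", "unknown", "nocturnal"]
    res = alignment_summary(hours, patterns, fit_glm=False)
    assert res.n_no_time == 1
    assert res.n_unknown_pattern == 1
    assert res.per_pattern["n_obs"].sum() == 2


def test_saturated_logistic_reproduces_proportions():
    rng = np.random.default_rng(0)
    rows = []
    for pattern, rate, n in [("diurnal", 0.8, 1000), ("nocturnal", 0.2, 1000), ("crepuscular", 0.5, 400)]:
        aligned = rng.random(n) < rate
        rows.append(pd.DataFrame({"pattern": pattern, "aligned": aligned}))
    df = pd.concat(rows, ignore_index=True)
    fit = fit_alignment_glm(df, reference="diurnal")
    obs_rates = df.groupby("pattern")["aligned"].mean()
    # a one-factor saturated logit: fitted level probabilities = observed
    b0 = fit["coefficients"]["Intercept"]
    for lvl in ("nocturnal", "crepuscular"):
        fitted = 1 / (1 + np.exp(-(b0 + fit["coefficients"][lvl])))
        assert fitted == pytest.approx(obs_rates[lvl], abs=1e-8)
    assert 1 / (1 + np.exp(-b0)) == pytest.approx(obs_rates["diurnal"], abs=1e-8)


def test_logistic_closed_form_coefficients():
    # exact rates 0.8 vs 0.2: level-2 coefficient = logit(.2) - logit(.8)
    df = pd.DataFrame(
        {
            "pattern": ["a"] * 1000 + ["b"] * 1000,
            "aligned": [True] * 800 + [False] * 200 + [True] * 200 + [False] * 800,
        }
    )
    fit = fit_alignment_glm(df, reference="a")
    assert fit["coefficients"]["b"] == pytest.approx(logit(0.2) - logit(0.8), abs=1e-6)
    assert fit["coefficients"]["b"] == pytest.approx(-2.7726, abs=1e-4)
    assert fit["coefficients"]["Intercept"] == pytest.approx(logit(0.8), abs=1e-6)


def test_logistic_intercept_reference_rate():
    df = pd.DataFrame(
        {
            "pattern": ["ref"] * 400 + ["alt"] * 100,
            "aligned": [True] * 300 + [False] * 100 + [True] * 50 + [False] * 50,
        }
    )
    fit = fit_alignment_glm(df, reference="ref")
    assert fit["coefficients"]["Intercept"] == pytest.approx(np.log(3), abs=1e-6)


def test_logistic_equal_rates_give_null_coefficient():
    df = pd.DataFrame(
        {
            "pattern": ["a"] * 200 + ["b"] * 200,
            "aligned": ([True, False] * 100) * 2,
        }
    )
    fit = fit_alignment_glm(df, reference="a")
    assert fit["coefficients"]["b"] == pytest.approx(0.0, abs=1e-6)
    assert fit["null_deviance"] == pytest.approx(fit["residual_deviance"], rel=1e-6)


def test_separation_flagged_not_fatal():
    df = pd.DataFrame(
        {
            "pattern": ["a"] * 50 + ["b"] * 50,
            "aligned": [True] * 50 + [False] * 25 + [True] * 25,
        }
    )
    fit = fit_alignment_glm(df, reference="b")
    assert fit["separation_levels"] == ["a"]


def test_daytime_effort_drives_nocturnal_alignment_down(small_community):
    # with w = 0.8 of hours from a 13:00 +/- 3 h effort peak, nocturnal
    # species are mostly observed by day, so their alignment falls well
    # below one half while flexible species always align
    cfg, table, truth, occ = small_community
    hours = occ["eventDate"].str.extract(r"T(\d+):(\d+)").astype(float)
    hour = hours[0] + hours[1] / 60
    patterns = occ["species"].str.split().str[:2].str.join(" ").map(truth.activity_pattern)
    res = alignment_summary(hour.to_numpy(), patterns.to_numpy(), fit_glm=False)
    per = res.per_pattern
    if "nocturnal" in per.index:
        assert per.loc["nocturnal", "prop_aligned"] < 0.5
    assert per.loc["flexible", "prop_aligned"] == 1.0
    assert per.loc["diurnal", "prop_aligned"] > 0.5
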