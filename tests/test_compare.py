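"""Expectancy differences, bootstrap intervals and change classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from healthspan import (
    ABSOLUTE_INCREASE,
    NO_CHANGE,
    RELATIVE_INCREASE,
    RELATIVE_REDUCTION,
    AgeGrid,
    ComparisonReport,
    DifferenceEstimate,
    ExpectancyResult,
    IllnessDeathSpec,
    IntensityParameters,
    Interval,
    SimulationConfig,
    bootstrap_differences,
    classify_change,
    expectancy_difference,
    generate_cohort,
    report_table,
    risk_profile_table,
)
from healthspan.compare import REPORT_COLUMNS


def _exp(start_age, cifle, cile):
    return ExpectancyResult(start_age=start_age, e11=cifle, e12=cile)


def _diff(tle, cifle, prop, label="b vs a", age=65.0):
    return DifferenceEstimate(
        label=label, start_age=age,
        tle=Interval(*tle), cifle=Interval(*cifle), proportion=Interval(*prop),
        B=500,
    )


class TestExpectancyDifference:
    def test_identical_inputs_give_zero(self):
        a = _exp(65.0, 11.1, 0.9)
        d = expectancy_difference(a, a)
        assert all(v == 0.0 for v in d.values())

    def test_mismatched_start_ages_rejected(self):
        with pytest.raises(ValueError):
            expectancy_difference(_exp(65.0, 10, 1), _exp(85.0, 3, 1))

    def test_published_style_arithmetic(self):
        # healthy vs unhealthy diet, men aged 65: TLE 12.0 -> 12.8 with
        # CIFLE 11.1 -> 12.1 gives differences 0.8 and 1.0
        ref = _exp(65.0, 11.1, 12.0 - 11.1)
        cmp_ = _exp(65.0, 12.1, 12.8 - 12.1)
        d = expectancy_difference(ref, cmp_)
        assert d["d_tle"] == pytest.approx(0.8)
        assert d["d_cifle"] == pytest.approx(1.0)
        assert d["d_cile"] == pytest.approx(-0.2)

    def test_proportion_difference_in_points(self):
        ref = _exp(65.0, 0.926 * 12.0, 12.0 * (1 - 0.926))
        cmp_ = _exp(65.0, 0.944 * 12.8, 12.8 * (1 - 0.944))
        d = expectancy_difference(ref, cmp_)
        assert d["d_proportion"] == pytest.approx(1.8, abs=1e-9)


# printed difference tuples (ΔTLE, ΔCIFLE, Δproportion with 95% CIs) for
# every exposure comparison whose direction of change the study's results
# text states explicitly, at ages 65 and 85
PUBLISHED_CLASSIFICATIONS = [
    ("men diet 65", (0.8, 0.3, 1.3), (1.0, 0.5, 1.5), (1.8, 1.1, 3.1), ABSOLUTE_INCREASE),
    ("women diet 65", (1.0, 0.4, 1.6), (1.4, 0.9, 1.9), (3.2, 2.1, 4.9), ABSOLUTE_INCREASE),
    ("men married 65", (1.9, 1.0, 2.4), (2.1, 1.3, 2.7), (3.0, 1.9, 5.9), ABSOLUTE_INCREASE),
    ("men mental 65", (1.5, 0.8, 2.2), (1.6, 0.9, 2.2), (1.8, 0.8, 3.6), ABSOLUTE_INCREASE),
    ("women mental 65", (1.6, 1.0, 2.3), (1.8, 1.1, 2.5), (2.3, 0.8, 4.2), ABSOLUTE_INCREASE),
    ("men social 65", (1.8, 1.1, 2.4), (1.9, 1.2, 2.4), (1.3, 0.6, 2.7), ABSOLUTE_INCREASE),
    ("women social 65", (1.7, 1.2, 2.4), (1.8, 1.2, 2.3), (1.7, 0.7, 3.1), ABSOLUTE_INCREASE),
    ("women productive 65", (3.4, 2.3, 3.9), (3.3, 2.5, 3.8), (2.2, 1.3, 4.6), RELATIVE_INCREASE),
    ("women never-smoking 65", (1.0, 0.5, 1.4), (0.7, 0.3, 1.1), (-1.2, -2.4, -0.1), RELATIVE_REDUCTION),
    ("women physical 65", (0.7, 0.3, 1.1), (0.5, 0.1, 0.8), (-1.3, -2.4, -0.6), RELATIVE_REDUCTION),
    ("men diet 85", (0.4, 0.1, 0.7), (0.6, 0.3, 0.9), (7.1, 4.7, 11.8), ABSOLUTE_INCREASE),
    ("women diet 85", (0.5, 0.1, 0.8), (0.8, 0.4, 1.0), (8.5, 6.3, 11.3), ABSOLUTE_INCREASE),
    ("men physical 85", (0.6, 0.1, 0.9), (0.7, 0.4, 0.9), (5.8, 3.5, 11.8), ABSOLUTE_INCREASE),
    ("men mental 85", (0.8, 0.3, 1.2), (1.0, 0.5, 1.4), (8.3, 4.7, 13.9), ABSOLUTE_INCREASE),
    ("women mental 85", (1.2, 0.3, 1.8), (1.6, 1.0, 2.2), (15.9, 10.7, 24.4), ABSOLUTE_INCREASE),
    ("men social 85", (1.0, 0.4, 1.5), (1.2, 0.7, 1.6), (9.9, 6.4, 18.0), ABSOLUTE_INCREASE),
    ("women social 85", (1.0, 0.5, 1.4), (1.1, 0.7, 1.4), (7.8, 4.8, 12.3), ABSOLUTE_INCREASE),
    ("women never-smoking 85", (0.4, 0.3, 0.6), (0.4, 0.3, 0.6), (3.7, 1.4, 6.3), RELATIVE_INCREASE),
    ("men married 85", (0.8, 0.3, 1.0), (0.7, 0.3, 1.0), (3.1, 1.4, 6.4), RELATIVE_INCREASE),
    ("women married 85", (0.9, 0.4, 1.2), (0.8, 0.5, 1.1), (5.2, 3.1, 8.4), RELATIVE_INCREASE),
    ("women physical 85", (0.7, 0.3, 0.8), (0.6, 0.3, 0.8), (2.9, 0.9, 5.5), RELATIVE_INCREASE),
    ("men productive 85", (1.4, 0.7, 1.9), (1.3, 0.8, 1.8), (6.2, 3.7, 12.0), RELATIVE_INCREASE),
    ("women productive 85", (1.8, 0.9, 2.2), (1.6, 1.0, 2.0), (10.4, 7.5, 15.3), RELATIVE_INCREASE),
]


class TestClassifyChange:
    @pytest.mark.parametrize(
        "label, tle, cifle, prop, expected",
        PUBLISHED_CLASSIFICATIONS,
        ids=[row[0] for row in PUBLISHED_CLASSIFICATIONS],
    )
    def test_reproduces_published_classifications(self, label, tle, cifle, prop, expected):
        assert classify_change(_diff(tle, cifle, prop)) == expected

    def test_ambiguous_gain_without_proportion_signal_is_no_change(self):
        # equal TLE and CIFLE gains with a null proportion CI decide nothing
        d = _diff((0.8, 0.3, 1.2), (0.8, 0.3, 1.2), (0.4, -0.2, 1.4))
        assert classify_change(d) == NO_CHANGE

    def test_null_difference_is_no_change(self):
        d = _diff((0.1, -0.5, 0.6), (0.1, -0.4, 0.5), (0.0, -1.0, 1.0))
        assert classify_change(d) == NO_CHANGE

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_swap_never_classifies_both_directions_as_gains(self, data):
        def interval(lo_range=(-3.0, 3.0)):
            a = data.draw(st.floats(*lo_range))
            b = data.draw(st.floats(*lo_range))
            lo, hi = min(a, b), max(a, b)
            pt = data.draw(st.floats(lo, hi))
            return Interval(pt, lo, hi)

        d = DifferenceEstimate(
            label="b vs a", start_age=65.0,
            tle=interval(), cifle=interval(), proportion=interval((-8.0, 8.0)),
        )
        mirrored = DifferenceEstimate(
            label="a vs b", start_age=65.0,
            tle=Interval(-d.tle.point, -d.tle.upper, -d.tle.lower),
            cifle=Interval(-d.cifle.point, -d.cifle.upper, -d.cifle.lower),
            proportion=Interval(
                -d.proportion.point, -d.proportion.upper, -d.proportion.lower
            ),
        )
        gains = {ABSOLUTE_INCREASE, RELATIVE_INCREASE}
        c1, c2 = classify_change(d), classify_change(mirrored)
        assert not (c1 in gains and c2 in gains)
        assert not (c1 == RELATIVE_REDUCTION and c2 == RELATIVE_REDUCTION)


@pytest.fixture(scope="module")
def null_panel():
    truth = IntensityParameters(
        beta0={"12": math.log(0.1), "13": math.log(0.05), "23": math.log(0.2)}
    )
    config = SimulationConfig(
        n_subjects=400, true_params=truth, seed=31,
        covariate_probs={"group": 0.5}, wave_offsets=(0.0, 3.0, 6.0, 9.0),
    )
    panel, _ = generate_cohort(config)
    return panel


GROUP_SPEC = IllnessDeathSpec(
    covariates={"12": ("group",), "13": ("group",), "23": ("group",)},
    age_effect=False, ref_age=80.0,
)
GROUP_PROFILES = {"reference": {"group": 0.0}, "comparison": {"group": 1.0}}


class TestBootstrapDifferences:
    def test_same_seed_reproduces_intervals_exactly(self, null_panel):
        kw = dict(start_ages=(65.0,), B=8, seed=5, grid_stop=300.0)
        out1 = bootstrap_differences(null_panel, GROUP_SPEC, GROUP_PROFILES, **kw)
        out2 = bootstrap_differences(null_panel, GROUP_SPEC, GROUP_PROFILES, **kw)
        assert out1.differences[0] == out2.differences[0]

    def test_point_inside_percentile_interval(self, null_panel):
        out = bootstrap_differences(
            null_panel, GROUP_SPEC, GROUP_PROFILES,
            start_ages=(65.0,), B=100, seed=6, grid_stop=300.0,
        )
        d = out.differences[0]
        for iv in (d.tle, d.cifle, d.proportion):
            assert iv.lower <= iv.point <= iv.upper
        assert d.B == 100 and not d.unreliable

    def test_interval_width_shrinks_with_sample_size(self):
        truth = IntensityParameters(
            beta0={"12": math.log(0.1), "13": math.log(0.05), "23": math.log(0.2)}
        )
        widths = {}
        for n in (500, 2000):
            config = SimulationConfig(
                n_subjects=n, true_params=truth, seed=77,
                covariate_probs={"group": 0.5}, wave_offsets=(0.0, 3.0, 6.0, 9.0),
            )
            panel, _ = generate_cohort(config)
            out = bootstrap_differences(
                panel, GROUP_SPEC, GROUP_PROFILES,
                start_ages=(65.0,), B=50, seed=8, grid_stop=300.0,
            )
            d = out.differences[0]
            widths[n] = d.cifle.upper - d.cifle.lower
        assert widths[2000] < widths[500]

    def test_rejects_degenerate_requests(self, null_panel):
        with pytest.raises(ValueError):
            bootstrap_differences(null_panel, GROUP_SPEC, GROUP_PROFILES, B=1)
        with pytest.raises(ValueError):
            bootstrap_differences(null_panel, GROUP_SPEC, {"only": {"group": 0.0}}, B=10)


class TestReportTables:
    def test_empty_input_gives_header_only(self):
        df, gaps = report_table([])
        assert list(df.columns) == REPORT_COLUMNS
        assert len(df) == 0 and gaps == []

    def test_reference_rows_marked_and_column_order_preserved(self):
        comp = ComparisonReport(
            variable="Dietary pattern", start_age=65.0,
            levels=["Unhealthy", "Healthy"],
            expectancies={
                "Unhealthy": _exp(65.0, 11.1, 0.9),
                "Healthy": _exp(65.0, 12.1, 0.7),
            },
            differences={
                "Healthy": _diff((0.8, 0.3, 1.3), (1.0, 0.5, 1.5), (1.8, 1.1, 3.1))
            },
        )
        df, gaps = report_table([comp])
        assert list(df.columns) == REPORT_COLUMNS
        ref_row = df[df["Variables"].str.strip() == "Unhealthy"].iloc[0]
        assert ref_row["Difference in TLE (95%CI)"] == "Reference"
        data_row = df[df["Variables"].str.strip() == "Healthy"].iloc[0]
        assert data_row["Difference in CIFLE (95%CI)"] == "1.0 (0.5 to 1.5)"
        assert gaps == []

    def test_missing_results_listed_as_gaps_not_dropped(self):
        comp = ComparisonReport(
            variable="Smoking", start_age=65.0,
            levels=["Current", "Never"],
            expectancies={"Current": _exp(65.0, 9.9, 1.0)},
        )
        _, gaps = report_table([comp])
        assert any("Never" in g for g in gaps)

    def test_risk_profile_table_layout(self):
        exp = {
            "high": _exp(65.0, 7.0, 0.7),
            "medium_high": _exp(65.0, 9.0, 1.1),
            "low": _exp(65.0, 12.1, 1.1),
        }
        diffs = {
            "medium_high": _diff((2.4, 2.0, 2.9), (2.0, 1.7, 2.5), (-2.0, -2.7, -1.1)),
            "low": _diff((5.5, 4.6, 6.5), (5.1, 4.3, 6.2), (0.6, -1.1, 2.4)),
        }
        table = risk_profile_table(exp, diffs)
        assert list(table.index) == ["TLE", "CIFLE", "Proportion (%)"]
        assert table.loc["TLE", "high risk profile"] == "7.7"
        assert "Difference of low vs high (95%CI)" in table.columns
        # medium_low was not supplied: cell left blank, not dropped
        assert table.loc["TLE", "medium_low risk profile"] == ""

    def test_plot_helper_returns_axis(self):
        from healthspan import plot_expectancy_bars

        ax = plot_expectancy_bars({"high": _exp(65.0, 7.0, 0.7), "low": _exp(65.0, 12.1, 1.1)})
        assert len(ax.patches) == 4
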