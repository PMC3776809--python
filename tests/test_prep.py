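import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seasurv.prep import (
    MonthlySeries,
    aggregate_to_monthly,
    climatology,
    detrend,
    filter_min_cases,
    normalize,
    read_cases,
    read_counts,
    read_sites,
    trim_low_years,
    write_cases,
    write_counts,
)


def _yearly(totals, start=(2000, 1)):
    """Series whose calendar-year totals equal ``totals`` (all cases in January)."""
    counts = []
    for tot in totals:
        counts.extend([tot] + [0] * 11)
    return MonthlySeries("y", 40.0, start[0], start[1], np.asarray(counts, float))


class TestAggregateToMonthly:
    def test_basic_counting(self):
        cases = pd.DataFrame(
            {"site": ["a"] * 3, "year": [2001, 2001, 2001], "month": [1, 1, 3]}
        )
        s = aggregate_to_monthly(cases, "a", (2001, 1), 3)
        np.testing.assert_array_equal(s.counts, [2, 0, 1])

    def test_empty_table_gives_zeros(self):
        cases = pd.DataFrame({"site": [], "year": [], "month": []})
        s = aggregate_to_monthly(cases, "a", (2001, 1), 4)
        np.testing.assert_array_equal(s.counts, [0, 0, 0, 0])

    def test_case_outside_span_names_record(self):
        cases = pd.DataFrame({"site": ["a"], "year": [2005], "month": [6]})
        with pytest.raises(ValueError, match=r"\('a', 2005, 6\)"):
            aggregate_to_monthly(cases, "a", (2001, 1), 12)


class TestFilterMinCases:
    def test_29_drops(self, make_series):
        assert not filter_min_cases(make_series([29] + [0] * 11))

    def test_30_keeps(self, make_series):
        assert filter_min_cases(make_series([30] + [0] * 11))

    def test_large_site_keeps(self, make_series):
        assert filter_min_cases(make_series([271_475] + [0] * 11))


class TestTrimLowYears:
    def test_drops_two_leading_low_years(self):
        trimmed = trim_low_years(_yearly([5, 10, 30, 40]))
        assert trimmed.n_months == 24
        assert trimmed.start_year == 2002
        assert trimmed.start_month == 1

    def test_fallback_threshold(self):
        trimmed = trim_low_years(_yearly([10, 12, 15]))
        assert trimmed.start_year == 2001  # primary drops all; fallback 12 keeps years 2-3
        assert trimmed.n_months == 24

    def test_interior_low_year_retained(self):
        trimmed = trim_low_years(_yearly([25, 3, 30]))
        assert trimmed.n_months == 36  # leading-years rule only

    def test_untestable_series(self):
        with pytest.raises(ValueError, match="untestable"):
            trim_low_years(_yearly([5, 5]))

    def test_partial_leading_year_counts_toward_its_calendar_year(self):
        # starts in November 2000: the 2-month partial year has 8 cases -> dropped
        counts = [4, 4] + [30] + [0] * 11 + [40] + [0] * 11
        s = MonthlySeries("p", 40.0, 2000, 11, np.asarray(counts, float))
        trimmed = trim_low_years(s)
        assert (trimmed.start_year, trimmed.start_month) == (2001, 1)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=60), min_size=2, max_size=6))
    def test_never_longer_and_always_a_suffix(self, totals):
        s = _yearly(totals)
        try:
            trimmed = trim_low_years(s)
        except ValueError:
            assert all(t < 12 for t in totals)
            return
        assert trimmed.n_months <= s.n_months
        # suffix property: trimmed counts equal the tail of the original
        np.testing.assert_array_equal(trimmed.counts, s.counts[s.n_months - trimmed.n_months :])


class TestDetrend:
    def test_exact_quadratic_divides_to_one(self, make_series):
        t = np.arange(60.0)
        s = make_series(4 + 0.1 * t + 0.01 * t**2)
        np.testing.assert_allclose(detrend(s).counts, 1.0, atol=1e-9)

    def test_constant_series(self, make_series):
        s = make_series([7.0] * 36)
        np.testing.assert_allclose(detrend(s).counts, 1.0, atol=1e-9)

    def test_trend_removed_from_seasonal_series(self, make_series):
        # noiseless trend x seasonality: refit coefficients shrink by >100x
        t = np.arange(240.0)
        m = t % 12 + 1
        s = make_series((40 + 0.3 * t + 0.002 * t**2) * (1 + 0.4 * np.cos(2 * np.pi * (m - 2) / 12)))
        out = detrend(s)
        c2, c1, _ = np.polyfit(t, out.counts, 2)
        assert abs(c1) < 0.3 / 100
        assert abs(c2) < 0.002 / 100

    def test_idempotent_on_flat_series(self, make_series):
        s = make_series([5.0] * 48)
        once = detrend(s)
        twice = detrend(once)
        np.testing.assert_allclose(twice.counts, once.counts, atol=1e-9)

    def test_degenerate_fit_errors(self, make_series):
        counts = np.r_[np.linspace(100, 1, 24), np.zeros(48)]
        with pytest.raises(ValueError, match="degenerate trend fit"):
            detrend(make_series(counts))


class TestClimatology:
    def test_constant_two_years(self, make_series):
        clim = climatology(make_series([5.0] * 24))
        np.testing.assert_allclose(clim.means, 5.0)
        assert clim.overall_mean == 5.0

    def test_occurrences_for_18_month_span(self, make_series):
        clim = climatology(make_series([1.0] * 18, start=(2001, 1)))
        np.testing.assert_array_equal(clim.occurrences[:6], 2)
        np.testing.assert_array_equal(clim.occurrences[6:], 1)

    def test_short_span_errors(self, make_series):
        with pytest.raises(ValueError, match="never occurs"):
            climatology(make_series([1.0] * 10))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=50), min_size=12, max_size=40),
        st.integers(min_value=1, max_value=12),
    )
    def test_conservation_of_total(self, counts, start_month):
        s = MonthlySeries("c", 0.0, 2000, start_month, np.asarray(counts, float))
        clim = climatology(s)
        assert clim.occurrences.sum() == s.n_months
        assert (clim.means * clim.occurrences).sum() == pytest.approx(s.total)


class TestNormalize:
    def test_constant_gives_ones(self, make_series):
        np.testing.assert_allclose(normalize(climatology(make_series([3.0] * 24))), 1.0)

    def test_two_level_example(self, make_series):
        clim = climatology(make_series([2.0] * 6 + [4.0] * 6))
        ratios = normalize(clim)
        np.testing.assert_allclose(ratios, [2 / 3] * 6 + [4 / 3] * 6)

    def test_zero_mean_errors(self, make_series):
        with pytest.raises(ValueError, match="overall mean"):
            normalize(climatology(make_series([0.0] * 12)))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=12, max_size=40))
    def test_occurrence_weighted_mean_is_one(self, counts):
        if sum(counts) == 0:
            counts[0] = 1
        s = MonthlySeries("n", 0.0, 2000, 1, np.asarray(counts, float))
        clim = climatology(s)
        ratios = normalize(clim)
        weighted = (ratios * clim.occurrences).sum() / clim.occurrences.sum()
        assert weighted == pytest.approx(1.0)


class TestIO:
    def test_counts_round_trip(self, tmp_path, make_series):
        series = [make_series([1, 2, 3] * 8, site_id="a"), make_series([4] * 12, site_id="b")]
        path = tmp_path / "counts.csv"
        write_counts(series, path)
        back = read_counts(path, {"a": 40.0, "b": -5.0})
        assert [s.site_id for s in back] == ["a", "b"]
        np.testing.assert_array_equal(back[0].counts, series[0].counts)
        assert back[1].latitude == -5.0

    def test_gap_detection(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("site,year,month,count\na,2000,1,3\na,2000,3,4\n")
        with pytest.raises(ValueError, match="gaps"):
            read_counts(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("site,year\na,2000\n")
        with pytest.raises(ValueError, match="missing required column"):
            read_counts(path)

    def test_cases_round_trip(self, tmp_path):
        cases = pd.DataFrame({"site": ["a", "a"], "year": [2000, 2001], "month": [1, 12]})
        path = tmp_path / "cases.csv"
        write_cases(cases, path)
        back = read_cases(path)
        pd.testing.assert_frame_equal(back, cases)

    def test_bad_month_in_cases(self, tmp_path):
        path = tmp_path / "cases.csv"
        path.write_text("site,year,month\na,2000,13\n")
        with pytest.raises(ValueError, match="month out of 1..12"):
            read_cases(path)

    def test_sites_validation(self, tmp_path):
        path = tmp_path / "sites.csv"
        path.write_text("site,latitude\na,95\n")
        with pytest.raises(ValueError, match="latitude out of range"):
            read_sites(path)
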