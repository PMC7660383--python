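import datetime as dt

import numpy as np
import pandas as pd
import pytest

from symte.exceptions import StateResolutionError
from symte.preprocessing import (
    EventList,
    EventRecord,
    aggregate_mode,
    events_to_binary,
    seasonal_adjust_detrend,
    symbolize_median,
    symbolize_sign,
)
from symte.series import MonthlySeries
from symte.datasets import load_mass_shootings

from .conftest import bs

WINDOW = ("1999-01", "2017-12")


def monthly(values, start="1999-01", kind="background_checks"):
    return MonthlySeries(np.asarray(values, float), start, "unit", kind=kind)


class TestSeasonalAdjustDetrend:
    def test_pure_line_residual_zero(self):
        t = np.arange(48)
        res = seasonal_adjust_detrend(monthly(3.0 + 0.5 * t))
        assert np.abs(res.values).max() < 1e-9
        assert res.kind == "residual"

    def test_line_plus_annual_sinusoid_residual_zero(self):
        t = np.arange(120)
        series = monthly(3.0 + 0.5 * t + 4.0 * np.sin(2 * np.pi * t / 12))
        res = seasonal_adjust_detrend(series)
        assert np.abs(res.values).max() < 1e-9

    def test_white_noise_monthly_means_zero(self, rng):
        series = monthly(rng.standard_normal(240))
        res = seasonal_adjust_detrend(series)
        for m in range(1, 13):
            assert res.values[res.month_numbers == m].mean() == pytest.approx(
                0.0, abs=1e-10
            )
        assert res.values.mean() == pytest.approx(0.0, abs=1e-10)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="24"):
            seasonal_adjust_detrend(monthly(np.arange(23)))

    def test_non_january_start_profile(self, rng):
        series = MonthlySeries(rng.standard_normal(60), "2000-05", "u")
        res = seasonal_adjust_detrend(series)
        for m in np.unique(res.month_numbers):
            assert res.values[res.month_numbers == m].mean() == pytest.approx(
                0.0, abs=1e-10
            )


class TestSymbolize:
    def test_sign_rule_zero_maps_down(self):
        res = monthly([0.5, -0.2, 0.0], kind="residual")
        assert symbolize_sign(res).symbols.tolist() == [1, 0, 0]

    def test_sign_requires_residual(self):
        with pytest.raises(ValueError, match="residual"):
            symbolize_sign(monthly([1.0, 2.0]))

    def test_sign_all_positive(self):
        res = monthly([0.1, 2.0, 3.5], kind="residual")
        assert symbolize_sign(res).symbols.tolist() == [1, 1, 1]

    def test_sign_antisymmetry(self, rng):
        vals = rng.standard_normal(50)
        vals[np.abs(vals) < 1e-6] = 0.5  # keep away from the tie point
        up = symbolize_sign(monthly(vals, kind="residual")).symbols
        down = symbolize_sign(monthly(-vals, kind="residual")).symbols
        assert np.array_equal(up, 1 - down)

    def test_median_strict_rule(self):
        assert symbolize_median(monthly([1, 2, 3, 4, 5])).symbols.tolist() == [
            0, 0, 0, 1, 1,
        ]

    def test_median_constant_all_down(self):
        assert symbolize_median(monthly([7.0] * 10)).symbols.sum() == 0

    def test_median_up_count_bound(self, rng):
        for _ in range(20):
            vals = rng.standard_normal(rng.integers(2, 40))
            ups = symbolize_median(monthly(vals)).symbols.sum()
            assert ups <= len(vals) // 2


class TestAggregateMode:
    def test_single_series_identity(self, rng):
        s = bs(rng.integers(0, 2, 30))
        assert np.array_equal(aggregate_mode([s]).symbols, s.symbols)

    def test_majority(self):
        out = aggregate_mode([bs([1, 1]), bs([1, 0]), bs([0, 0])])
        assert out.symbols.tolist() == [1, 0]

    def test_three_of_five_majority(self, rng):
        ups = [bs([1] * 12) for _ in range(3)]
        downs = [bs([0] * 12) for _ in range(2)]
        assert aggregate_mode(ups + downs).symbols.sum() == 12

    def test_tie_resolves_down_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = aggregate_mode([bs([1, 0]), bs([0, 0])])
        assert out.symbols.tolist() == [0, 0]
        assert "tie" in caplog.text

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            aggregate_mode([])

    def test_order_invariance(self, rng):
        series = [bs(rng.integers(0, 2, 20)) for _ in range(5)]
        a = aggregate_mode(series).symbols
        b = aggregate_mode(series[::-1]).symbols
        assert np.array_equal(a, b)

    def test_idempotent_on_copies(self, rng):
        s = bs(rng.integers(0, 2, 20))
        assert np.array_equal(aggregate_mode([s, s, s]).symbols, s.symbols)


class TestEventsToBinary:
    def test_empty_event_list_all_down(self):
        out = events_to_binary(EventList([]), WINDOW)
        assert out.symbols.sum() == 0
        assert len(out) == 228

    def test_national_columbine_month_up(self):
        events = load_mass_shootings()
        national = events_to_binary(events, WINDOW, scope="national")
        assert national.symbols[national.index.get_loc(pd.Period("1999-04", "M"))] == 1

    def test_california_in_state_eleven_up_months(self):
        events = load_mass_shootings()
        in_ca = events_to_binary(events, WINDOW, scope="in_state", state="CA")
        assert int(in_ca.symbols.sum()) == 11

    def test_elsewhere_excludes_focal_and_keeps_excluded_units(self):
        events = EventList(
            [
                EventRecord("a", "CA", dt.date(2000, 5, 2)),
                EventRecord("b", "HI", dt.date(2000, 6, 3)),
                EventRecord("c", "DC", dt.date(2000, 7, 4)),
            ]
        )
        out = events_to_binary(events, ("2000-01", "2000-12"), "elsewhere", state="CA")
        assert out.symbols.tolist() == [0, 0, 0, 0, 0, 1, 1, 0, 0, 0, 0, 0]

    def test_elsewhere_independent_of_in_state_same_month(self):
        events = EventList(
            [
                EventRecord("a", "CA", dt.date(2000, 5, 2)),
                EventRecord("b", "TX", dt.date(2000, 5, 9)),
            ]
        )
        out = events_to_binary(events, ("2000-01", "2000-12"), "elsewhere", state="CA")
        assert out.symbols[4] == 1  # out-of-state event counts regardless

    def test_unresolvable_state_names_record(self):
        events = EventList([EventRecord("mystery", "XX", dt.date(2000, 1, 1))])
        with pytest.raises(StateResolutionError, match="mystery"):
            events_to_binary(events, ("2000-01", "2000-12"))

    def test_full_name_resolution(self):
        events = EventList([EventRecord("a", "California", dt.date(2000, 1, 5))])
        out = events_to_binary(events, ("2000-01", "2000-03"), "in_state", state="CA")
        assert out.symbols.tolist() == [1, 0, 0]

    def test_national_is_or_of_in_state_plus_districts(self):
        events = load_mass_shootings()
        national = events_to_binary(events, WINDOW, scope="national")
        combined = np.zeros(len(national), dtype=int)
        for code in sorted({r.state for r in events}):
            part = events_to_binary(events, WINDOW, scope="in_state", state=code)
            combined |= part.symbols.astype(int)
        assert np.array_equal(combined, national.symbols)


class TestEventList:
    def test_filter_window(self):
        events = load_mass_shootings()
        sub = events.filter_window("2012-01", "2012-12")
        assert all(r.date.year == 2012 for r in sub)
        assert len(sub) == 7

    def test_per_state_counts_total(self):
        events = load_mass_shootings()
        assert sum(events.per_state_counts().values()) == 87
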