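"""From raw monthly series and event lists to binary symbolic series.

Continuous background-check series are seasonally adjusted and linearly
detrended with a classical decomposition (OLS trend plus month-of-year mean
profile), then symbolized by the sign of the residual. Media counts are
symbolized against their sample median. Event lists are binned to monthly
occurrence indicators at national, in-state, or elsewhere scope.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from symte.exceptions import AlignmentError
from symte.series import DOWN, UP, BinarySeries, MonthlySeries, check_aligned
from symte.states import resolve_state

logger = logging.getLogger(__name__)

#: minimum length for seasonal decomposition: two full annual cycles
MIN_DECOMPOSITION_LENGTH = 24


@dataclass(frozen=True)
class EventRecord:
    """A dated, state-tagged event."""

    name: str
    state: str
    date: dt.date

    @property
    def month(self) -> pd.Period:
        return pd.Period(f"{self.date.year}-{self.date.month:02d}", freq="M")


@dataclass
class EventList:
    records: list[EventRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def filter_window(self, start, end) -> "EventList":
        start, end = pd.Period(start, "M"), pd.Period(end, "M")
        return EventList([r for r in self.records if start <= r.month <= end])

    def per_state_counts(self) -> dict[str, int]:
        """Event tally per resolved state code (districts included)."""
        tally: dict[str, int] = {}
        for rec in self.records:
            code = resolve_state(rec.state, context=f"event {rec.name!r}")
            tally[code] = tally.get(code, 0) + 1
        return tally


def seasonal_adjust_detrend(series: MonthlySeries) -> MonthlySeries:
    """Remove a linear trend and the month-of-year mean profile (joint OLS).

    The residual has zero sample mean and zero month-of-year means; a pure
    line plus any 12-month-periodic profile is removed exactly. Only the
    residual's sign survives symbolization downstream. Requires two full
    annual cycles.
    """
    if len(series) < MIN_DECOMPOSITION_LENGTH:
        raise ValueError(
            f"need >= {MIN_DECOMPOSITION_LENGTH} months for decomposition, "
            f"got {len(series)}"
        )
    T = len(series)
    t = np.arange(T, dtype=float)
    months = series.month_numbers
    # joint OLS fit of trend and month-of-year profile: an intercept, a
    # linear term, and one dummy per calendar month beyond the first
    design = [np.ones(T), t]
    present = np.unique(months)
    for m in present[1:]:
        design.append((months == m).astype(float))
    X = np.column_stack(design)
    coef, *_ = np.linalg.lstsq(X, series.values, rcond=None)
    residual = series.values - X @ coef
    return MonthlySeries(residual, series.start, series.unit_id, kind="residual")


def symbolize_sign(residual: MonthlySeries) -> BinarySeries:
    """Positive residual -> up; negative or zero -> down."""
    if residual.kind != "residual":
        raise ValueError(
            f"sign symbolization expects a residual series, got kind={residual.kind!r}"
        )
    return BinarySeries(
        (residual.values > 0).astype(np.int8), residual.start, residual.unit_id
    )


def symbolize_median(series: MonthlySeries) -> BinarySeries:
    """Strictly above the sample median -> up; at or below -> down."""
    med = float(np.median(series.values))
    return BinarySeries(
        (series.values > med).astype(np.int8), series.start, series.unit_id
    )


def aggregate_mode(series_list: Sequence[BinarySeries], label: str = "") -> BinarySeries:
    """Per-month majority symbol across several aligned binary series.

    Ties (possible only for even list sizes) resolve to down, with a logged
    warning, consistent with the down convention for zeros and median ties.
    """
    series_list = list(series_list)
    if not series_list:
        raise ValueError("cannot aggregate an empty list of series")
    check_aligned(*series_list)
    ups = np.sum([s.symbols for s in series_list], axis=0)
    n = len(series_list)
    ties = ups * 2 == n
    if ties.any():
        months = series_list[0].index[ties]
        logger.warning(
            "mode aggregation tie at %d month(s) (first: %s); resolved to down",
            int(ties.sum()),
            months[0],
        )
    out = (ups * 2 > n).astype(np.int8)
    return BinarySeries(out, series_list[0].start, label or series_list[0].label)


def events_to_binary(
    events: EventList,
    window: tuple,
    scope: str = "national",
    state: str | None = None,
    label: str = "",
) -> BinarySeries:
    """Monthly occurrence indicator for an event list.

    scope:
      * ``"national"`` — up iff at least one event anywhere that month;
      * ``"in_state"`` — up iff at least one event in ``state``;
      * ``"elsewhere"`` — up iff at least one event in any other unit
        (districts and excluded units count), regardless of in-state events.
    """
    start, end = pd.Period(window[0], "M"), pd.Period(window[1], "M")
    if scope not in ("national", "in_state", "elsewhere"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope in ("in_state", "elsewhere"):
        if state is None:
            raise ValueError(f"scope {scope!r} requires a state")
        state = resolve_state(state, context="events_to_binary scope")
    index = pd.period_range(start, end, freq="M")
    symbols = np.zeros(len(index), dtype=np.int8)
    for rec in events.filter_window(start, end):
        code = resolve_state(rec.state, context=f"event {rec.name!r}")
        if scope == "in_state" and code != state:
            continue
        if scope == "elsewhere" and code == state:
            continue
        symbols[index.get_loc(rec.month)] = UP
    return BinarySeries(symbols, start, label or f"events:{scope}:{state or 'US'}")
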