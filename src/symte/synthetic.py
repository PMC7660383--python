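"""Generators for inputs with planted causal structure.

Symbolic effect series are generated directly from known binary kernels so
estimator tests are isolated from preprocessing; a composed mode embeds a
planted symbol sequence into a continuous trend+seasonal series for
end-to-end tests. All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from symte.partitioning import StateRecord, assign_clusters
from symte.preprocessing import EventList, EventRecord
from symte.series import BinarySeries, MonthlySeries
from symte.states import US_STATES
from symte.studies import StudyData

DEFAULT_T = 228  # 19 years of monthly observations
DEFAULT_START = "1999-01"


@dataclass
class SimulationConfig:
    """Knobs for the full synthetic-bundle generator."""

    T: int = DEFAULT_T
    n_states: int = 48
    coupling: float = 0.0
    seasonal_amplitude: float = 1.0
    trend_slope: float = 0.01
    noise_scale: float = 1.0
    restrictive_fraction: float = 7 / 48
    population_low: float = 5e5
    population_high: float = 5e7
    event_rate: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 24:
            raise ValueError("T must be at least 24 months")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")


def _coin(rng: np.random.Generator, size: int) -> np.ndarray:
    return rng.integers(0, 2, size=size, dtype=np.int8)


def gen_coupled_binary(
    T: int, coupling: float, rng: np.random.Generator, start: str = DEFAULT_START
) -> tuple[BinarySeries, BinarySeries]:
    """An iid fair cause and an effect that copies it with probability c.

    ``effect(t+1) = cause(t)`` with probability ``coupling``, otherwise a
    fresh fair coin. The exact transfer entropy of the kernel is available
    through :func:`coupled_pmf`.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    x = _coin(rng, T)
    y = np.empty(T, dtype=np.int8)
    y[0] = _coin(rng, 1)[0]
    follow = rng.random(T - 1) < coupling
    fresh = _coin(rng, T - 1)
    y[1:] = np.where(follow, x[:-1], fresh)
    return (
        BinarySeries(x, start, "cause"),
        BinarySeries(y, start, "effect"),
    )


def coupled_pmf(coupling: float) -> np.ndarray:
    """Exact stationary pmf over (y_next, y_now, x_now) of the coupled kernel."""
    p = np.empty((2, 2, 2))
    for y_next in (0, 1):
        for y_now in (0, 1):
            for x in (0, 1):
                copy = coupling if y_next == x else 0.0
                p[y_next, y_now, x] = 0.25 * (copy + (1 - coupling) / 2)
    return p


def gen_confounded_triplet(
    T: int,
    rng: np.random.Generator,
    persistence: float = 0.9,
    start: str = DEFAULT_START,
) -> tuple[BinarySeries, BinarySeries, BinarySeries]:
    """A mediated chain x -> z -> y that fools pairwise transfer entropy.

    ``x`` is a symmetric two-state Markov chain with stay probability
    ``persistence``; ``z(t+1) = x(t)`` and ``y(t+1) = z(t)``. With a
    persistent ``x`` the pairwise estimate from x to y is positive while
    conditioning on z removes it entirely (see :func:`confounded_pmf`).
    """
    if not 0.0 < persistence < 1.0:
        raise ValueError("persistence must lie in (0, 1)")
    x = np.empty(T, dtype=np.int8)
    x[0] = _coin(rng, 1)[0]
    stay = rng.random(T - 1) < persistence
    for t in range(1, T):
        x[t] = x[t - 1] if stay[t - 1] else 1 - x[t - 1]
    z = np.empty(T, dtype=np.int8)
    z[0] = _coin(rng, 1)[0]
    z[1:] = x[:-1]
    y = np.empty(T, dtype=np.int8)
    y[0] = _coin(rng, 1)[0]
    y[1:] = z[:-1]
    return (
        BinarySeries(x, start, "x"),
        BinarySeries(z, start, "z"),
        BinarySeries(y, start, "y"),
    )


def confounded_pmf(persistence: float = 0.9) -> np.ndarray:
    """Exact stationary pmf over (y_next, y_now, x_now, z_now) of the chain.

    In the stationary regime ``y(t+1) = z(t)``, ``z(t) = x(t-1)``, and
    ``y(t) = x(t-2)``, so the pmf is that of three consecutive states of the
    Markov chain, with y_next pinned to z.
    """
    a = persistence
    trans = np.array([[a, 1 - a], [1 - a, a]])
    p = np.zeros((2, 2, 2, 2))
    for y in (0, 1):  # x(t-2)
        for z in (0, 1):  # x(t-1)
            for x in (0, 1):  # x(t)
                p[z, y, x, z] = 0.5 * trans[y, z] * trans[z, x]
    return p


def gen_monthly_continuous(
    T: int,
    trend: float,
    amplitude: float,
    noise: float,
    rng: np.random.Generator,
    start: str = DEFAULT_START,
    unit_id: str = "",
) -> MonthlySeries:
    """Linear trend plus a fixed 12-month sinusoid plus iid Gaussian noise."""
    if T < 24:
        raise ValueError("T must be at least 24 months")
    t = np.arange(T, dtype=float)
    series = MonthlySeries(np.zeros(T), start, unit_id)
    phase = 2 * np.pi * (series.month_numbers - 1) / 12
    values = trend * t + amplitude * np.sin(phase) + noise * rng.standard_normal(T)
    return MonthlySeries(values, start, unit_id, kind="background_checks")


def embed_symbols_in_continuous(
    symbols: BinarySeries,
    trend: float,
    amplitude: float,
    rng: np.random.Generator,
    magnitude: float = 1.0,
    unit_id: str = "",
) -> MonthlySeries:
    """Continuous series whose detrended/deseasonalized sign tracks ``symbols``.

    The residual component is ``+|g|*magnitude`` for up months and
    ``-|g|*magnitude`` for down months, g standard normal, on top of a trend
    and seasonal profile; classical decomposition then recovers the planted
    symbols up to edge distortion.
    """
    T = len(symbols)
    t = np.arange(T, dtype=float)
    phase = 2 * np.pi * (symbols.index.month - 1) / 12
    sign = 2.0 * symbols.symbols - 1.0
    resid = sign * np.abs(rng.standard_normal(T)) * magnitude
    values = trend * t + amplitude * np.sin(phase) + resid
    return MonthlySeries(values, symbols.start, unit_id, kind="background_checks")


def gen_state_map(
    n_states: int,
    restrictive_fraction: float,
    rng: np.random.Generator,
    event_rate: float = 0.0,
    T: int = DEFAULT_T,
    start: str = DEFAULT_START,
    population_low: float = 5e5,
    population_high: float = 5e7,
) -> tuple[list[StateRecord], EventList]:
    """Units on a jittered grid with a bimodal legal environment and events.

    Populations are log-uniform over roughly two decades; law restrictiveness
    is drawn from a well-separated two-component Gaussian mixture; events are
    assigned to units with population-proportional rates. Unit codes reuse
    real state codes so event-state resolution works unchanged.
    """
    if n_states < 4:
        raise ValueError("need at least 4 states")
    codes = sorted(US_STATES)[:n_states]
    if len(codes) < n_states:
        raise ValueError(f"at most {len(US_STATES)} states supported")
    side = int(np.ceil(np.sqrt(n_states)))
    lat0, lon0 = 30.0, -120.0
    populations = np.exp(
        rng.uniform(np.log(population_low), np.log(population_high), n_states)
    )
    n_restrictive = max(1, round(restrictive_fraction * n_states))
    is_restrictive = np.zeros(n_states, dtype=bool)
    is_restrictive[rng.choice(n_states, n_restrictive, replace=False)] = True
    frac = np.where(
        is_restrictive,
        np.clip(rng.normal(0.70, 0.04, n_states), 0.5, 1.0),
        np.clip(rng.normal(0.20, 0.04, n_states), 0.0, 0.4),
    )
    states = []
    for i, code in enumerate(codes):
        row, col = divmod(i, side)
        states.append(
            StateRecord(
                code=code,
                name=US_STATES[code],
                population=float(populations[i]),
                lat=lat0 + 3.5 * row + rng.uniform(-1, 1),
                lon=lon0 + 5.0 * col + rng.uniform(-1, 1),
                law_restrictiveness=float(frac[i]),
            )
        )
    events = []
    if event_rate > 0:
        months = pd.period_range(start, periods=T, freq="M")
        weights = populations / populations.sum()
        for month in months:
            for _ in range(rng.poisson(event_rate)):
                i = int(rng.choice(n_states, p=weights))
                day = int(rng.integers(1, month.days_in_month + 1))
                events.append(
                    EventRecord(
                        name=f"synthetic event {month}-{len(events):04d}",
                        state=codes[i],
                        date=dt.date(month.year, month.month, day),
                    )
                )
    return states, EventList(events)


def _markov_binary(
    T: int, persistence: float, rng: np.random.Generator
) -> np.ndarray:
    x = np.empty(T, dtype=np.int8)
    x[0] = _coin(rng, 1)[0]
    flips = rng.random(T - 1) >= persistence
    for t in range(1, T):
        x[t] = 1 - x[t - 1] if flips[t - 1] else x[t - 1]
    return x


def gen_study_bundle(
    n_states: int = 48,
    T: int = DEFAULT_T,
    planted: Mapping[str, tuple[str, float]] | None = None,
    spatial_coupling: float = 0.0,
    in_state_coupling: float = 0.0,
    event_rate: float = 0.4,
    seed: int = 0,
    start: str = DEFAULT_START,
) -> StudyData:
    """A full study-ready bundle with optional planted causal structure.

    ``planted`` maps a shared cause name (one of the study-1 column names)
    to ``(group, strength)``: background checks of states in that group copy
    the cause with the given probability one month later. ``spatial_coupling``
    drives every state's background checks from a common persistent latent
    series, inducing detectable neighbor interaction. ``in_state_coupling``
    couples each state's background checks to its own local event series.
    """
    from symte.studies import (
        CAUSE_EVENTS_NATIONAL,
        CAUSE_MEDIA_FC,
        CAUSE_MEDIA_S,
    )
    from symte.preprocessing import events_to_binary

    rng = np.random.default_rng(seed)
    planted = dict(planted or {})
    states, events = gen_state_map(
        n_states, 7 / 48, rng, event_rate=event_rate, T=T, start=start
    )
    assign_clusters(states, exclude=())
    window = (str(pd.Period(start, "M")), str(pd.Period(start, "M") + T - 1))

    shared = {
        CAUSE_EVENTS_NATIONAL: events_to_binary(events, window, scope="national"),
        CAUSE_MEDIA_FC: BinarySeries(_coin(rng, T), start, "media_fc"),
        CAUSE_MEDIA_S: BinarySeries(_coin(rng, T), start, "media_s"),
    }
    latent = _markov_binary(T, 0.9, rng)

    bc = {}
    for st in states:
        driver = None
        strength = 0.0
        for cause_name, (group, c) in planted.items():
            if st.cluster == group:
                driver, strength = shared[cause_name].symbols, c
        if driver is None and spatial_coupling > 0:
            driver, strength = latent, spatial_coupling
        if driver is None and in_state_coupling > 0:
            local = events_to_binary(
                events, window, scope="in_state", state=st.code
            )
            driver, strength = local.symbols, in_state_coupling
        y = np.empty(T, dtype=np.int8)
        y[0] = _coin(rng, 1)[0]
        fresh = _coin(rng, T - 1)
        if driver is None:
            y[1:] = fresh
        else:
            follow = rng.random(T - 1) < strength
            y[1:] = np.where(follow, driver[:-1], fresh)
        bc[st.code] = BinarySeries(y, start, f"bc:{st.code}")

    return StudyData(
        states=states,
        bc=bc,
        media_fc=shared[CAUSE_MEDIA_FC],
        media_s=shared[CAUSE_MEDIA_S],
        events=events,
        window=window,
        events_national=shared[CAUSE_EVENTS_NATIONAL],
    )
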