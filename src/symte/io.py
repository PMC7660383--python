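"""CSV readers and writers plus full-pipeline data loading.

All tabular formats are plain CSV:

* events — ``name,state,date`` with ISO dates;
* monthly series — long format ``month,unit_id,value`` (YYYY-MM months);
* binary series — ``month,symbol`` with symbols encoded 0/1;
* state metadata — ``code,name,population,lat,lon,law_restrictiveness,included``;
* distances — ``from,to,km``.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from symte.config import PipelineConfig
from symte.exceptions import CalendarGapError
from symte.partitioning import StateRecord, assign_clusters
from symte.preprocessing import (
    EventList,
    EventRecord,
    aggregate_mode,
    seasonal_adjust_detrend,
    symbolize_median,
    symbolize_sign,
)
from symte.series import BinarySeries, MonthlySeries
from symte.states import resolve_state


def read_events(path) -> EventList:
    frame = pd.read_csv(path)
    required = {"name", "state", "date"}
    if missing := required - set(frame.columns):
        raise ValueError(f"events CSV {path} lacks column(s) {sorted(missing)}")
    records = []
    for i, row in frame.iterrows():
        try:
            date = dt.date.fromisoformat(str(row["date"]))
        except ValueError as exc:
            raise ValueError(f"{path} line {i + 2}: bad date {row['date']!r}") from exc
        code = resolve_state(row["state"], context=f"{path} line {i + 2}")
        records.append(EventRecord(name=str(row["name"]), state=code, date=date))
    return EventList(records)


def write_events(events: EventList, path) -> None:
    pd.DataFrame(
        [
            {"name": r.name, "state": r.state, "date": r.date.isoformat()}
            for r in events
        ]
    ).to_csv(path, index=False)


def read_series(path, kind: str = "background_checks") -> dict[str, MonthlySeries]:
    """Long-format monthly series, one :class:`MonthlySeries` per unit_id."""
    frame = pd.read_csv(path)
    required = {"month", "unit_id", "value"}
    if missing := required - set(frame.columns):
        raise ValueError(f"series CSV {path} lacks column(s) {sorted(missing)}")
    out: dict[str, MonthlySeries] = {}
    for unit_id, grp in frame.groupby("unit_id", sort=True):
        grp = grp.sort_values("month")
        try:
            idx = pd.PeriodIndex(grp["month"].astype(str), freq="M")
        except Exception as exc:
            raise ValueError(f"{path} unit {unit_id}: unparseable month") from exc
        expected = pd.period_range(idx[0], periods=len(idx), freq="M")
        if not idx.equals(expected):
            gap = expected.difference(idx)
            month = str(gap[0]) if len(gap) else "a duplicated month"
            raise CalendarGapError(f"{path} unit {unit_id}: gap at {month}")
        out[str(unit_id)] = MonthlySeries(
            grp["value"].to_numpy(float), idx[0], str(unit_id), kind=kind
        )
    return out


def write_series(series: Iterable[MonthlySeries], path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(
        path, index=False
    )


def read_binary_series(path, label: str = "") -> BinarySeries:
    return BinarySeries.from_frame(pd.read_csv(path), label=label)


def write_binary_series(series: BinarySeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_states(path) -> list[StateRecord]:
    frame = pd.read_csv(path)
    required = {"code", "name", "population", "lat", "lon", "law_restrictiveness"}
    if missing := required - set(frame.columns):
        raise ValueError(f"states CSV {path} lacks column(s) {sorted(missing)}")
    records = []
    for i, row in frame.iterrows():
        try:
            records.append(
                StateRecord(
                    code=str(row["code"]).upper(),
                    name=str(row["name"]),
                    population=float(row["population"]),
                    lat=float(row["lat"]),
                    lon=float(row["lon"]),
                    law_restrictiveness=float(row["law_restrictiveness"]),
                    included=bool(row.get("included", True)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} line {i + 2}: {exc}") from exc
    return records


def write_states(states: Sequence[StateRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "code": st.code,
                "name": st.name,
                "population": st.population,
                "lat": st.lat,
                "lon": st.lon,
                "law_restrictiveness": st.law_restrictiveness,
                "included": st.included,
            }
            for st in states
        ]
    ).to_csv(path, index=False)


def read_distances(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"from", "to", "km"}
    if missing := required - set(frame.columns):
        raise ValueError(f"distance CSV {path} lacks column(s) {sorted(missing)}")
    return frame.pivot(index="from", columns="to", values="km")


def write_results(tables, out_dir, config: PipelineConfig | None = None) -> list[Path]:
    """One CSV per study table plus a JSON provenance sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not isinstance(tables, (list, tuple)):
        tables = [tables]
    written = []
    for table in tables:
        stem = table.study if table.n is None else f"{table.study}_n{table.n}"
        path = out_dir / f"{stem}.csv"
        table.to_frame().to_csv(path, index=False)
        written.append(path)
    sidecar = {
        "tables": [p.name for p in written],
        "B": tables[0].B,
        "seed": tables[0].seed,
        "alpha": tables[0].alpha,
    }
    if config is not None:
        sidecar["config_hash"] = config.content_hash()
        sidecar["config"] = config.to_dict()
    provenance = out_dir / "provenance.json"
    provenance.write_text(json.dumps(sidecar, indent=2, default=str))
    written.append(provenance)
    return written


def build_study_data(cfg: PipelineConfig):
    """Read, preprocess, and symbolize everything a study run needs."""
    from symte.studies import StudyData

    states = read_states(cfg.states_csv)
    assign_clusters(states, exclude=cfg.exclude)

    bc_raw = read_series(cfg.bc_csv, kind="background_checks")
    bc = {
        code: symbolize_sign(seasonal_adjust_detrend(series))
        for code, series in bc_raw.items()
        if code not in cfg.exclude
    }
    media = {}
    for key, path in (("fc", cfg.media_fc_csv), ("s", cfg.media_s_csv)):
        outlets = read_series(path, kind="media_count")
        media[key] = aggregate_mode(
            [symbolize_median(s) for _, s in sorted(outlets.items())],
            label=f"media_{key}",
        )
    events = read_events(cfg.events_csv) if cfg.events_csv else None
    return StudyData(
        states=states,
        bc=bc,
        media_fc=media["fc"],
        media_s=media["s"],
        events=events,
        window=cfg.window,
    )
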