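"""Orchestration of the three group-level causal analyses.

* Study 1 — national event occurrence and the two media series as candidate
  causes of each group's background checks, each conditioned on the other two.
* Study 2 — in-state versus elsewhere event occurrence as candidate causes,
  each conditioned on the other.
* Study 3 — the neighbor background-check mode plus the two media series,
  each conditioned on the other two of the trio, swept over neighbor counts.

Also provides the conditional-probability map underlying the choropleths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from symte.inference import (
    DEFAULT_ALPHA,
    DEFAULT_B,
    GroupMember,
    GroupSpec,
    SurrogateResult,
    significance,
    surrogate_test,
)
from symte.partitioning import PERMISSIVE, RESTRICTIVE, StateRecord
from symte.preprocessing import EventList, events_to_binary
from symte.series import BinarySeries, check_aligned
from symte.spatial import distance_matrix, neighbor_mode_series

GROUPS = (RESTRICTIVE, PERMISSIVE)

CAUSE_EVENTS_NATIONAL = "events_national"
CAUSE_MEDIA_FC = "media_firearm_control"
CAUSE_MEDIA_S = "media_shootings"
CAUSE_EVENTS_IN_STATE = "events_in_state"
CAUSE_EVENTS_ELSEWHERE = "events_elsewhere"
CAUSE_NEIGHBOR_BC = "neighbor_bc"


@dataclass
class StudyData:
    """Everything the three studies consume, already symbolized."""

    states: list[StateRecord]
    bc: dict[str, BinarySeries]
    media_fc: BinarySeries
    media_s: BinarySeries
    events: EventList | None = None
    window: tuple[str, str] = ("1999-01", "2017-12")
    events_national: BinarySeries | None = None

    def __post_init__(self) -> None:
        if self.events_national is None and self.events is not None:
            self.events_national = events_to_binary(
                self.events, self.window, scope="national"
            )

    def group_members(self, group: str) -> list[StateRecord]:
        members = [
            st for st in self.states if st.included and st.cluster == group
        ]
        if not members:
            raise ValueError(f"no included states carry cluster label {group!r}")
        return members


@dataclass(frozen=True)
class CellResult:
    """One table cell: a group statistic with its permutation null."""

    group: str
    cause: str
    te: float
    q95: float
    p_value: float
    significant: bool
    degenerate_states: tuple[str, ...] = ()
    member_te: Mapping[str, float] = field(default_factory=dict)


@dataclass
class StudyTable:
    """Rows are effect groups, columns candidate causes."""

    study: str
    cells: list[CellResult]
    B: int
    seed: int
    alpha: float = DEFAULT_ALPHA
    n: int | None = None

    def cell(self, group: str, cause: str) -> CellResult:
        for c in self.cells:
            if c.group == group and c.cause == cause:
                return c
        raise KeyError((group, cause))

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(c.group for c in self.cells))

    @property
    def causes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(c.cause for c in self.cells))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append(
                {
                    "study": self.study,
                    "n_neighbors": self.n,
                    "group": c.group,
                    "cause": c.cause,
                    "te": c.te,
                    "q95": c.q95,
                    "p_value": c.p_value,
                    "significant": c.significant,
                    "degenerate_states": ";".join(c.degenerate_states),
                }
            )
        return pd.DataFrame(rows)


def _cell_seed(seed: int, study_no: int, group_idx: int, cause_idx: int, extra: int = 0) -> int:
    ss = np.random.SeedSequence([int(seed), study_no, group_idx, cause_idx, extra])
    return int(ss.generate_state(1)[0])


def _run_cells(
    study: str,
    study_no: int,
    data: StudyData,
    cause_table: Mapping[str, Mapping[str, tuple[BinarySeries, tuple[BinarySeries, ...]]]],
    B: int,
    seed: int,
    alpha: float,
    n: int | None = None,
) -> StudyTable:
    """cause_table: group -> cause name -> per-state (cause, conds) factory output."""
    cells = []
    for gi, group in enumerate(GROUPS):
        members = data.group_members(group)
        for ci, (cause_name, per_state) in enumerate(cause_table[group].items()):
            spec = GroupSpec(
                members=[
                    GroupMember(
                        code=st.code,
                        population=st.population,
                        cause=per_state[st.code][0],
                        effect=data.bc[st.code],
                        conds=per_state[st.code][1],
                    )
                    for st in members
                ]
            )
            res: SurrogateResult = surrogate_test(
                spec, B=B, seed=_cell_seed(seed, study_no, gi, ci, n or 0)
            )
            cells.append(
                CellResult(
                    group=group,
                    cause=cause_name,
                    te=res.observed,
                    q95=res.q95,
                    p_value=res.p_value,
                    significant=significance(res, alpha),
                    degenerate_states=res.degenerate_members,
                    member_te=res.member_observed,
                )
            )
    return StudyTable(study=study, cells=cells, B=B, seed=seed, alpha=alpha, n=n)


def run_study1(
    data: StudyData,
    B: int = DEFAULT_B,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> StudyTable:
    """Three shared candidate causes per group, mutually conditioned."""
    if data.events_national is None:
        raise ValueError("study 1 needs the national event series")
    shared = {
        CAUSE_EVENTS_NATIONAL: data.events_national,
        CAUSE_MEDIA_FC: data.media_fc,
        CAUSE_MEDIA_S: data.media_s,
    }
    check_aligned(*shared.values())
    cause_table = {}
    for group in GROUPS:
        members = data.group_members(group)
        per_group = {}
        for cause_name, cause in shared.items():
            conds = tuple(s for k, s in shared.items() if k != cause_name)
            per_group[cause_name] = {st.code: (cause, conds) for st in members}
        cause_table[group] = per_group
    return _run_cells("study1", 1, data, cause_table, B, seed, alpha)


def run_study2(
    data: StudyData,
    B: int = DEFAULT_B,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
) -> StudyTable:
    """In-state versus elsewhere event occurrence, conditioned on each other."""
    if data.events is None:
        raise ValueError("study 2 needs the event list")
    cause_table = {}
    for group in GROUPS:
        members = data.group_members(group)
        in_state = {
            st.code: events_to_binary(
                data.events, data.window, scope="in_state", state=st.code
            )
            for st in members
        }
        elsewhere = {
            st.code: events_to_binary(
                data.events, data.window, scope="elsewhere", state=st.code
            )
            for st in members
        }
        cause_table[group] = {
            CAUSE_EVENTS_IN_STATE: {
                st.code: (in_state[st.code], (elsewhere[st.code],)) for st in members
            },
            CAUSE_EVENTS_ELSEWHERE: {
                st.code: (elsewhere[st.code], (in_state[st.code],)) for st in members
            },
        }
    return _run_cells("study2", 2, data, cause_table, B, seed, alpha)


def run_study3(
    data: StudyData,
    n_list: Sequence[int] = (1, 3, 5, 7, 9),
    B: int = DEFAULT_B,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    distances: pd.DataFrame | None = None,
) -> list[StudyTable]:
    """Neighbor interaction plus the two media drivers, per neighbor count."""
    if distances is None:
        distances = distance_matrix([st for st in data.states if st.included])
    tables = []
    for n in n_list:
        cause_table = {}
        for group in GROUPS:
            members = data.group_members(group)
            bcbar = {
                st.code: neighbor_mode_series(
                    st.code, n, data.bc, data.states, distances=distances
                )
                for st in members
            }
            cause_table[group] = {
                CAUSE_NEIGHBOR_BC: {
                    st.code: (bcbar[st.code], (data.media_fc, data.media_s))
                    for st in members
                },
                CAUSE_MEDIA_S: {
                    st.code: (data.media_s, (bcbar[st.code], data.media_fc))
                    for st in members
                },
                CAUSE_MEDIA_FC: {
                    st.code: (data.media_fc, (bcbar[st.code], data.media_s))
                    for st in members
                },
            }
        tables.append(
            _run_cells("study3", 3, data, cause_table, B, seed, alpha, n=n)
        )
    return tables


def conditional_prob_map(
    bc: BinarySeries, cause: BinarySeries, cause_value: int
) -> float | None:
    """Plug-in P(BC(t+1)=up | BC(t)=down, cause(t)=cause_value).

    Returns None when the conditioning event never occurs.
    """
    check_aligned(bc, cause)
    if cause_value not in (0, 1):
        raise ValueError("cause_value must be 0 (down) or 1 (up)")
    mask = (bc.symbols[:-1] == 0) & (cause.symbols[:-1] == cause_value)
    if not mask.any():
        return None
    return float(bc.symbols[1:][mask].mean())


def probmap_frame(data: StudyData) -> pd.DataFrame:
    """Per-state conditional probabilities for every shared cause and value."""
    causes = {
        CAUSE_EVENTS_NATIONAL: data.events_national,
        CAUSE_MEDIA_FC: data.media_fc,
        CAUSE_MEDIA_S: data.media_s,
    }
    rows = []
    for st in data.states:
        if not st.included:
            continue
        for cause_name, cause in causes.items():
            if cause is None:
                continue
            for value in (0, 1):
                prob = conditional_prob_map(data.bc[st.code], cause, value)
                rows.append(
                    {
                        "state": st.code,
                        "cluster": st.cluster,
                        "cause": cause_name,
                        "cause_value": value,
                        "probability": np.nan if prob is None else prob,
                    }
                )
    return pd.DataFrame(rows)
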