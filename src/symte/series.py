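"""Calendar-indexed series types shared across the pipeline.

Two representations are used throughout: :class:`MonthlySeries` for raw or
residual continuous monthly values, and :class:`BinarySeries` for symbolic
up/down sequences (encoded 1 = up, 0 = down).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from symte.exceptions import AlignmentError

#: integer codes for the binary alphabet
DOWN, UP = 0, 1
ALPHABET_SIZE = 2


def _as_period(month) -> pd.Period:
    p = pd.Period(month, freq="M") if not isinstance(month, pd.Period) else month
    if p.freqstr not in ("M", "ME"):
        p = p.asfreq("M")
    return p


@dataclass(eq=False)
class BinarySeries:
    """A monthly sequence over the alphabet {down, up}, encoded {0, 1}.

    Parameters
    ----------
    symbols:
        Sequence of 0/1 values, one per month, length >= 2.
    start:
        Calendar month of the first symbol (anything ``pd.Period`` accepts).
    label:
        Optional identifier, e.g. the variable or unit name.
    """

    symbols: np.ndarray
    start: pd.Period = field(default_factory=lambda: pd.Period("1999-01", "M"))
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.symbols)
        if arr.dtype == bool:
            arr = arr.astype(np.int8)
        arr = arr.astype(np.int8, copy=False)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("a binary series needs at least two monthly symbols")
        bad = ~np.isin(arr, (DOWN, UP))
        if bad.any():
            raise ValueError(f"symbols must be 0 or 1; offending values {np.unique(arr[bad])}")
        self.symbols = arr
        self.start = _as_period(self.start)

    def __len__(self) -> int:
        return int(self.symbols.size)

    @property
    def index(self) -> pd.PeriodIndex:
        return pd.period_range(self.start, periods=len(self), freq="M")

    def aligned_with(self, other: "BinarySeries") -> bool:
        return len(self) == len(other) and self.start == other.start

    def relabeled(self) -> "BinarySeries":
        """Swap the two symbols consistently (down <-> up)."""
        return BinarySeries(1 - self.symbols, self.start, self.label)

    def is_degenerate(self) -> bool:
        """True when the series carries a single symbol only."""
        return bool(self.symbols.min() == self.symbols.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"month": self.index.strftime("%Y-%m"), "symbol": self.symbols.astype(int)}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str = "") -> "BinarySeries":
        frame = frame.sort_values("month")
        idx = pd.PeriodIndex(frame["month"].astype(str), freq="M")
        _require_contiguous(idx)
        return cls(frame["symbol"].to_numpy(), idx[0], label)


@dataclass(eq=False)
class MonthlySeries:
    """A continuous monthly series for one unit.

    ``kind`` distinguishes raw counts (``background_checks``, ``media_count``)
    from decomposition output (``residual``).
    """

    values: np.ndarray
    start: pd.Period = field(default_factory=lambda: pd.Period("1999-01", "M"))
    unit_id: str = ""
    kind: str = "background_checks"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("a monthly series needs at least one value")
        if not np.isfinite(arr).all():
            raise ValueError("monthly series values must be finite")
        self.values = arr
        self.start = _as_period(self.start)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def index(self) -> pd.PeriodIndex:
        return pd.period_range(self.start, periods=len(self), freq="M")

    @property
    def month_numbers(self) -> np.ndarray:
        """Calendar month (1..12) of every observation."""
        first = self.start.month
        return (first - 1 + np.arange(len(self))) % 12 + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": self.index.strftime("%Y-%m"),
                "unit_id": self.unit_id,
                "value": self.values,
            }
        )


def _require_contiguous(idx: pd.PeriodIndex) -> None:
    from symte.exceptions import CalendarGapError

    if len(idx) == 0:
        return
    expected = pd.period_range(idx[0], periods=len(idx), freq="M")
    if not idx.equals(expected):
        missing = expected.difference(idx)
        hint = str(missing[0]) if len(missing) else str(idx[idx.duplicated()][0])
        raise CalendarGapError(f"monthly index is not contiguous near {hint}")


def check_aligned(*series) -> None:
    """Raise :class:`AlignmentError` unless all series share start and length."""
    if not series:
        return
    first = series[0]
    for s in series[1:]:
        if len(s) != len(first) or s.start != first.start:
            raise AlignmentError(
                f"series {getattr(s, 'label', getattr(s, 'unit_id', ''))!r} "
                f"({s.start}, T={len(s)}) not aligned with "
                f"{getattr(first, 'label', getattr(first, 'unit_id', ''))!r} "
                f"({first.start}, T={len(first)})"
            )
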