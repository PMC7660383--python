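"""Plug-in estimation of entropy and (conditional) transfer entropy.

All quantities are in bits. The joint distribution over the tuple
``(Y(t+1), Y(t), X(t), Z1(t), ..., Zq(t))`` is estimated by frequency counts
over the T-1 adjacent month pairs; conditional entropies are computed as
differences of joint entropies, with no bias correction (a permutation null
absorbs estimator bias downstream).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import xlogy

from symte.exceptions import CapacityError, EmptyHistogramError, NormalizationError
from symte.series import ALPHABET_SIZE, BinarySeries, check_aligned

#: default minimum average observations per histogram cell before warning
MIN_SAMPLES_PER_CELL = 5


class CapacityWarning(UserWarning):
    """Series length is marginal for the requested conditioning order."""


@dataclass(frozen=True)
class TEEstimate:
    """A (conditional) transfer entropy value in bits."""

    value: float
    cause_id: str = ""
    effect_id: str = ""
    conditioning_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("transfer entropy estimate must be nonnegative")


@dataclass
class JointHistogram:
    """Counts of transition tuples ``(y_next, y_now, x_now, z1_now, ...)``."""

    counts: dict[tuple[int, ...], int]
    arity: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_array(self) -> np.ndarray:
        """Dense array of shape (2,) * arity."""
        arr = np.zeros((ALPHABET_SIZE,) * self.arity, dtype=float)
        for key, c in self.counts.items():
            arr[key] = c
        return arr

    def to_json(self) -> str:
        return json.dumps(
            {",".join(map(str, k)): v for k, v in sorted(self.counts.items())}
        )


def plugin_entropy(hist: Mapping | Sequence | np.ndarray) -> float:
    """Shannon entropy in bits of a histogram of symbol counts.

    Accepts a mapping ``symbol -> count`` or an array of counts. Zero counts
    contribute nothing (0 log 0 = 0).
    """
    if isinstance(hist, Mapping):
        counts = np.asarray(list(hist.values()), dtype=float)
    else:
        counts = np.asarray(hist, dtype=float).ravel()
    if counts.size == 0:
        raise EmptyHistogramError("histogram has no symbols")
    if (counts < 0).any():
        raise ValueError("histogram counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise EmptyHistogramError("histogram has no observations")
    p = counts / total
    return float(-xlogy(p, p).sum() / np.log(2))


def _entropy_of_array(arr: np.ndarray) -> float:
    total = arr.sum()
    if total <= 0:
        raise EmptyHistogramError("histogram has no observations")
    return float(np.log2(total) - xlogy(arr, arr).sum() / (total * np.log(2)))


def cte_from_joint(joint: np.ndarray) -> float:
    """Conditional transfer entropy from a joint array (counts or pmf).

    Axes are ``(y_next, y_now, x_now, z1, ..., zq)``. Returns
    ``H(Y+|Y,Z) - H(Y+|Y,X,Z)`` expanded into four joint entropies. Tiny
    negative values from floating-point cancellation are clipped to zero.
    """
    h_full = _entropy_of_array(joint)
    h_yyz = _entropy_of_array(joint.sum(axis=2))  # marginalize x
    h_yxz = _entropy_of_array(joint.sum(axis=0))  # marginalize y_next
    h_yz = _entropy_of_array(joint.sum(axis=(0, 2)))
    value = h_yyz + h_yxz - h_yz - h_full
    if value < -1e-9:
        raise AssertionError(f"plug-in CTE came out negative: {value}")
    return max(value, 0.0)


def check_capacity(
    t_samples: int, q: int, min_samples_per_cell: int = MIN_SAMPLES_PER_CELL
) -> None:
    """Guard the estimation burden of the (q+3)-variate joint histogram.

    Raises :class:`CapacityError` when there are fewer transition samples than
    cells; warns when the average falls below ``min_samples_per_cell``.
    """
    cells = ALPHABET_SIZE ** (q + 3)
    if t_samples < cells:
        raise CapacityError(
            f"{t_samples} transition samples cannot populate {cells} cells "
            f"(q={q} conditioning series); shorten the conditioning set"
        )
    if t_samples < min_samples_per_cell * cells:
        warnings.warn(
            f"only {t_samples} transition samples for {cells} cells "
            f"(< {min_samples_per_cell}/cell); estimates will be noisy",
            CapacityWarning,
            stacklevel=3,
        )


def transition_arrays(
    effect: BinarySeries,
    cause: BinarySeries,
    conds: Sequence[BinarySeries] = (),
) -> tuple[np.ndarray, ...]:
    """Aligned per-transition arrays ``(y_next, y_now, x_now, z...)``."""
    check_aligned(effect, cause, *conds)
    y = effect.symbols
    return (y[1:], y[:-1], cause.symbols[:-1], *(z.symbols[:-1] for z in conds))


def build_joint_histogram(
    effect: BinarySeries,
    cause: BinarySeries,
    conds: Sequence[BinarySeries] = (),
) -> JointHistogram:
    """One tuple per adjacent month pair; total count is T - 1."""
    cols = transition_arrays(effect, cause, conds)
    stacked = np.stack(cols, axis=1)
    counts: dict[tuple[int, ...], int] = {}
    uniq, n = np.unique(stacked, axis=0, return_counts=True)
    for row, c in zip(uniq, n):
        counts[tuple(int(v) for v in row)] = int(c)
    return JointHistogram(counts=counts, arity=len(cols))


def _joint_array(
    effect: BinarySeries, cause: BinarySeries, conds: Sequence[BinarySeries]
) -> np.ndarray:
    cols = transition_arrays(effect, cause, conds)
    arity = len(cols)
    code = np.zeros(cols[0].size, dtype=np.int64)
    for k, col in enumerate(cols):
        code += col.astype(np.int64) << (arity - 1 - k)
    flat = np.bincount(code, minlength=ALPHABET_SIZE**arity).astype(float)
    return flat.reshape((ALPHABET_SIZE,) * arity)


def conditional_transfer_entropy(
    cause: BinarySeries,
    effect: BinarySeries,
    conds: Sequence[BinarySeries] = (),
    min_samples_per_cell: int = MIN_SAMPLES_PER_CELL,
) -> TEEstimate:
    """Plug-in conditional transfer entropy from ``cause`` to ``effect``.

    With an empty conditioning set this is ordinary transfer entropy:
    ``H(Y(t+1)|Y(t)) - H(Y(t+1)|Y(t), X(t))``. Only lag-1 histories enter.
    """
    conds = tuple(conds)
    check_aligned(effect, cause, *conds)
    check_capacity(len(effect) - 1, len(conds), min_samples_per_cell)
    joint = _joint_array(effect, cause, conds)
    return TEEstimate(
        value=cte_from_joint(joint),
        cause_id=cause.label,
        effect_id=effect.label,
        conditioning_ids=tuple(z.label for z in conds),
    )


def transfer_entropy(cause: BinarySeries, effect: BinarySeries) -> TEEstimate:
    """Transfer entropy from ``cause`` to ``effect`` (no conditioning)."""
    return conditional_transfer_entropy(cause, effect, ())


def te_from_pmf(pmf: np.ndarray) -> float:
    """Exact conditional transfer entropy of a supplied joint pmf.

    ``pmf`` has axes ``(y_next, y_now, x_now, z1, ..., zq)`` and must sum
    to one; no estimation is involved. Intended as a closed-form oracle.
    """
    arr = np.asarray(pmf, dtype=float)
    if arr.ndim < 3:
        raise ValueError("pmf needs at least the (y_next, y_now, x_now) axes")
    if (arr < 0).any():
        raise NormalizationError("pmf has negative mass")
    if not np.isclose(arr.sum(), 1.0, atol=1e-8):
        raise NormalizationError(f"pmf sums to {arr.sum()}, expected 1")
    return cte_from_joint(arr)
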