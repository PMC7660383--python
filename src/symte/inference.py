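"""Stratified permutation testing and population-weighted aggregation.

The null distribution of the group statistic is built by permuting each
member's cause series only within strata sharing the same present-time tuple
of the effect and conditioning processes, which preserves the joint histogram
of (X(t), Y(t), Z(t)) exactly and destroys only the association between X(t)
and Y(t+1) inside each stratum.

Per-member random streams derive deterministically from the master seed and
the member's code, so results are independent of member ordering; replicates
consume the stream in replicate order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import xlogy

from symte.exceptions import AlignmentError
from symte.infotheory import (
    MIN_SAMPLES_PER_CELL,
    check_capacity,
    cte_from_joint,
    transition_arrays,
)
from symte.series import ALPHABET_SIZE, BinarySeries

DEFAULT_B = 20_000
DEFAULT_ALPHA = 0.050


@dataclass
class GroupMember:
    """One unit's series entering a group-level test."""

    code: str
    population: float
    cause: BinarySeries
    effect: BinarySeries
    conds: tuple[BinarySeries, ...] = ()

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError(f"member {self.code} needs population > 0")


@dataclass
class GroupSpec:
    """A non-empty set of members with aligned series."""

    members: list[GroupMember]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a group needs at least one member")


@dataclass
class SurrogateResult:
    """Observed group statistic with its permutation null distribution."""

    observed: float
    surrogate_values: np.ndarray
    q95: float
    p_value: float
    B: int
    seed: int
    member_observed: dict[str, float] = field(default_factory=dict)
    degenerate_members: tuple[str, ...] = ()

    def p_string(self) -> str:
        """Render the p-value, reporting zero exceedances as '< 1/B'."""
        if self.p_value == 0.0:
            return f"< {1.0 / self.B:g}"
        return f"{self.p_value:.3f}"


def strata_codes(effect: BinarySeries, conds: Sequence[BinarySeries] = ()) -> np.ndarray:
    """Stratum label per transition time: the tuple (Y(t), Z1(t), ..., Zq(t)).

    The future value Y(t+1) deliberately does not enter the stratum, so the
    tested dependence is destroyed by within-stratum shuffles.
    """
    cols = (effect.symbols[:-1], *(z.symbols[:-1] for z in conds))
    code = np.zeros(cols[0].size, dtype=np.int64)
    for k, col in enumerate(cols):
        code += col.astype(np.int64) << k
    return code


def stratified_permute(
    cause: BinarySeries, strata: np.ndarray, rng: np.random.Generator
) -> BinarySeries:
    """Shuffle cause symbols only among time instants in the same stratum.

    ``strata`` labels the T-1 transition instants; the final cause symbol
    enters no transition and stays fixed. Within each stratum the multiset of
    symbols is preserved; across strata nothing moves.
    """
    strata = np.asarray(strata)
    if strata.size != len(cause) - 1:
        raise AlignmentError(
            f"strata cover {strata.size} instants but the cause has "
            f"{len(cause) - 1} transition samples"
        )
    x = cause.symbols.copy()
    head = _permute_within_strata(x[:-1][None, :], strata, rng)
    x[:-1] = head[0]
    return BinarySeries(x, cause.start, cause.label)


def _permute_within_strata(
    rows: np.ndarray, strata: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Independently permute each row of ``rows`` within strata (vectorized)."""
    out = rows.copy()
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        if idx.size > 1:
            out[:, idx] = rng.permuted(out[:, idx], axis=1)
    return out


def aggregate_group_te(
    per_state_te: dict[str, float], populations: dict[str, float]
) -> float:
    """Population-weighted group statistic.

    The square of the population-weighted sum of the square roots of the
    per-unit transfer entropies, divided by the sum of squared populations:
    ``(sum_s pop_s * sqrt(TE_s))**2 / sum_s pop_s**2``.
    """
    if set(per_state_te) != set(populations):
        raise KeyError("per-unit TE and population key sets differ")
    codes = sorted(per_state_te)
    te = np.asarray([per_state_te[c] for c in codes], dtype=float)
    pop = np.asarray([populations[c] for c in codes], dtype=float)
    if (te < 0).any():
        raise ValueError("transfer entropy values must be nonnegative")
    if (pop <= 0).any():
        raise ValueError("populations must be positive")
    return float((pop * np.sqrt(te)).sum() ** 2 / (pop**2).sum())


# ---------------------------------------------------------------------------
# batched surrogate machinery

def _entropy_rows(counts: np.ndarray) -> np.ndarray:
    """Shannon entropy in bits of each row of a counts matrix."""
    flat = counts.reshape(counts.shape[0], -1)
    totals = flat.sum(axis=1)
    return np.log2(totals) - xlogy(flat, flat).sum(axis=1) / (totals * np.log(2))


def _cte_rows(counts: np.ndarray, q: int) -> np.ndarray:
    """CTE in bits per row; rows are flat joint histograms over 2**(q+3) cells."""
    shaped = counts.reshape(-1, 2, 2, 2, *(2,) * q)
    h_full = _entropy_rows(shaped)
    h_yyz = _entropy_rows(shaped.sum(axis=3))
    h_yxz = _entropy_rows(shaped.sum(axis=1))
    h_yz = _entropy_rows(shaped.sum(axis=(1, 3)))
    return np.clip(h_yyz + h_yxz - h_yz - h_full, 0.0, None)


def _member_rng(seed: int, code: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), *(ord(c) for c in str(code))])


def _member_surrogates(
    member: GroupMember, B: int, seed: int
) -> tuple[float, np.ndarray]:
    """Observed CTE and B surrogate CTEs for one member."""
    y_next, y_now, x, *zs = transition_arrays(member.effect, member.cause, member.conds)
    q = len(zs)
    arity = q + 3
    cols = (y_next, y_now, x, *zs)
    base = np.zeros(y_next.size, dtype=np.int64)
    for k, col in enumerate(cols):
        if k != 2:  # the x column is added per replicate
            base += col.astype(np.int64) << (arity - 1 - k)
    x_weight = 1 << (arity - 3)
    cells = ALPHABET_SIZE**arity

    obs_counts = np.bincount(base + x_weight * x, minlength=cells).astype(float)
    observed = cte_from_joint(obs_counts.reshape((2,) * arity))

    strata = strata_codes(member.effect, member.conds)
    rng = _member_rng(seed, member.code)
    xmat = _permute_within_strata(
        np.tile(x.astype(np.int64), (B, 1)), strata, rng
    )
    codes = base[None, :] + x_weight * xmat
    offsets = np.arange(B, dtype=np.int64)[:, None] * cells
    counts = np.bincount(
        (codes + offsets).ravel(), minlength=B * cells
    ).reshape(B, cells).astype(float)
    return observed, _cte_rows(counts, q)


def surrogate_test(
    group: GroupSpec,
    B: int = DEFAULT_B,
    seed: int = 0,
    min_samples_per_cell: int = MIN_SAMPLES_PER_CELL,
) -> SurrogateResult:
    """Permutation test of the population-weighted group statistic.

    The observed statistic aggregates per-member conditional transfer
    entropies; each of the B replicates independently applies a stratified
    permutation to every member's cause series, recomputes the per-member
    CTEs, and aggregates identically. The p-value is the fraction of
    surrogates at or above the observed value.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    for m in group.members:
        check_capacity(len(m.effect) - 1, len(m.conds), min_samples_per_cell)

    pops = np.asarray([m.population for m in group.members], dtype=float)
    member_observed: dict[str, float] = {}
    degenerate: list[str] = []
    surr_matrix = np.empty((B, len(group.members)))
    obs_vec = np.empty(len(group.members))
    for j, m in enumerate(group.members):
        obs, surr = _member_surrogates(m, B, seed)
        obs_vec[j] = obs
        surr_matrix[:, j] = surr
        member_observed[m.code] = obs
        if m.cause.is_degenerate() or m.effect.is_degenerate():
            degenerate.append(m.code)

    denom = (pops**2).sum()
    observed = float((pops * np.sqrt(obs_vec)).sum() ** 2 / denom)
    surrogate_values = ((np.sqrt(surr_matrix) * pops).sum(axis=1) ** 2) / denom
    q95 = float(np.quantile(surrogate_values, 0.95))
    p_value = float(np.count_nonzero(surrogate_values >= observed)) / B
    return SurrogateResult(
        observed=observed,
        surrogate_values=surrogate_values,
        q95=q95,
        p_value=p_value,
        B=B,
        seed=seed,
        member_observed=member_observed,
        degenerate_members=tuple(degenerate),
    )


def significance(result: SurrogateResult, alpha: float = DEFAULT_ALPHA) -> bool:
    """True iff the null is rejected: p strictly below alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return result.p_value < alpha
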