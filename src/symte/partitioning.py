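"""Classify units as restrictive or permissive from law-restrictiveness.

In one dimension with two clusters the optimal k-means partition is an
interval split, so it is found exactly by scanning all threshold positions;
no random initialization is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

RESTRICTIVE = "restrictive"
PERMISSIVE = "permissive"
EXCLUDED = "excluded"

#: size of the law catalogue the restrictiveness fraction refers to
TOTAL_LAWS = 133


@dataclass
class StateRecord:
    """One geographic unit with the metadata the analysis needs."""

    code: str
    name: str = ""
    population: float = 0.0
    lat: float = 0.0
    lon: float = 0.0
    law_restrictiveness: float = 0.0
    included: bool = True
    cluster: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.law_restrictiveness <= 1.0:
            raise ValueError(
                f"law_restrictiveness must be in [0, 1], got {self.law_restrictiveness}"
            )
        if self.included and self.population <= 0:
            raise ValueError(f"included state {self.code} needs population > 0")


def law_restrictiveness_fraction(
    laws_in_effect_by_year: Sequence[float], total_laws: int = TOTAL_LAWS
) -> float:
    """Mean over years of (laws in effect / total laws in the catalogue)."""
    counts = np.asarray(laws_in_effect_by_year, dtype=float)
    if total_laws <= 0:
        raise ValueError("total_laws must be positive")
    if counts.size == 0:
        raise ValueError("need at least one yearly count")
    if (counts < 0).any():
        raise ValueError("yearly law counts must be nonnegative")
    if (counts > total_laws).any():
        raise ValueError("yearly law counts cannot exceed the catalogue size")
    return float(counts.mean() / total_laws)


def implied_average_laws(fraction: float, total_laws: int = TOTAL_LAWS) -> float:
    """Average number of laws in effect implied by a restrictiveness fraction."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    return fraction * total_laws


def kmeans_partition(values: Sequence[float], k: int = 2) -> np.ndarray:
    """Exact 1-D two-cluster k-means by threshold search.

    Scans every split of the sorted values, minimizing the within-cluster sum
    of squares; the cluster with the larger mean is labeled restrictive.
    Deterministic and seed-free. Returns an array of labels aligned with the
    input order.
    """
    if k != 2:
        raise NotImplementedError("only k=2 is supported")
    vals = np.asarray(values, dtype=float)
    if np.unique(vals).size < k:
        raise ValueError(f"need at least {k} distinct values to form {k} clusters")
    order = np.argsort(vals, kind="stable")
    s = vals[order]
    n = s.size
    best_split, best_wcss = None, np.inf
    for i in range(1, n):
        if s[i - 1] == s[i]:
            continue  # equal values cannot straddle a threshold
        lo, hi = s[:i], s[i:]
        wcss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if wcss < best_wcss:
            best_wcss, best_split = wcss, i
    labels = np.empty(n, dtype=object)
    labels[order[:best_split]] = PERMISSIVE
    labels[order[best_split:]] = RESTRICTIVE
    return labels


def assign_clusters(
    states: Sequence[StateRecord], exclude: Sequence[str] = ("CT", "HI")
) -> list[StateRecord]:
    """Apply the exclusion list, then cluster the remaining units in place."""
    exclude = {c.upper() for c in exclude}
    kept = []
    for st in states:
        if st.code in exclude:
            st.included = False
            st.cluster = EXCLUDED
        elif st.included:
            kept.append(st)
        else:
            st.cluster = EXCLUDED
    labels = kmeans_partition([st.law_restrictiveness for st in kept])
    for st, lab in zip(kept, labels):
        st.cluster = str(lab)
    return list(states)
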