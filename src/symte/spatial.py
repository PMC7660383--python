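"""Geodesic proximity and neighbor-interaction series.

Distances are great-circle (haversine) on a sphere of radius 6371 km between
unit centroids; neighbor sets draw only from included units. The neighbor
interaction series is the per-month mode of the n nearest units' binary
background-check series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from symte.partitioning import StateRecord
from symte.preprocessing import aggregate_mode
from symte.series import BinarySeries

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class NeighborSet:
    """The n nearest included units of a focal unit, nearest first."""

    focal: str
    neighbors: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.focal in self.neighbors:
            raise ValueError("a unit cannot neighbor itself")

    @property
    def n(self) -> int:
        return len(self.neighbors)


def geodesic_distance(
    lat1: float, lon1: float, lat2: float, lon2: float, radius: float = EARTH_RADIUS_KM
) -> float:
    """Great-circle distance in kilometers between two lat/lon points."""
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
            raise ValueError(f"coordinates out of range: ({lat}, {lon})")
    phi1, phi2, dlam = np.radians(lat1), np.radians(lat2), np.radians(lon2 - lon1)
    dphi = phi2 - phi1
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def distance_matrix(states: Sequence[StateRecord]) -> pd.DataFrame:
    """Symmetric pairwise geodesic distances (km), zero diagonal."""
    codes = [st.code for st in states]
    lat = np.radians([st.lat for st in states])
    lon = np.radians([st.lon for st in states])
    dphi = lat[:, None] - lat[None, :]
    dlam = lon[:, None] - lon[None, :]
    a = (
        np.sin(dphi / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlam / 2) ** 2
    )
    km = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(km, 0.0)
    return pd.DataFrame(km, index=codes, columns=codes)


def nearest_neighbors(
    focal: str,
    states: Sequence[StateRecord],
    n: int,
    distances: pd.DataFrame | None = None,
) -> NeighborSet:
    """The n included units closest to ``focal`` by geodesic distance.

    Neighbors are not filtered by cluster label; excluded units never appear.
    Distance ties break lexicographically by code (logged).
    """
    included = [st for st in states if st.included]
    candidates = [st for st in included if st.code != focal]
    if n < 1 or n > len(candidates):
        raise ValueError(
            f"n={n} out of range: {len(candidates)} candidate neighbors for {focal}"
        )
    by_code = {st.code: st for st in included}
    if focal not in by_code:
        raise ValueError(f"focal unit {focal!r} not among included states")
    f = by_code[focal]
    if distances is not None:
        dist = [(float(distances.loc[focal, st.code]), st.code) for st in candidates]
    else:
        dist = [
            (geodesic_distance(f.lat, f.lon, st.lat, st.lon), st.code)
            for st in candidates
        ]
    dist.sort()  # (distance, code): lexicographic tie-break by construction
    kms = [d for d, _ in dist]
    if len(set(kms)) < len(kms):
        logger.warning("distance ties for %s broken lexicographically by code", focal)
    return NeighborSet(focal=focal, neighbors=tuple(code for _, code in dist[:n]))


def neighbor_mode_series(
    focal: str,
    n: int,
    bc_binary: Mapping[str, BinarySeries],
    states: Sequence[StateRecord],
    distances: pd.DataFrame | None = None,
) -> BinarySeries:
    """Per-month mode of the n nearest units' background-check symbols."""
    nset = nearest_neighbors(focal, states, n, distances=distances)
    missing = [c for c in nset.neighbors if c not in bc_binary]
    if missing:
        raise KeyError(f"missing background-check series for neighbor(s) {missing}")
    return aggregate_mode(
        [bc_binary[c] for c in nset.neighbors], label=f"bcbar:{focal}:n{n}"
    )
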