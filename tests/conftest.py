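"""Shared fixtures and independent oracle helpers.

The oracles here deliberately avoid the package's code paths: distances use
a locally written haversine, clustering uses breadth-first transitive
closure over the pairwise relation, and planar areas use the shoelace
formula / scipy's ConvexHull.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ventassess import GeoConfig, VentField

EARTH_RADIUS_KM = 6371.0088


def mkfield(site_id: str, lat: float, lon: float, area: str = "A1") -> VentField:
    return VentField(site_id=site_id, name=site_id, lat=lat, lon=lon,
                     management_area_id=area)


def oracle_haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Independent great-circle distance (law-of-cosines-free haversine)."""
    p1, l1, p2, l2 = map(math.radians, (a[0], a[1], b[0], b[1]))
    h = (
        math.sin((p2 - p1) / 2) ** 2
        + math.cos(p1) * math.cos(p2) * math.sin((l2 - l1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


def oracle_partition(fields, threshold_km: float = 80.0) -> set[frozenset[str]]:
    """Brute-force transitive closure of 'same area AND distance < threshold'."""
    n = len(fields)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            same_area = fields[i].management_area_id == fields[j].management_area_id
            close = (
                oracle_haversine_km(
                    (fields[i].lat, fields[i].lon), (fields[j].lat, fields[j].lon)
                )
                < threshold_km
            )
            adj[i][j] = adj[j][i] = same_area and close
    seen: set[int] = set()
    groups: set[frozenset[str]] = set()
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            i = stack.pop()
            if i in comp:
                continue
            comp.add(i)
            stack.extend(j for j in range(n) if adj[i][j] and j not in comp)
        seen |= comp
        groups.add(frozenset(fields[i].site_id for i in comp))
    return groups


def oracle_laea_km(lats, lons, lat0: float, lon0: float):
    """Independent Lambert azimuthal equal-area projection (sphere), km."""
    phi = np.radians(np.asarray(lats, dtype=float))
    phi0 = math.radians(lat0)
    dl = np.radians(((np.asarray(lons, dtype=float) - lon0 + 180.0) % 360.0) - 180.0)
    cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dl)
    k = np.sqrt(2.0 / (1.0 + cosc))
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dl)
    y = EARTH_RADIUS_KM * k * (
        math.cos(phi0) * np.sin(phi) - math.sin(phi0) * np.cos(phi) * np.cos(dl)
    )
    return x, y


def shoelace_area(xy) -> float:
    """Signed-area-free shoelace formula for a polygon's vertex list."""
    xy = np.asarray(xy, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def random_regional_instance(rng: np.random.Generator, max_sites: int = 50):
    """Random sites scattered over a ~600 km region with 1-3 management areas,
    so that both merged and separated location structures occur."""
    n = int(rng.integers(1, max_sites + 1))
    lat0 = float(rng.uniform(-55.0, 55.0))
    lon0 = float(rng.uniform(-170.0, 170.0))
    n_areas = int(rng.integers(1, 4))
    fields = []
    for i in range(n):
        dlat = float(rng.uniform(-3.0, 3.0))
        dlon = float(rng.uniform(-3.0, 3.0))
        area = f"A{int(rng.integers(1, n_areas + 1))}"
        fields.append(mkfield(f"S{i:03d}", lat0 + dlat, lon0 + dlon, area))
    return fields


@pytest.fixture
def config() -> GeoConfig:
    return GeoConfig()
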