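"""Synthetic ridge-system generator with constructive ground truth.

Emulates the geometry the assessment procedure targets: a mid-ocean ridge
segment dotted with tiny vent fields (each well under 0.1 km²), grouped
into clusters whose internal spacing is far below the location threshold
while inter-cluster gaps exceed it, and cut by management-area boundaries.
Because the intended location partition is built in by construction, the
generator doubles as an independent oracle for the clustering code.

Real survey data differ in ways the generator does not emulate: vent fields
are not evenly spaced, ridges bend, and management boundaries are polygons
rather than fractions of arc length. None of those features enter the
clustering definition, which depends only on pairwise distances and area
membership.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .errors import InfeasibleSpecError, ValidationError
from .geo import VentField
from .threats import RegulatoryRegime

__all__ = ["SyntheticRidgeSpec", "SyntheticRidge", "generate_synthetic_ridge"]

# jitter draws are clipped at 4 sigma; the feasibility margin of 12 sigma on
# nominal gaps then guarantees realised gaps stay on the intended side of the
# threshold (two points, each displaced at most 4*sqrt(2) sigma)
_CLIP_SIGMA = 4.0
_MARGIN_SIGMA = 12.0

#: deterministic regime rotation for generated management areas
_REGIME_CYCLE = (
    RegulatoryRegime.EXPLORATION_LICENSE,
    RegulatoryRegime.PROTECTED_EFFECTIVE,
    RegulatoryRegime.UNPROTECTED_NO_LICENSE,
)


@dataclass(frozen=True)
class SyntheticRidgeSpec:
    """Specification of a synthetic ridge system.

    ``cluster_sizes`` gives the intended location structure before
    management splits (sums to ``n_fields``); consecutive fields within a
    cluster sit ``mean_spacing_km`` apart along the ridge, clusters are
    separated by ``gap_km``, and every field is jittered isotropically with
    standard deviation ``jitter_km``. ``management_splits`` are strictly
    increasing fractions in (0, 1) of the occupied ridge length at which a
    new management area begins.
    """

    n_fields: int
    ridge_start: tuple[float, float] = (-35.0, 50.0)
    ridge_end: tuple[float, float] = (-25.0, 65.0)
    mean_spacing_km: float = 10.0
    jitter_km: float = 0.5
    gap_km: float = 200.0
    cluster_sizes: tuple[int, ...] | None = None
    management_splits: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fields < 1:
            raise ValidationError("n_fields must be >= 1", field="n_fields")
        if self.mean_spacing_km <= 0:
            raise ValidationError("mean_spacing_km must be > 0", field="mean_spacing_km")
        if self.jitter_km < 0:
            raise ValidationError("jitter_km must be >= 0", field="jitter_km")
        if self.gap_km <= 0:
            raise ValidationError("gap_km must be > 0", field="gap_km")
        if self.cluster_sizes is not None:
            if any(s < 1 for s in self.cluster_sizes):
                raise ValidationError("cluster sizes must be >= 1", field="cluster_sizes")
            if sum(self.cluster_sizes) != self.n_fields:
                raise ValidationError(
                    f"cluster_sizes sum {sum(self.cluster_sizes)} != n_fields {self.n_fields}",
                    field="cluster_sizes",
                )
        if any(not (0.0 < f < 1.0) for f in self.management_splits):
            raise ValidationError(
                "management splits must lie strictly in (0, 1)", field="management_splits"
            )
        if list(self.management_splits) != sorted(set(self.management_splits)):
            raise ValidationError(
                "management splits must be strictly increasing", field="management_splits"
            )

    @property
    def effective_cluster_sizes(self) -> tuple[int, ...]:
        return self.cluster_sizes if self.cluster_sizes is not None else (self.n_fields,)


@dataclass(frozen=True)
class SyntheticRidge:
    """Generator output: occurrences, regimes and the intended partition."""

    fields: tuple[VentField, ...]
    regimes: dict[str, RegulatoryRegime]
    true_partition: tuple[frozenset[str], ...]
    spec: SyntheticRidgeSpec


def _unit_vector(lat: float, lon: float) -> np.ndarray:
    phi, lmb = math.radians(lat), math.radians(lon)
    return np.array(
        [math.cos(phi) * math.cos(lmb), math.cos(phi) * math.sin(lmb), math.sin(phi)]
    )


def _to_latlon(v: np.ndarray) -> tuple[float, float]:
    v = v / np.linalg.norm(v)
    lat = math.degrees(math.asin(max(-1.0, min(1.0, float(v[2])))))
    lon = math.degrees(math.atan2(float(v[1]), float(v[0])))
    if lon >= 180.0:
        lon -= 360.0
    return lat, lon


def generate_synthetic_ridge(
    spec: SyntheticRidgeSpec,
    threshold_km: float = 80.0,
    earth_radius_km: float = 6371.0088,
) -> SyntheticRidge:
    """Generate occurrence records along a great-circle ridge segment.

    ``threshold_km`` is the clustering threshold the output is constructed
    for: the spec is rejected as infeasible unless intra-cluster spacing
    (plus jitter margin) stays below it and inter-cluster gaps (minus
    margin) stay above it, so the returned ``true_partition`` is the
    provably correct location partition at that threshold. Deterministic
    for a fixed seed.
    """
    margin = _MARGIN_SIGMA * spec.jitter_km
    if spec.mean_spacing_km + margin >= threshold_km:
        raise InfeasibleSpecError(
            f"mean_spacing_km {spec.mean_spacing_km} + jitter margin {margin:.1f} "
            f"is not below threshold {threshold_km} km; intra-cluster chaining "
            "cannot be guaranteed"
        )
    if len(spec.effective_cluster_sizes) > 1 and spec.gap_km - margin <= threshold_km:
        raise InfeasibleSpecError(
            f"gap_km {spec.gap_km} - jitter margin {margin:.1f} is not above "
            f"threshold {threshold_km} km; cluster separation cannot be guaranteed"
        )

    # nominal along-ridge arc-length of each field
    positions: list[float] = []
    cluster_of: list[int] = []
    s = 0.0
    for ci, size in enumerate(spec.effective_cluster_sizes):
        if ci > 0:
            s += spec.gap_km
        for k in range(size):
            if k > 0:
                s += spec.mean_spacing_km
            positions.append(s)
            cluster_of.append(ci)
    total = positions[-1] if positions[-1] > 0 else 1.0

    u0 = _unit_vector(*spec.ridge_start)
    u1 = _unit_vector(*spec.ridge_end)
    omega = math.acos(max(-1.0, min(1.0, float(np.dot(u0, u1)))))
    ridge_length = omega * earth_radius_km
    if total > ridge_length:
        raise InfeasibleSpecError(
            f"fields span {total:.0f} km but the ridge segment is only "
            f"{ridge_length:.0f} km long"
        )

    rng = np.random.default_rng(spec.seed)
    jitter = np.clip(
        rng.normal(0.0, spec.jitter_km or 1.0, size=(len(positions), 2)),
        -_CLIP_SIGMA * (spec.jitter_km or 1.0),
        _CLIP_SIGMA * (spec.jitter_km or 1.0),
    ) * (1.0 if spec.jitter_km > 0 else 0.0)

    # management area from the nominal fraction of occupied ridge length
    bounds = list(spec.management_splits) + [1.0 + 1e-9]

    fields: list[VentField] = []
    area_ids: list[str] = []
    for i, (pos, (jx, jy)) in enumerate(zip(positions, jitter.tolist())):
        w = pos / earth_radius_km  # arc angle along the ridge
        v = (math.sin(omega - w) * u0 + math.sin(w) * u1) / math.sin(omega) if omega > 0 else u0
        lat, lon = _to_latlon(v)
        # isotropic jitter applied in the local tangent plane
        lat_j = lat + math.degrees(jy / earth_radius_km)
        lon_j = lon + math.degrees(jx / (earth_radius_km * math.cos(math.radians(lat))))
        frac = pos / total
        area_idx = next(k for k, b in enumerate(bounds) if frac < b)
        area_id = f"M{area_idx + 1:02d}"
        area_ids.append(area_id)
        fields.append(
            VentField(
                site_id=f"SYN{i + 1:03d}",
                name=f"synthetic vent field {i + 1}",
                lat=lat_j,
                lon=((lon_j + 180.0) % 360.0) - 180.0,
                management_area_id=area_id,
                footprint_km2=0.05,
            )
        )

    regimes = {
        area: _REGIME_CYCLE[k % len(_REGIME_CYCLE)]
        for k, area in enumerate(sorted(set(area_ids)))
    }
    # ground truth: construction cluster further split at management borders
    groups: dict[tuple[int, str], set[str]] = {}
    for f, ci, area in zip(fields, cluster_of, area_ids):
        groups.setdefault((ci, area), set()).add(f.site_id)
    partition = tuple(frozenset(g) for _, g in sorted(groups.items()))
    return SyntheticRidge(
        fields=tuple(fields),
        regimes=regimes,
        true_partition=partition,
        spec=spec,
    )
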