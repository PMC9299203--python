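"""Geodesic distance, location clustering, AOO and EOO."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import ConvexHull

from ventassess import (
    GeoConfig,
    NoOccurrenceRecordsError,
    ValidationError,
    VentField,
    cluster_locations,
    compute_aoo,
    compute_eoo,
    compute_range_metrics,
    geodesic_distance_km,
)

from conftest import (
    EARTH_RADIUS_KM,
    mkfield,
    oracle_haversine_km,
    oracle_laea_km,
    oracle_partition,
    random_regional_instance,
    shoelace_area,
)

latitudes = st.floats(min_value=-85.0, max_value=85.0)
longitudes = st.floats(min_value=-180.0, max_value=179.999)


class TestGeodesicDistance:
    @pytest.mark.parametrize(
        "a, b, expected, tol",
        [
            ((10.0, 20.0), (10.0, 20.0), 0.0, 1e-12),  # identity
            # one degree of arc along the equator: R * pi / 180
            ((0.0, 0.0), (0.0, 1.0), EARTH_RADIUS_KM * math.pi / 180.0, 1e-3),
            # near-antipodal points: the arc R * pi * 179.9999 / 180
            # (longitude 180 itself is normalised to -180, outside the domain)
            ((0.0, 0.0), (0.0, 179.9999),
             math.pi * EARTH_RADIUS_KM * 179.9999 / 180.0, 1e-2),
        ],
    )
    def test_closed_form_arcs(self, a, b, expected, tol):
        assert geodesic_distance_km(a, b) == pytest.approx(expected, abs=tol)

    def test_printed_reference_values(self):
        # the closed-form arcs above evaluate to these km figures
        assert geodesic_distance_km((0.0, 0.0), (0.0, 1.0)) == pytest.approx(111.195, abs=1e-3)
        assert geodesic_distance_km((0.0, 0.0), (0.0, 179.9999)) == pytest.approx(
            20015.103, abs=1e-2
        )

    @pytest.mark.parametrize("bad", [(95.0, 0.0), (-91.0, 10.0)])
    def test_latitude_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError, match="lat"):
            geodesic_distance_km(bad, (0.0, 0.0))

    def test_longitude_out_of_range_rejected(self):
        with pytest.raises(ValidationError, match="lon"):
            geodesic_distance_km((0.0, 200.0), (0.0, 0.0))

    @settings(max_examples=150, derandomize=True)
    @given(
        lat1=latitudes, lon1=longitudes, lat2=latitudes, lon2=longitudes,
        lat3=latitudes, lon3=longitudes,
    )
    def test_symmetry_and_triangle_inequality(self, lat1, lon1, lat2, lon2, lat3, lon3):
        a, b, c = (lat1, lon1), (lat2, lon2), (lat3, lon3)
        dab = geodesic_distance_km(a, b)
        assert dab == pytest.approx(geodesic_distance_km(b, a), abs=1e-9)
        assert dab >= 0.0
        assert dab <= geodesic_distance_km(a, c) + geodesic_distance_km(c, b) + 1e-6

    @settings(max_examples=100, derandomize=True)
    @given(lat1=latitudes, lon1=longitudes, lat2=latitudes, lon2=longitudes)
    def test_matches_independent_haversine(self, lat1, lon1, lat2, lon2):
        got = geodesic_distance_km((lat1, lon1), (lat2, lon2))
        assert got == pytest.approx(oracle_haversine_km((lat1, lon1), (lat2, lon2)), abs=1e-9)


class TestClusterLocations:
    def test_three_fields_within_threshold_one_area(self):
        # ~0.3 degrees apart along a meridian: all pairwise gaps < 80 km
        fields = [mkfield(f"S{i}", -3.5 + 0.3 * i, 151.7) for i in range(3)]
        locs = cluster_locations(fields)
        assert len(locs) == 1
        assert locs[0].site_ids == {"S0", "S1", "S2"}
        assert locs[0].location_id == "L001"

    def test_chain_merges_even_when_endpoints_far(self):
        # A-B 70 km, B-C 70 km, A-C 140 km: single-linkage chains all three
        step = 70.0 / (EARTH_RADIUS_KM * math.pi / 180.0)
        fields = [mkfield(f"S{i}", 0.0, i * step) for i in range(3)]
        assert geodesic_distance_km((0, 0), (0, 2 * step)) > 80.0
        locs = cluster_locations(fields)
        assert len(locs) == 1
        assert oracle_partition(fields) == {frozenset({"S0", "S1", "S2"})}

    def test_management_area_boundary_separates_nearby_fields(self):
        fields = [
            mkfield("S0", 0.0, 0.0, area="ISA_1"),
            mkfield("S1", 0.0, 0.45, area="EEZ_X"),  # 50 km away
        ]
        locs = cluster_locations(fields)
        assert len(locs) == 2
        assert {loc.management_area_id for loc in locs} == {"ISA_1", "EEZ_X"}

    def test_gap_exactly_at_threshold_separates(self):
        step = 80.0 / (EARTH_RADIUS_KM * math.pi / 180.0)
        fields = [mkfield("S0", 0.0, 0.0), mkfield("S1", 0.0, step)]
        assert geodesic_distance_km((0, 0), (0, step)) == pytest.approx(80.0, abs=1e-9)
        assert len(cluster_locations(fields)) == 2

    def test_deterministic_ordering_by_smallest_site_id(self):
        fields = [
            mkfield("Z9", 0.0, 0.0, area="A"),
            mkfield("A1", 10.0, 10.0, area="B"),
        ]
        locs = cluster_locations(fields)
        assert [sorted(l.site_ids)[0] for l in locs] == ["A1", "Z9"]
        assert [l.location_id for l in locs] == ["L001", "L002"]

    def test_empty_input_raises(self):
        with pytest.raises(NoOccurrenceRecordsError):
            cluster_locations([])

    def test_matches_brute_force_transitive_closure(self):
        rng = np.random.default_rng(20260929)
        for _ in range(50):
            fields = random_regional_instance(rng, max_sites=50)
            got = {frozenset(l.site_ids) for l in cluster_locations(fields)}
            assert got == oracle_partition(fields)

    def test_threshold_monotonicity(self):
        """Shrinking the threshold never decreases the number of locations."""
        rng = np.random.default_rng(12)
        for _ in range(25):
            fields = random_regional_instance(rng, max_sites=30)
            counts = [
                len(cluster_locations(fields, GeoConfig(threshold_km=t)))
                for t in (160.0, 80.0, 40.0)
            ]
            assert counts == sorted(counts)

    def test_merging_management_areas_never_increases_locations(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            fields = random_regional_instance(rng, max_sites=30)
            merged = [
                VentField(f.site_id, f.name, f.lat, f.lon, "MERGED")
                for f in fields
            ]
            assert len(cluster_locations(merged)) <= len(cluster_locations(fields))


class TestComputeAoo:
    def test_three_fields_three_cells(self):
        fields = [mkfield(f"S{i}", -3.5 + 0.1 * i, 151.7) for i in range(3)]  # ~11 km apart
        assert compute_aoo(fields) == 12.0

    def test_two_fields_in_one_cell_count_once(self):
        fields = [mkfield("S0", 10.0, 20.0), mkfield("S1", 10.0045, 20.0)]  # ~0.5 km
        assert compute_aoo(fields) == 4.0

    def test_single_field(self):
        assert compute_aoo([mkfield("S0", -37.78, 49.65)]) == 4.0

    def test_duplicate_coordinates_occupy_one_cell(self):
        fields = [mkfield("S0", 5.0, 5.0), mkfield("S1", 5.0, 5.0)]
        assert compute_aoo(fields) == 4.0

    def test_multiple_of_cell_area_and_bounded(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            fields = random_regional_instance(rng, max_sites=40)
            aoo = compute_aoo(fields)
            assert aoo % 4.0 == 0.0
            assert 4.0 <= aoo <= 4.0 * len(fields)

    def test_custom_cell_size(self):
        fields = [mkfield("S0", 0.0, 0.0), mkfield("S1", 0.0, 0.5)]
        aoo = compute_aoo(fields, GeoConfig(cell_km=10.0))
        assert aoo % 100.0 == 0.0 and aoo in (100.0, 200.0)


class TestComputeEoo:
    def test_single_field_floored_to_aoo(self):
        fields = [mkfield("S0", -37.78, 49.65)]
        assert compute_eoo(fields, aoo_km2=4.0) == 4.0

    def test_collinear_fields_floored_to_aoo(self):
        fields = [mkfield(f"S{i}", 0.0, 0.2 * i) for i in range(3)]  # equatorial geodesic
        assert compute_eoo(fields, aoo_km2=12.0) == 12.0

    def test_triangle_matches_shoelace_oracle(self):
        fields = [
            mkfield("S0", 0.0, 0.0),
            mkfield("S1", 0.0, 0.5),
            mkfield("S2", 0.4, 0.25),
        ]
        lats = [f.lat for f in fields]
        lons = [f.lon for f in fields]
        x, y = oracle_laea_km(lats, lons, float(np.mean(lats)), float(np.mean(lons)))
        expected = shoelace_area(np.column_stack([x, y]))
        assert expected > 12.0  # above the AOO floor, so the hull area governs
        got = compute_eoo(fields, aoo_km2=12.0)
        assert got == pytest.approx(expected, rel=1e-3)

    def test_hull_area_matches_scipy_convex_hull(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(25):
            fields = random_regional_instance(rng, max_sites=50)
            if len(fields) < 3:
                continue
            lats = np.array([f.lat for f in fields])
            lons = np.array([f.lon for f in fields])
            lmb = np.radians(lons)
            lon0 = math.degrees(math.atan2(np.mean(np.sin(lmb)), np.mean(np.cos(lmb))))
            x, y = oracle_laea_km(lats, lons, float(np.mean(lats)), lon0)
            pts = np.column_stack([x, y])
            if np.linalg.matrix_rank(pts - pts[0]) < 2:
                continue
            expected = ConvexHull(pts).volume  # 2-D: area
            got = compute_eoo(fields, aoo_km2=0.001)
            assert got == pytest.approx(expected, rel=1e-3)
            checked += 1
        assert checked >= 10

    def test_antimeridian_range_is_compact(self):
        # a ~110 km-wide range straddling 180 deg must not wrap into a
        # near-global polygon
        fields = [
            mkfield("S0", -20.0, 179.7),
            mkfield("S1", -20.5, -179.8),
            mkfield("S2", -20.2, -179.95),
        ]
        assert compute_eoo(fields, aoo_km2=12.0) < 5_000.0


class TestRangeMetrics:
    def test_worked_single_location_species(self):
        fields = [mkfield(f"S{i}", -3.5 + 0.1 * i, 151.7) for i in range(3)]
        m = compute_range_metrics(fields)
        assert (m.n_fields, m.n_locations, m.aoo_km2) == (3, 1, 12.0)
        assert m.eoo_km2 >= 12.0

    def test_singleton(self):
        m = compute_range_metrics([mkfield("S0", -37.78, 49.65)])
        assert (m.n_fields, m.n_locations, m.aoo_km2, m.eoo_km2) == (1, 1, 4.0, 4.0)

    def test_matches_componentwise_recomputation(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            fields = random_regional_instance(rng, max_sites=10)
            m = compute_range_metrics(fields)
            assert m.n_fields == len(fields)
            assert m.n_locations == len(oracle_partition(fields))
            assert m.aoo_km2 == compute_aoo(fields)
            assert m.eoo_km2 == compute_eoo(fields, m.aoo_km2)
            assert m.eoo_km2 >= m.aoo_km2

    def test_duplicate_site_ids_rejected(self):
        fields = [mkfield("S0", 0.0, 0.0), mkfield("S0", 1.0, 1.0)]
        with pytest.raises(ValidationError, match="duplicate"):
            compute_range_metrics(fields)
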