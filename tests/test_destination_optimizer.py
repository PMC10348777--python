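"""Geodesic primitive, ground/air rule, and nearest-alternative search."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retriage import cohort, destination_optimizer as do
from retriage.hospitals import HospitalDirectory

from conftest import make_encounters

SF = (37.7749, -122.4194)
LA = (34.0522, -118.2437)

MILES_PER_DEG_LAT = math.pi * do.EARTH_RADIUS_MILES / 180.0


def point_at_miles(origin, miles):
    """Point due north of origin at an exact great-circle distance."""
    return (origin[0] + miles / MILES_PER_DEG_LAT, origin[1])


def test_haversine_zero_and_known_distance():
    assert do.haversine_miles(SF, SF) == 0.0
    # frozen from an independent geodesic implementation (R geosphere,
    # distHaversine with r = 3958.8 mi)
    assert do.haversine_miles(SF, LA) == pytest.approx(347.4253, abs=0.01)


@given(
    st.floats(-80, 80), st.floats(-179, 179), st.floats(-80, 80), st.floats(-179, 179)
)
@settings(deadline=None, max_examples=100, derandomize=True)
def test_haversine_symmetric_and_nonnegative(lat1, lon1, lat2, lon2):
    d12 = do.haversine_miles((lat1, lon1), (lat2, lon2))
    d21 = do.haversine_miles((lat2, lon2), (lat1, lon1))
    assert d12 >= 0.0
    assert d12 == pytest.approx(d21, rel=1e-9, abs=1e-9)


def test_mode_rule_below_and_above_threshold():
    near = point_at_miles(SF, 49.0)
    far = point_at_miles(SF, 60.0)
    est_near = do.estimate_transport(SF, near)
    assert est_near.mode == do.GROUND
    # fallback drive model: circuity 1.3 at 40 mph
    assert est_near.time_hours == pytest.approx(49.0 * 1.3 / 40.0, rel=1e-6)
    est_far = do.estimate_transport(SF, far)
    assert est_far.mode == do.AIR
    assert est_far.time_hours == pytest.approx(0.5, rel=1e-6)


def test_exact_50_mile_boundary_goes_to_air(monkeypatch):
    monkeypatch.setattr(do, "haversine_miles", lambda p1, p2: 50.0)
    assert do.estimate_transport(SF, LA).mode == do.AIR
    monkeypatch.setattr(do, "haversine_miles", lambda p1, p2: 49.999)
    assert do.estimate_transport(SF, LA).mode == do.GROUND


def test_failing_provider_falls_back_with_warning(caplog):
    class Broken:
        def drive_time_hours(self, p1, p2):
            raise RuntimeError("routing service down")

    near = point_at_miles(SF, 10.0)
    with caplog.at_level("WARNING"):
        est = do.estimate_transport(SF, near, Broken())
    assert est.mode == do.GROUND
    assert est.time_hours == pytest.approx(10.0 * 1.3 / 40.0, rel=1e-6)
    assert any("fallback" in r.message for r in caplog.records)


# --- alternative destination search ------------------------------------------

def _geo_directory(centers):
    """centers: list of (facility_id, level, lat, lon)."""
    return HospitalDirectory.from_records(
        [
            {
                "facility_id": fid,
                "name": fid,
                "latitude": lat,
                "longitude": lon,
                "facility_type": "SHORT_TERM_ACUTE",
                "lemsa_id": "L1",
                "rtcc_id": "SOUTH_WEST",
                "level_by_year": {y: level for y in range(2009, 2019)},
            }
            for fid, level, lat, lon in centers
        ]
    )


def test_ground_preference_within_50_miles():
    d = _geo_directory(
        [
            ("II10", "LEVEL_II", *point_at_miles(SF, 10.0)),
            ("I30", "LEVEL_I", *point_at_miles(SF, 30.0)),
        ]
    )
    alt = do.find_alternative_destination(SF, 2018, d)
    assert alt["resolvable"] and alt["proposed_facility_id"] == "II10"
    assert alt["mode"] == do.GROUND


def test_air_when_no_center_within_50_miles():
    d = _geo_directory(
        [
            ("I80", "LEVEL_I", *point_at_miles(SF, 80.0)),
            ("II120", "LEVEL_II", *point_at_miles(SF, 120.0)),
        ]
    )
    alt = do.find_alternative_destination(SF, 2018, d)
    assert alt["proposed_facility_id"] == "I80" and alt["mode"] == do.AIR
    assert alt["time_hours"] == pytest.approx(80.0 / 120.0, rel=1e-6)


def test_unresolvable_when_no_high_level_centers():
    d = _geo_directory([("N1", "NONTRAUMA", *SF)])
    alt = do.find_alternative_destination(SF, 2018, d)
    assert alt["resolvable"] is False and alt["proposed_facility_id"] is None


def test_candidates_respect_annual_designation():
    d = _geo_directory([("X", "LEVEL_II", *point_at_miles(SF, 5.0))])
    d.levels.loc[d.levels["year"] < 2015, "level"] = "LEVEL_III"
    d = HospitalDirectory(d.facilities, d.levels)
    assert not do.find_alternative_destination(SF, 2014, d)["resolvable"]
    assert do.find_alternative_destination(SF, 2015, d)["resolvable"]


def brute_force_choice(sending, year, directory):
    """Independent oracle: evaluate every candidate, then apply the
    two-branch rule (ground among <50 mi if any, else air over all)."""
    cand = directory.operating_centers(year, {"LEVEL_I", "LEVEL_II"})
    options = []
    for row in cand.itertuples():
        miles = do.haversine_miles(sending, (row.latitude, row.longitude))
        ground_time = 1.3 * miles / 40.0
        air_time = miles / 120.0
        options.append((row.facility_id, miles, ground_time, air_time))
    if not options:
        return None
    near = [o for o in options if o[1] < 50.0]
    if near:
        return min(near, key=lambda o: (o[2], o[0]))[0]
    return min(options, key=lambda o: (o[3], o[0]))[0]


def test_oracle_equivalence_random_geographies_small():
    rng = np.random.default_rng(12)
    for _ in range(100):
        k = int(rng.integers(1, 8))
        centers = [
            (f"C{j}", rng.choice(["LEVEL_I", "LEVEL_II"]),
             float(rng.uniform(32, 42)), float(rng.uniform(-124, -114)))
            for j in range(k)
        ]
        d = _geo_directory(centers)
        sending = (float(rng.uniform(32, 42)), float(rng.uniform(-124, -114)))
        alt = do.find_alternative_destination(sending, 2018, d)
        assert alt["proposed_facility_id"] == brute_force_choice(sending, 2018, d)


def test_adding_a_candidate_never_increases_time():
    rng = np.random.default_rng(13)
    sending = (36.0, -120.0)
    centers = []
    prev_time = float("inf")
    for j in range(15):
        centers.append(
            (f"C{j:02d}", "LEVEL_II",
             float(rng.uniform(32, 42)), float(rng.uniform(-124, -114)))
        )
        alt = do.find_alternative_destination(sending, 2018, _geo_directory(centers))
        assert alt["time_hours"] <= prev_time + 1e-12
        prev_time = alt["time_hours"]


def test_optimize_all_accounting(clean_events, clean_directory):
    table, summary = do.optimize_all(clean_events, clean_directory)
    assert len(table) == summary["n_suboptimal"]
    assert summary["suboptimal_rate_after"] == pytest.approx(
        (summary["n_suboptimal"] - summary["n_resolvable"]) / summary["n_retriage"]
    )
    resolved = table[table["resolvable"]]
    # proposed destinations are always level I/II in the event's year
    years = clean_events.loc[resolved["event_id"], "year"]
    levels = clean_directory.levels_for(
        resolved["proposed_facility_id"].reset_index(drop=True),
        years.reset_index(drop=True),
    )
    assert levels.isin(["LEVEL_I", "LEVEL_II"]).all()


def test_desert_geography_resolvable_fraction():
    # sending centers in a region with no level I/II anywhere -> unresolvable
    d = _geo_directory([("N1", "NONTRAUMA", *SF), ("N2", "LEVEL_III", *LA)])
    base = {"recv_facility_id": "N2", "recv_admission_type": "EMERGENT", "gap_days": 0}
    ev = make_encounters([{**base, "facility_id": "N1"}] * 4)
    ev = cohort.label_optimality(ev, d)
    table, summary = do.optimize_all(ev, d)
    assert summary["resolvable_fraction"] == 0.0
    assert summary["suboptimal_rate_after"] == summary["suboptimal_rate_before"]
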