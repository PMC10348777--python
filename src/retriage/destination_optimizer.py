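"""Alternative level I/II destinations under the ground/air transport rule.

For each suboptimal re-triage the optimizer searches the level I/II trauma
centers operating that year and picks the one with the shortest estimated
transport time. Transport mode follows a distance threshold: ground is
assumed fastest below 50 miles, air at and above 50 miles. Air time is
straight-line (great-circle) distance at a conservative 120 mph; ground time
comes from a pluggable drive-time provider, with a built-in fallback that
scales great-circle distance by a road circuity factor over an average road
speed. Selection rule: if any candidate lies within 50 miles, take the
shortest ground time among those; otherwise take the shortest air time over
all candidates. No candidate anywhere means the event is unresolvable — a
data outcome, not an error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import vocab
from .cohort import SUBOPTIMAL
from .hospitals import HospitalDirectory

log = logging.getLogger(__name__)

EARTH_RADIUS_MILES = 3958.8
AIR_SPEED_MPH = 120.0
GROUND_AIR_THRESHOLD_MILES = 50.0

GROUND = "GROUND"
AIR = "AIR"


def haversine_miles(p1, p2) -> float:
    """Great-circle distance in statute miles between (lat, lon) points."""
    return float(_haversine_vec(p1[0], p1[1], np.array([p2[0]]), np.array([p2[1]]))[0])


def _haversine_vec(lat1, lon1, lats, lons):
    phi1, lam1 = math.radians(lat1), math.radians(lon1)
    phi2, lam2 = np.radians(lats), np.radians(lons)
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2) ** 2 + math.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return EARTH_RADIUS_MILES * 2 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class FallbackDriveTimeProvider:
    """Drive-time model used when no routing engine is wired in: road distance
    is great-circle distance inflated by a circuity factor, traversed at an
    average road speed.

    circuity: unitless road-to-crow-flies ratio (default 1.3).
    speed_mph: average door-to-door road speed (default 40 mph).
    """

    circuity: float = 1.3
    speed_mph: float = 40.0

    def drive_time_hours(self, p1, p2) -> float:
        return self.drive_distance_miles(p1, p2) / self.speed_mph

    def drive_distance_miles(self, p1, p2) -> float:
        return self.circuity * haversine_miles(p1, p2)


@dataclass
class TransportEstimate:
    mode: str
    distance_miles: float
    time_hours: float


def estimate_transport(sending, candidate, drive_time_provider=None) -> TransportEstimate:
    """Mode and time for one sending-candidate pair.

    Below 50 great-circle miles the mode is GROUND with the provider's drive
    time; at or above 50 miles it is AIR at straight-line miles / 120 mph.
    A failing provider falls back to the built-in drive model with a warning.
    """
    provider = drive_time_provider or FallbackDriveTimeProvider()
    miles = haversine_miles(sending, candidate)
    if miles >= GROUND_AIR_THRESHOLD_MILES:
        return TransportEstimate(AIR, miles, miles / AIR_SPEED_MPH)
    try:
        hours = provider.drive_time_hours(sending, candidate)
    except Exception as exc:
        log.warning("drive-time provider failed (%s); using fallback model", exc)
        hours = FallbackDriveTimeProvider().drive_time_hours(sending, candidate)
    return TransportEstimate(GROUND, miles, hours)


def _candidate_table(directory: HospitalDirectory, year: int) -> pd.DataFrame:
    return directory.operating_centers(year, vocab.HIGH_LEVELS)


def find_alternative_destination(
    sending_coords,
    year: int,
    directory: HospitalDirectory,
    drive_time_provider=None,
    exclude: set | None = None,
) -> dict:
    """Best alternative level I/II destination for one suboptimal event.

    Candidates are the level I/II short-term acute centers operating that
    year (minus ``exclude``). If any lie within the 50-mile screen
    (great-circle by default), the shortest ground time among them wins;
    otherwise the shortest air time over all candidates. Ties break by
    facility_id. Returns a dict with ``resolvable=False`` when no candidate
    exists.
    """
    cand = _candidate_table(directory, year)
    if exclude:
        cand = cand[~cand["facility_id"].isin(exclude)]
    if cand.empty:
        return {"resolvable": False, "proposed_facility_id": None,
                "mode": None, "distance_miles": None, "time_hours": None}
    provider = drive_time_provider or FallbackDriveTimeProvider()
    lat, lon = sending_coords
    miles = _haversine_vec(lat, lon, cand["latitude"].to_numpy(), cand["longitude"].to_numpy())
    within = miles < GROUND_AIR_THRESHOLD_MILES
    if within.any():
        sub = cand[within].reset_index(drop=True)
        times = np.array(
            [
                estimate_transport(sending_coords, (r.latitude, r.longitude), provider).time_hours
                for r in sub.itertuples()
            ]
        )
        order = np.lexsort((sub["facility_id"].to_numpy(), times))
        best = sub.iloc[order[0]]
        est = estimate_transport(sending_coords, (best["latitude"], best["longitude"]), provider)
    else:
        times = miles / AIR_SPEED_MPH
        order = np.lexsort((cand["facility_id"].to_numpy(), times))
        best = cand.iloc[order[0]]
        est = estimate_transport(sending_coords, (best["latitude"], best["longitude"]), provider)
    return {
        "resolvable": True,
        "proposed_facility_id": best["facility_id"],
        "mode": est.mode,
        "distance_miles": est.distance_miles,
        "time_hours": est.time_hours,
    }


def optimize_all(
    events: pd.DataFrame,
    directory: HospitalDirectory,
    drive_time_provider=None,
) -> tuple[pd.DataFrame, dict]:
    """Alternative destination for every suboptimal event, plus a summary.

    The summary reports the fraction of suboptimal events with a resolvable
    alternative, and the statewide suboptimal rate before and after the
    hypothetical rerouting (unresolvable events remain suboptimal).
    """
    sub = events[events["optimality"] == SUBOPTIMAL]
    rows = []
    for idx, ev in sub.iterrows():
        coords = directory.coordinates(ev["facility_id"])
        alt = find_alternative_destination(
            coords, int(ev["year"]), directory, drive_time_provider,
            exclude={ev["facility_id"]},
        )
        rows.append(
            {
                "event_id": idx,
                "sending_facility_id": ev["facility_id"],
                "original_receiving_facility_id": ev["recv_facility_id"],
                "proposed_facility_id": alt["proposed_facility_id"],
                "mode": alt["mode"],
                "distance_miles": alt["distance_miles"],
                "time_hours": alt["time_hours"],
                "resolvable": alt["resolvable"],
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "event_id", "sending_facility_id", "original_receiving_facility_id",
            "proposed_facility_id", "mode", "distance_miles", "time_hours", "resolvable",
        ],
    )
    n_total = len(events)
    n_sub = len(sub)
    n_resolved = int(table["resolvable"].sum()) if len(table) else 0
    summary = {
        "n_retriage": n_total,
        "n_suboptimal": n_sub,
        "n_resolvable": n_resolved,
        "resolvable_fraction": n_resolved / n_sub if n_sub else float("nan"),
        "suboptimal_rate_before": n_sub / n_total if n_total else float("nan"),
        "suboptimal_rate_after": (n_sub - n_resolved) / n_total if n_total else float("nan"),
    }
    return table, summary
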