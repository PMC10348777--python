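"""Hospital directory: facility identity, location, and year-indexed trauma level.

The directory mirrors what public annual hospital-utilization reports provide:
one row per facility with WGS84 coordinates, facility type, LEMSA and regional
(RTCC) membership, plus an annual trauma-level designation that may change
from year to year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import vocab

FACILITY_COLUMNS = [
    "facility_id",
    "name",
    "latitude",
    "longitude",
    "facility_type",
    "lemsa_id",
    "rtcc_id",
]


@dataclass
class HospitalDirectory:
    """Facilities plus their annual trauma-level designations.

    Parameters
    ----------
    facilities
        One row per facility with columns ``facility_id, name, latitude,
        longitude, facility_type, lemsa_id, rtcc_id``.
    levels
        One row per (facility_id, year) with column ``level``; every facility
        must carry a designation for every year of the simulation horizon.
    """

    facilities: pd.DataFrame
    levels: pd.DataFrame
    _level_lookup: dict = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        fac = self.facilities
        if (fac["latitude"].abs() > 90).any() or (fac["longitude"].abs() > 180).any():
            raise ValueError("facility coordinates outside WGS84 bounds")
        unknown = set(self.levels["level"]) - set(vocab.TRAUMA_LEVELS)
        if unknown:
            raise ValueError(f"unknown trauma levels in directory: {sorted(unknown)}")
        if self.levels.duplicated(["facility_id", "year"]).any():
            raise ValueError("duplicate (facility_id, year) level designations")
        self._level_lookup = {
            (fid, int(yr)): lvl
            for fid, yr, lvl in self.levels[["facility_id", "year", "level"]].itertuples(
                index=False
            )
        }
        self._facility_rows = self.facilities.set_index("facility_id")

    # -- lookups --------------------------------------------------------------

    @property
    def facility_ids(self) -> list[str]:
        return self.facilities["facility_id"].tolist()

    def has_facility(self, facility_id: str) -> bool:
        return facility_id in self._facility_rows.index

    def level_for(self, facility_id: str, year: int) -> str:
        try:
            return self._level_lookup[(facility_id, int(year))]
        except KeyError:
            raise KeyError(
                f"no trauma-level designation for facility {facility_id!r} in {year}"
            ) from None

    def levels_for(self, facility_ids: pd.Series, years: pd.Series) -> pd.Series:
        """Vectorized level lookup; raises on any unresolvable pair."""
        keys = list(zip(facility_ids, years.astype(int)))
        missing = [k for k in keys if k not in self._level_lookup]
        if missing:
            raise KeyError(f"unresolvable facility-year designations, e.g. {missing[0]}")
        return pd.Series(
            [self._level_lookup[k] for k in keys], index=facility_ids.index, dtype=object
        )

    def attribute_for(self, facility_ids: pd.Series, column: str) -> pd.Series:
        unknown = set(facility_ids) - set(self._facility_rows.index)
        if unknown:
            raise KeyError(f"unknown facility_id {sorted(unknown)[0]!r}")
        return (
            self._facility_rows[column]
            .reindex(facility_ids)
            .set_axis(facility_ids.index)
        )

    def coordinates(self, facility_id: str) -> tuple[float, float]:
        row = self._facility_rows.loc[facility_id]
        return float(row["latitude"]), float(row["longitude"])

    def operating_centers(self, year: int, levels: frozenset | set) -> pd.DataFrame:
        """Facilities holding one of ``levels`` in ``year`` (short-term acute only)."""
        lv = self.levels[(self.levels["year"] == year) & self.levels["level"].isin(levels)]
        out = self.facilities.merge(lv[["facility_id", "level"]], on="facility_id")
        return out[out["facility_type"] == vocab.SHORT_TERM_ACUTE].reset_index(drop=True)

    # -- summaries ------------------------------------------------------------

    def summary(self) -> dict:
        """Counts per level per year plus a flag when no level I/II center
        exists anywhere in a year (the optimizer's no-alternative regime)."""
        counts = (
            self.levels.groupby(["year", "level"]).size().unstack(fill_value=0).sort_index()
        )
        high = counts.reindex(columns=sorted(vocab.HIGH_LEVELS), fill_value=0).sum(axis=1)
        return {
            "n_facilities": int(len(self.facilities)),
            "levels_by_year": counts,
            "years_without_high_level_center": [int(y) for y in high.index[high == 0]],
        }

    # -- i/o ------------------------------------------------------------------

    def to_csv(self, path) -> None:
        """One tidy row per facility-year."""
        tidy = self.levels.merge(self.facilities, on="facility_id")
        tidy[FACILITY_COLUMNS + ["year", "level"]].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HospitalDirectory":
        tidy = pd.read_csv(path)
        facilities = tidy[FACILITY_COLUMNS].drop_duplicates("facility_id").reset_index(drop=True)
        levels = tidy[["facility_id", "year", "level"]].copy()
        levels["year"] = levels["year"].astype(int)
        return cls(facilities, levels)

    @classmethod
    def from_records(cls, records: list[dict]) -> "HospitalDirectory":
        """Build from per-facility dicts carrying a ``level_by_year`` mapping."""
        fac_rows, lvl_rows = [], []
        for rec in records:
            fac_rows.append({k: rec[k] for k in FACILITY_COLUMNS})
            for year, level in rec["level_by_year"].items():
                lvl_rows.append(
                    {"facility_id": rec["facility_id"], "year": int(year), "level": level}
                )
        return cls(pd.DataFrame(fac_rows), pd.DataFrame(lvl_rows))
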