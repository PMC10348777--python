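"""Optimality labeling, covariate encoding, and hierarchical rate aggregation.

A re-triage is *optimal* when the receiving center holds a level I or II
designation in that year — regardless of distance — and *suboptimal* when
the receiving center is itself a nontrauma or level III/IV center.
Suboptimal counts and rates are aggregated at the state, regional (RTCC),
LEMSA, and sending-center levels, pooled and per year.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import vocab
from .hospitals import HospitalDirectory

OPTIMAL = "OPTIMAL"
SUBOPTIMAL = "SUBOPTIMAL"

AGGREGATION_LEVELS = ("STATE", "RTCC", "LEMSA", "CENTER")


def label_optimality(pairs: pd.DataFrame, directory: HospitalDirectory) -> pd.DataFrame:
    """Turn linked pairs into labeled re-triage events.

    Both trauma levels are resolved at the sending discharge year (the
    designation is annual). Distance is never consulted. Adds sending and
    receiving levels, the optimality label, and the sending center's LEMSA
    and RTCC membership.
    """
    events = pairs.copy()
    year = events["year"].astype(int)
    events["sending_level"] = directory.levels_for(events["facility_id"], year)
    events["receiving_level"] = directory.levels_for(events["recv_facility_id"], year)
    events["optimality"] = np.where(
        events["receiving_level"].isin(vocab.HIGH_LEVELS), OPTIMAL, SUBOPTIMAL
    )
    events["lemsa_id"] = directory.attribute_for(events["facility_id"], "lemsa_id")
    events["rtcc_id"] = directory.attribute_for(events["facility_id"], "rtcc_id")
    return events


def encode_covariates(events: pd.DataFrame) -> pd.DataFrame:
    """Map raw covariate codes into the analysis vocabularies.

    Deterministic coding: age and injury-severity bands, the four-level race
    and mechanism groupings, and the insurance mapping in which managed-care
    plan codes count as private except the unspecified managed-care
    category, which stays distinct. Raises on any unmapped code.
    """
    out = events.copy()

    def map_col(col, mapping, new):
        vals = out[col].astype(str).str.lower()
        bad = sorted(set(vals) - set(mapping))
        if bad:
            raise ValueError(f"unmapped {col} code(s): {bad}")
        out[new] = vals.map(mapping)

    out["age_band"] = [vocab.age_band(int(a)) for a in out["age"]]
    out["riss_band"] = [vocab.riss_band(int(r)) for r in out["riss"]]
    map_col("race", vocab.RACE_CODE_MAP, "race")
    map_col("ethnicity", vocab.ETHNICITY_CODE_MAP, "ethnicity")
    map_col("insurance", vocab.INSURANCE_CODE_MAP, "insurance")
    map_col("mechanism", vocab.MECHANISM_CODE_MAP, "mechanism")
    return out


def resolve_body_region(flags: dict[str, bool]) -> str:
    """Collapse multiple affected-region flags to one category by precedence:
    TBI > torso > other head/face/neck > extremities > other."""
    for region in vocab.BODY_REGION_PRECEDENCE:
        if flags.get(region):
            return region
    return "OTHER"


def _rate_rows(groups) -> pd.DataFrame:
    rows = []
    for key, g in groups:
        n = len(g)
        n_sub = int((g["optimality"] == SUBOPTIMAL).sum())
        rows.append(key + (n, n_sub, n_sub / n if n else np.nan))
    return pd.DataFrame(
        rows, columns=["unit_id", "year", "n_retriage", "n_suboptimal", "rate"]
    )


def aggregate_rates(
    events: pd.DataFrame, directory: HospitalDirectory, level: str
) -> pd.DataFrame:
    """Suboptimal re-triage counts/rates per unit, per year and pooled.

    ``level`` is one of STATE, RTCC, LEMSA, CENTER. Each row carries the
    unit, the year (or ``ALL`` for the pooled row), counts, the rate, and
    the unit's share of all statewide suboptimal re-triages in that period.
    Units with zero re-triages do not appear (their rate is undefined, never
    reported as 0).
    """
    if level not in AGGREGATION_LEVELS:
        raise ValueError(f"unknown aggregation level {level!r}")
    ev = events.copy()
    unit = {
        "STATE": lambda df: pd.Series("CA", index=df.index),
        "RTCC": lambda df: df["rtcc_id"],
        "LEMSA": lambda df: df["lemsa_id"],
        "CENTER": lambda df: df["facility_id"],
    }[level](ev)
    ev["_unit"] = unit

    per_year = _rate_rows(
        ((u, int(y)), g) for (u, y), g in ev.groupby(["_unit", "year"], sort=True)
    )
    pooled = _rate_rows(((u, "ALL"), g) for u, g in ev.groupby("_unit", sort=True))
    table = pd.concat([pooled, per_year], ignore_index=True)

    state_sub_by_year = ev[ev["optimality"] == SUBOPTIMAL].groupby("year").size()
    state_sub_total = int((ev["optimality"] == SUBOPTIMAL).sum())

    def share(row):
        denom = state_sub_total if row["year"] == "ALL" else state_sub_by_year.get(row["year"], 0)
        return row["n_suboptimal"] / denom if denom else np.nan

    table["share_of_state_suboptimal"] = table.apply(share, axis=1)
    table.insert(0, "aggregation_level", level)
    return table


def annual_trend(events: pd.DataFrame) -> pd.DataFrame:
    """Per-year statewide suboptimal rate plus each region's share of that
    year's suboptimal re-triages. Shares across regions sum to 1 in every
    year with at least one suboptimal re-triage."""
    rows = []
    for year, g in events.groupby("year", sort=True):
        n, n_sub = len(g), int((g["optimality"] == SUBOPTIMAL).sum())
        sub_by_rtcc = g[g["optimality"] == SUBOPTIMAL].groupby("rtcc_id").size()
        for rtcc in sorted(events["rtcc_id"].unique()):
            rows.append(
                {
                    "year": int(year),
                    "state_rate": n_sub / n,
                    "rtcc_id": rtcc,
                    "rtcc_share_of_suboptimal": (
                        sub_by_rtcc.get(rtcc, 0) / n_sub if n_sub else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def center_level_summary(
    events: pd.DataFrame, directory: HospitalDirectory
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sending-center counts plus the two headline center fractions.

    The denominator is the number of sending-eligible centers (nontrauma or
    level III/IV, short-term acute) operating each year (or in any year, for
    the pooled row). Reports the fraction of those centers with at least one
    suboptimal re-triage, and the fraction of centers with at least one
    re-triage that sent >=40% of their re-triages suboptimally (inclusive
    threshold).
    """
    per_center = _rate_rows(
        ((u, "ALL"), g) for u, g in events.groupby("facility_id", sort=True)
    )

    years = sorted(events["year"].astype(int).unique())
    rows = []

    def eligible_centers(year=None) -> set:
        lv = directory.levels
        if year is not None:
            lv = lv[lv["year"] == year]
        lv = lv[lv["level"].isin(vocab.LOW_LEVELS)]
        fac = directory.facilities
        sta = set(fac.loc[fac["facility_type"] == vocab.SHORT_TERM_ACUTE, "facility_id"])
        return set(lv["facility_id"]) & sta

    def summarize(ev, denom_centers, label):
        by_center = ev.groupby("facility_id")["optimality"].agg(
            n="size", n_sub=lambda s: int((s == SUBOPTIMAL).sum())
        )
        n_with_sub = int((by_center["n_sub"] >= 1).sum())
        with_events = by_center[by_center["n"] > 0]
        n_high_share = int((with_events["n_sub"] / with_events["n"] >= 0.40).sum())
        denom = len(denom_centers)
        rows.append(
            {
                "year": label,
                "n_eligible_centers": denom,
                "frac_with_any_suboptimal": n_with_sub / denom if denom else np.nan,
                "frac_sending_40pct_suboptimal": (
                    n_high_share / len(with_events) if len(with_events) else np.nan
                ),
            }
        )

    summarize(events, eligible_centers(), "ALL")
    for y in years:
        summarize(events[events["year"] == y], eligible_centers(y), int(y))
    return per_center, pd.DataFrame(rows)


TABLE_ONE_FACTORS = (
    "age_band", "sex", "race", "ethnicity", "insurance",
    "mechanism", "body_region", "riss_band", "rtcc_id",
)


def table_one(events: pd.DataFrame, factors: tuple = TABLE_ONE_FACTORS) -> pd.DataFrame:
    """Characteristics table: per covariate level, counts and percentages
    among all re-triages and within the suboptimal and optimal strata.
    Percent denominators are the stratum totals."""
    n_all = len(events)
    sub = events[events["optimality"] == SUBOPTIMAL]
    opt = events[events["optimality"] == OPTIMAL]
    rows = [{
        "variable": "total", "level": "", "n_retriage": n_all, "pct_retriage": 100.0,
        "n_suboptimal": len(sub), "pct_suboptimal": 100.0,
        "n_optimal": len(opt), "pct_optimal": 100.0,
    }]
    for factor in factors:
        levels = vocab.FACTOR_LEVELS.get(factor, sorted(events[factor].unique()))
        for level in levels:
            if (events[factor] == level).sum() == 0:
                continue
            row = {"variable": factor, "level": level}
            for name, frame in (("retriage", events), ("suboptimal", sub), ("optimal", opt)):
                k = int((frame[factor] == level).sum())
                row[f"n_{name}"] = k
                row[f"pct_{name}"] = 100.0 * k / len(frame) if len(frame) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def format_rate_percent(rate: float) -> float:
    """Report rates as percentages rounded to one decimal."""
    return float(np.round(100.0 * rate, 1))
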