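"""Record cleaning, encounter pairing, and the inclusion/exclusion cascade.

The linkage strategy mirrors what administrative discharge data permit:
records carry a pseudonymous patient identifier (RLN) and date-only stamps,
so a re-triage is recognised as a sending ED encounter and a receiving
encounter at a different facility under the same RLN whose admission falls 0
or 1 days after the ED discharge. The 1-day window keeps transfers that
start late at night and finish as early-morning admissions; longer gaps are
nonemergent interfacility transfers and are excluded.

Every ED encounter ends in exactly one of three buckets: a cohort re-triage
pair, the under-triaged-not-transferred stratum, or excluded-with-reason.
The cascade's order is fixed and published so ledgers are comparable run to
run; final cohorts do not depend on the order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import vocab
from .hospitals import HospitalDirectory

DEDUP_KEY = ["rln", "facility_id", "record_kind", "admit_date", "discharge_date"]

#: Cascade rules in application order, with first-match attribution.
EXCLUSION_RULES = [
    "missing_rln",
    "age_out_of_18_89",
    "no_injury_diagnosis",
    "riss_15_or_less",
    "burn_injury",
    "field_triage_to_level_I_II",
    "sending_not_low_level_short_term_acute",
    "excluded_sending_disposition",
    "interfacility_transfer_gap_over_1_day",
    "elective_receiving_admission",
    "receiving_not_short_term_acute",
]


@dataclass
class ExclusionLedger:
    """Ordered audit of the cascade: (rule, n_removed, n_remaining)."""

    steps: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["rule", "n_removed", "n_remaining"])

    @property
    def total_removed(self) -> int:
        return int(sum(s[1] for s in self.steps))

    @property
    def final_remaining(self) -> int:
        return int(self.steps[-1][2]) if self.steps else 0


def deduplicate_records(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse exact duplicate rows (same RLN, facility, kind, admit and
    discharge date), keeping the first occurrence and preserving order."""
    before = len(records)
    out = records.drop_duplicates(subset=DEDUP_KEY, keep="first").reset_index(drop=True)
    return out, before - len(out)


def link_encounter_pairs(
    ed_records: pd.DataFrame, inpatient_records: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair ED encounters with receiving encounters by RLN and date adjacency.

    A candidate requires matching non-null RLNs and a different receiving
    facility. Candidates at gap 0-1 days (receiving admission minus ED
    discharge) are re-triage pairs; gaps of 2+ days are returned separately
    as interfacility candidates. When several receiving encounters qualify
    for one ED encounter, the earliest admission wins, ties broken by
    facility_id.

    Inputs must already be deduplicated. Returns ``(pairs, interfacility)``;
    both carry the ED columns plus ``recv_*`` receiving columns and
    ``gap_days``.
    """
    ed = ed_records[ed_records["rln"].notna()].copy()
    ip = inpatient_records[inpatient_records["rln"].notna()].copy()
    ed["_ed_row"] = np.arange(len(ed))
    recv_cols = [
        "facility_id", "admit_date", "discharge_date", "disposition",
        "admission_type", "year",
    ] + (["surgery_class"] if "surgery_class" in ip.columns else [])
    ip_small = ip[["rln"] + recv_cols].rename(columns={c: f"recv_{c}" for c in recv_cols})

    cand = ed.merge(ip_small, on="rln", how="inner")
    cand = cand[cand["recv_facility_id"] != cand["facility_id"]]
    gap = (
        pd.to_datetime(cand["recv_admit_date"]) - pd.to_datetime(cand["discharge_date"])
    ).dt.days
    cand = cand.assign(gap_days=gap)
    cand = cand[cand["gap_days"] >= 0]

    def best(frame):
        frame = frame.sort_values(
            ["_ed_row", "recv_admit_date", "recv_facility_id"], kind="mergesort"
        )
        return frame.drop_duplicates("_ed_row", keep="first")

    pairs = best(cand[cand["gap_days"] <= 1])
    # interfacility candidates: ED encounters whose only matches are 2+ days out
    inter = best(cand[(cand["gap_days"] >= 2) & ~cand["_ed_row"].isin(pairs["_ed_row"])])
    drop = lambda f: f.drop(columns="_ed_row").reset_index(drop=True)
    return drop(pairs), drop(inter)


def apply_inclusion_exclusion(
    ed_records: pd.DataFrame,
    inpatient_records: pd.DataFrame,
    directory: HospitalDirectory,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionLedger]:
    """Run the full cascade over deduplicated ED encounters.

    Returns ``(cohort, under_triaged, ledger)``: cohort rows are linked
    re-triage pairs that satisfy every rule; under-triaged rows are
    qualifying ED encounters with no transfer within the window; everything
    else is removed at the first rule it violates. The ledger accounts for
    every input ED encounter: total removed + cohort + under-triaged equals
    the deduplicated ED count.
    """
    unknown = set(ed_records["facility_id"]) - set(directory.facility_ids)
    if unknown:
        raise KeyError(f"unknown facility_id in ED records: {sorted(unknown)[0]!r}")

    pairs, inter = link_encounter_pairs(ed_records, inpatient_records)

    ed = ed_records.copy()
    ed["_key"] = list(zip(ed["rln"], ed["facility_id"], ed["admit_date"]))
    pair_keys = set(zip(pairs["rln"], pairs["facility_id"], pairs["admit_date"]))
    inter_keys = set(zip(inter["rln"], inter["facility_id"], inter["admit_date"]))

    merged = ed.merge(
        pairs[
            ["rln", "facility_id", "admit_date"]
            + [c for c in pairs.columns if c.startswith("recv_") or c == "gap_days"]
        ],
        on=["rln", "facility_id", "admit_date"],
        how="left",
    )
    merged["_paired"] = merged["_key"].isin(pair_keys)
    merged["_interfacility"] = merged["_key"].isin(inter_keys) & ~merged["_paired"]

    sending_level = directory.levels_for(merged["facility_id"], merged["year"])
    sending_type = directory.attribute_for(merged["facility_id"], "facility_type")
    recv_type = pd.Series(index=merged.index, dtype=object)
    has_recv = merged["_paired"]
    if has_recv.any():
        recv_type.loc[has_recv] = directory.attribute_for(
            merged.loc[has_recv, "recv_facility_id"], "facility_type"
        )

    age = merged["age"].astype(float)
    riss = merged["riss"].astype(float)
    conditions = {
        "missing_rln": merged["rln"].isna(),
        "age_out_of_18_89": (age < 18) | (age > 89),
        "no_injury_diagnosis": riss.isna(),
        "riss_15_or_less": riss <= 15,
        "burn_injury": merged["burn_flag"].astype(bool),
        "field_triage_to_level_I_II": sending_level.isin(vocab.HIGH_LEVELS),
        "sending_not_low_level_short_term_acute": ~sending_level.isin(vocab.LOW_LEVELS)
        | (sending_type != vocab.SHORT_TERM_ACUTE),
        "excluded_sending_disposition": merged["disposition"].isin(
            vocab.EXCLUDED_SENDING_DISPOSITIONS
        ),
        "interfacility_transfer_gap_over_1_day": merged["_interfacility"],
        "elective_receiving_admission": merged["_paired"]
        & (merged["recv_admission_type"] == vocab.ELECTIVE),
        "receiving_not_short_term_acute": merged["_paired"]
        & (recv_type != vocab.SHORT_TERM_ACUTE),
    }

    alive = pd.Series(True, index=merged.index)
    steps = []
    for rule in EXCLUSION_RULES:
        hit = alive & conditions[rule]
        n_removed = int(hit.sum())
        alive &= ~hit
        steps.append((rule, n_removed, int(alive.sum())))

    kept = merged[alive]
    cohort = kept[kept["_paired"]].drop(columns=["_key", "_paired", "_interfacility"])
    under = kept[~kept["_paired"]].drop(
        columns=["_key", "_paired", "_interfacility"]
        + [c for c in kept.columns if c.startswith("recv_") or c == "gap_days"]
    )
    ledger = ExclusionLedger(steps)
    return cohort.reset_index(drop=True), under.reset_index(drop=True), ledger
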