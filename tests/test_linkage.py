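"""Deduplication, RLN/date pairing, and the exclusion cascade."""

import datetime as dt

import pandas as pd
import pytest

from retriage import linkage
from retriage.synthetic_data import (
    SimulationConfig,
    generate_hospital_directory,
    generate_encounters,
)

from conftest import make_directory, make_encounters


# --- deduplication -----------------------------------------------------------

def test_exact_duplicates_collapse_keeping_first_and_order():
    rows = make_encounters([{"rln": "P1"}, {"rln": "P2"}, {"rln": "P1"}])
    out, n = linkage.deduplicate_records(rows)
    assert n == 1
    assert out["rln"].tolist() == ["P1", "P2"]


def test_rows_differing_in_discharge_date_are_kept():
    rows = make_encounters(
        [{"rln": "P1"}, {"rln": "P1", "discharge_date": dt.date(2018, 5, 2)}]
    )
    out, n = linkage.deduplicate_records(rows)
    assert n == 0 and len(out) == 2


def test_dedup_is_idempotent(clean_dataset):
    ed, _, _ = clean_dataset
    once, n1 = linkage.deduplicate_records(ed)
    twice, n2 = linkage.deduplicate_records(once)
    assert n2 == 0
    pd.testing.assert_frame_equal(once, twice)


# --- pairing -----------------------------------------------------------------

def _pairing_case(recv_admit, recv_fid="B", rln_ip="P1"):
    ed = make_encounters([{"rln": "P1"}])
    ip = make_encounters(
        [
            {
                "rln": rln_ip,
                "facility_id": recv_fid,
                "record_kind": "INPATIENT",
                "admit_date": recv_admit,
                "discharge_date": recv_admit + dt.timedelta(days=3),
            }
        ]
    )
    return linkage.link_encounter_pairs(ed, ip)


def test_next_day_admission_pairs_with_gap_1():
    pairs, inter = _pairing_case(dt.date(2018, 5, 2))
    assert len(pairs) == 1 and len(inter) == 0
    assert pairs["gap_days"].iloc[0] == 1


def test_gap_2_is_interfacility_not_retriage():
    pairs, inter = _pairing_case(dt.date(2018, 5, 3))
    assert len(pairs) == 0 and len(inter) == 1
    assert inter["gap_days"].iloc[0] == 2


def test_different_rlns_never_pair():
    pairs, inter = _pairing_case(dt.date(2018, 5, 2), rln_ip="P9")
    assert len(pairs) == 0 and len(inter) == 0


def test_same_facility_transfer_is_not_a_pair():
    pairs, inter = _pairing_case(dt.date(2018, 5, 2), recv_fid="A")
    assert len(pairs) == 0 and len(inter) == 0


def test_earliest_admission_wins_then_facility_id():
    ed = make_encounters([{"rln": "P1"}])
    ip = make_encounters(
        [
            {"rln": "P1", "facility_id": "C", "record_kind": "INPATIENT",
             "admit_date": dt.date(2018, 5, 2), "discharge_date": dt.date(2018, 5, 4)},
            {"rln": "P1", "facility_id": "B", "record_kind": "INPATIENT",
             "admit_date": dt.date(2018, 5, 1), "discharge_date": dt.date(2018, 5, 4)},
            {"rln": "P1", "facility_id": "D", "record_kind": "INPATIENT",
             "admit_date": dt.date(2018, 5, 1), "discharge_date": dt.date(2018, 5, 5)},
        ]
    )
    pairs, _ = linkage.link_encounter_pairs(ed, ip)
    assert len(pairs) == 1
    assert pairs["recv_facility_id"].iloc[0] == "B"  # same-day tie -> lexicographic


# --- exclusion cascade -------------------------------------------------------

def _cascade(ed_rows, ip_rows=()):
    d = make_directory()
    ed = make_encounters(ed_rows)
    ip = make_encounters(
        [{"record_kind": "INPATIENT", "facility_id": "B",
          "admit_date": dt.date(2018, 5, 2), "discharge_date": dt.date(2018, 5, 5), **r}
         for r in ip_rows]
    )
    return linkage.apply_inclusion_exclusion(ed, ip, d)


def _removed_at(ledger, rule):
    frame = ledger.to_frame().set_index("rule")
    return int(frame.loc[rule, "n_removed"])


@pytest.mark.parametrize(
    "ed_override, rule",
    [
        ({"age": 90}, "age_out_of_18_89"),
        ({"age": 17}, "age_out_of_18_89"),
        ({"riss": 15}, "riss_15_or_less"),
        ({"riss": None}, "no_injury_diagnosis"),
        ({"burn_flag": True}, "burn_injury"),
        ({"facility_id": "D"}, "field_triage_to_level_I_II"),
        ({"disposition": "expired"}, "excluded_sending_disposition"),
        ({"rln": None}, "missing_rln"),
    ],
)
def test_each_rule_fires_and_attributes(ed_override, rule):
    _, _, ledger = _cascade([{**ed_override}], [{"rln": "P1"}])
    assert _removed_at(ledger, rule) == 1
    assert ledger.final_remaining == 0


def test_riss_16_passes_strict_threshold():
    cohort, _, _ = _cascade([{"riss": 16}], [{"rln": "P1"}])
    assert len(cohort) == 1


def test_rehab_receiving_facility_excluded():
    _, _, ledger = _cascade([{}], [{"rln": "P1", "facility_id": "R"}])
    assert _removed_at(ledger, "receiving_not_short_term_acute") == 1


def test_elective_receiving_admission_excluded():
    _, _, ledger = _cascade([{}], [{"rln": "P1", "admission_type": "ELECTIVE"}])
    assert _removed_at(ledger, "elective_receiving_admission") == 1


def test_unknown_sending_facility_raises():
    d = make_directory()
    ed = make_encounters([{"facility_id": "ZZZ"}])
    with pytest.raises(KeyError, match="ZZZ"):
        linkage.apply_inclusion_exclusion(ed, ed.iloc[:0], d)


def test_unpaired_qualifying_encounter_lands_in_under_triaged():
    cohort, under, ledger = _cascade([{"disposition": "admitted-or-home"}])
    assert len(cohort) == 0 and len(under) == 1
    assert ledger.total_removed == 0


# --- partition and recovery on generated data --------------------------------

def test_partition_and_ledger_conservation(clean_dataset, clean_directory, clean_cohort):
    ed, _, _ = clean_dataset
    ed, _ = linkage.deduplicate_records(ed)
    pairs, under, ledger = clean_cohort
    assert ledger.total_removed + len(pairs) + len(under) == len(ed)
    frame = ledger.to_frame()
    assert frame["n_remaining"].is_monotonic_decreasing
    assert frame["n_remaining"].iloc[-1] == len(pairs) + len(under)


def test_full_recovery_without_missing_rlns(clean_dataset, clean_cohort):
    _, _, truth = clean_dataset
    pairs, _, _ = clean_cohort
    want = truth[truth["is_retriage_pair"]]
    got = set(zip(pairs["rln"], pairs["recv_facility_id"]))
    assert got == set(zip(want["rln"], want["receiving_facility_id"]))


def test_recovered_pairs_decrease_with_missing_rln():
    counts = []
    for p in (0.0, 0.1, 0.25):
        cfg = SimulationConfig(n_patients=4000, seed=17, p_missing_rln=p)
        d = generate_hospital_directory(cfg)
        ed, ip, _ = generate_encounters(cfg, d)
        ed, _ = linkage.deduplicate_records(ed)
        ip, _ = linkage.deduplicate_records(ip)
        pairs, _, _ = linkage.apply_inclusion_exclusion(ed, ip, d)
        counts.append(len(pairs))
    assert counts[0] > counts[1] > counts[2]
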