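"""Optimality labeling, covariate coding, and hierarchical rate tables."""

import numpy as np
import pandas as pd
import pytest

from retriage import cohort, vocab
from retriage.synthetic_data import (
    SimulationConfig,
    generate_hospital_directory,
    generate_encounters,
)
from retriage import linkage

from conftest import make_directory, make_encounters


def _pairs(rows):
    base = {
        "recv_facility_id": "B",
        "recv_admission_type": "EMERGENT",
        "gap_days": 1,
    }
    return make_encounters([{**base, **r} for r in rows])


# --- labeling ----------------------------------------------------------------

@pytest.mark.parametrize(
    "sending, receiving, expected",
    [
        ("A", "B", "OPTIMAL"),      # nontrauma -> level II
        ("C", "E", "SUBOPTIMAL"),   # level III -> level IV
        ("C", "D", "OPTIMAL"),      # level III -> distant level I: distance ignored
        ("A", "C", "SUBOPTIMAL"),   # nontrauma -> level III
    ],
)
def test_label_optimality(sending, receiving, expected):
    d = make_directory()
    ev = cohort.label_optimality(
        _pairs([{"facility_id": sending, "recv_facility_id": receiving}]), d
    )
    assert ev["optimality"].iloc[0] == expected


def test_label_uses_that_years_designation():
    d = make_directory()
    # facility C is LEVEL_III every year in the tiny directory: rebuild with a switch
    recs = [
        dict(facility_id="A", level="NONTRAUMA"),
        dict(facility_id="C", level="LEVEL_III"),
    ]
    d = make_directory(recs)
    d.levels.loc[(d.levels["facility_id"] == "C") & (d.levels["year"] >= 2015), "level"] = "LEVEL_II"
    d = type(d)(d.facilities, d.levels)
    for year, expected in [(2014, "SUBOPTIMAL"), (2015, "OPTIMAL")]:
        ev = cohort.label_optimality(
            _pairs([{"facility_id": "A", "recv_facility_id": "C", "year": year}]), d
        )
        assert ev["optimality"].iloc[0] == expected


# --- covariate coding --------------------------------------------------------

@pytest.mark.parametrize(
    "age, band", [(18, "18-24"), (24, "18-24"), (25, "25-34"), (84, "75-84"), (85, "85-89"), (89, "85-89")]
)
def test_age_bands(age, band):
    assert vocab.age_band(age) == band


@pytest.mark.parametrize("riss, band", [(16, "16-25"), (25, "16-25"), (26, ">25")])
def test_riss_bands(riss, band):
    assert vocab.riss_band(riss) == band


def test_managed_care_unspecified_kept_distinct():
    d = make_directory()
    ev = cohort.label_optimality(
        _pairs([{"insurance": "HMO-unspecified"}, {"insurance": "hmo"}]), d
    )
    out = cohort.encode_covariates(ev)
    assert out["insurance"].tolist() == ["MANAGED_CARE_UNSPECIFIED", "PRIVATE"]


def test_unmapped_code_raises_listing_it():
    d = make_directory()
    ev = cohort.label_optimality(_pairs([{"insurance": "zorp"}]), d)
    with pytest.raises(ValueError, match="zorp"):
        cohort.encode_covariates(ev)


def test_body_region_precedence():
    assert cohort.resolve_body_region({"TBI": True, "TORSO": True}) == "TBI"
    assert cohort.resolve_body_region({"EXTREMITIES": True, "TORSO": True}) == "TORSO"
    assert cohort.resolve_body_region({}) == "OTHER"


# --- aggregation -------------------------------------------------------------

def _labeled_events(n_sub, n_opt, rtcc="SOUTH_WEST", year=2018, fid="A"):
    rows = [{"facility_id": fid, "recv_facility_id": "C", "year": year}] * n_sub
    rows += [{"facility_id": fid, "recv_facility_id": "B", "year": year}] * n_opt
    d = make_directory()
    ev = cohort.label_optimality(_pairs(rows), d)
    return ev, d


def test_state_rate_and_zero_suboptimal_unit():
    ev, d = _labeled_events(3, 7)
    table = cohort.aggregate_rates(ev, d, "STATE")
    pooled = table[table["year"] == "ALL"].iloc[0]
    assert pooled["n_retriage"] == 10 and pooled["n_suboptimal"] == 3
    assert pooled["rate"] == pytest.approx(0.3)
    ev0, d0 = _labeled_events(0, 10)
    t0 = cohort.aggregate_rates(ev0, d0, "STATE")
    assert t0[t0["year"] == "ALL"]["rate"].iloc[0] == 0.0


def test_units_with_no_events_are_absent_not_zero(clean_events, clean_directory):
    table = cohort.aggregate_rates(clean_events, clean_directory, "CENTER")
    assert table["n_retriage"].min() >= 1
    assert table["rate"].notna().all()


def test_shares_sum_to_one_and_rollup(clean_events, clean_directory):
    for level in ("RTCC", "LEMSA", "CENTER"):
        table = cohort.aggregate_rates(clean_events, clean_directory, level)
        pooled = table[table["year"] == "ALL"]
        assert pooled["share_of_state_suboptimal"].sum() == pytest.approx(1.0, abs=1e-9)
        state = cohort.aggregate_rates(clean_events, clean_directory, "STATE")
        assert pooled["n_suboptimal"].sum() == state[state["year"] == "ALL"]["n_suboptimal"].iloc[0]
        assert pooled["n_retriage"].sum() == len(clean_events)


def test_rate_tables_invariant_to_input_order(clean_events, clean_directory):
    shuffled = clean_events.sample(frac=1.0, random_state=3)
    t1 = cohort.aggregate_rates(clean_events, clean_directory, "RTCC")
    t2 = cohort.aggregate_rates(shuffled, clean_directory, "RTCC")
    pd.testing.assert_frame_equal(
        t1.reset_index(drop=True), t2.reset_index(drop=True)
    )


def test_annual_trend_shares_and_sign():
    # construct events with a rate rising 10% -> 60% over six years
    d = make_directory()
    frames = []
    for i, year in enumerate(range(2012, 2018)):
        n_sub = 2 + 2 * i
        frames.append(_pairs(
            [{"facility_id": "A", "recv_facility_id": "C", "year": year}] * n_sub
            + [{"facility_id": "A", "recv_facility_id": "B", "year": year}] * (20 - n_sub)
        ))
    ev = cohort.label_optimality(pd.concat(frames, ignore_index=True), d)
    trend = cohort.annual_trend(ev)
    per_year = trend.drop_duplicates("year")
    slope = np.polyfit(per_year["year"], per_year["state_rate"], 1)[0]
    assert slope > 0
    shares = trend.groupby("year")["rtcc_share_of_suboptimal"].sum()
    assert np.allclose(shares, 1.0)


def test_center_summary_fractions():
    d = make_directory()
    # centers A and C are sending-eligible low-level STA; only A has events
    rows = [{"facility_id": "A", "recv_facility_id": "C"}] * 4  # 4 suboptimal
    rows += [{"facility_id": "A", "recv_facility_id": "B"}] * 6  # 6 optimal
    ev = cohort.label_optimality(_pairs(rows), d)
    _, summary = cohort.center_level_summary(ev, d)
    pooled = summary[summary["year"] == "ALL"].iloc[0]
    # eligible low-level STA centers in the tiny directory: A, C, E
    assert pooled["n_eligible_centers"] == 3
    assert pooled["frac_with_any_suboptimal"] == pytest.approx(1 / 3)
    # 4/10 = 40% hits the inclusive >=40% threshold
    assert pooled["frac_sending_40pct_suboptimal"] == pytest.approx(1.0)


def test_all_optimal_gives_zero_center_fractions():
    d = make_directory()
    ev = cohort.label_optimality(
        _pairs([{"facility_id": "A", "recv_facility_id": "B"}] * 5), d
    )
    _, summary = cohort.center_level_summary(ev, d)
    pooled = summary[summary["year"] == "ALL"].iloc[0]
    assert pooled["frac_with_any_suboptimal"] == 0.0


def test_table_one_uses_stratum_denominators(clean_events):
    t1 = cohort.table_one(clean_events)
    total = t1[t1["variable"] == "total"].iloc[0]
    sex = t1[t1["variable"] == "sex"]
    assert sex["n_retriage"].sum() == total["n_retriage"]
    female = sex[sex["level"] == "FEMALE"].iloc[0]
    assert female["pct_suboptimal"] == pytest.approx(
        100 * female["n_suboptimal"] / total["n_suboptimal"]
    )


def test_rate_recovery_uniform_p(clean_directory):
    cfg = SimulationConfig(
        n_patients=8000, seed=23, p_missing_rln=0.0,
        p_suboptimal_given_retriage=0.30,
    )
    d = generate_hospital_directory(cfg)
    ed, ip, _ = generate_encounters(cfg, d)
    ed, _ = linkage.deduplicate_records(ed)
    ip, _ = linkage.deduplicate_records(ip)
    pairs, _, _ = linkage.apply_inclusion_exclusion(ed, ip, d)
    ev = cohort.label_optimality(pairs, d)
    rate = (ev["optimality"] == "SUBOPTIMAL").mean()
    se = np.sqrt(0.3 * 0.7 / len(ev))
    assert abs(rate - 0.30) < 3 * se
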