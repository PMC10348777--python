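"""Synthetic administrative discharge data with known re-triage ground truth.

Emulates the structure of statewide ED and inpatient discharge records:
pseudonymous record-linkage numbers (RLN), date-only stamps, coded
dispositions, demographic/insurance/mechanism covariates, a precomputed
injury-severity field, duplicate rows, and a configurable fraction of missing
RLNs. Every patient's true trajectory (re-triaged or not, optimal or
suboptimal receiving level, which exclusion rule applies) is recorded in a
ground-truth table so the linkage, labeling, modelling and optimization
stages can all be verified against a known answer.

Suboptimality is assigned on the logit scale: a per-region baseline
probability, plus configurable covariate log-odds effects, plus Gaussian
random intercepts for sending center and year.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import vocab
from .hospitals import HospitalDirectory

ENCOUNTER_COLUMNS = [
    "rln",
    "facility_id",
    "record_kind",
    "admit_date",
    "discharge_date",
    "disposition",
    "admission_type",
    "age",
    "sex",
    "race",
    "ethnicity",
    "insurance",
    "riss",
    "mechanism",
    "body_region",
    "burn_flag",
    "year",
]

# Default suboptimality baselines per region: urban regions high, the rural
# central region low — the geographic gradient the analysis is designed to
# detect.
DEFAULT_P_SUBOPTIMAL = {
    "NORTH": 0.22,
    "BAY_AREA": 0.375,
    "CENTRAL": 0.104,
    "SOUTH_EAST": 0.202,
    "SOUTH_WEST": 0.688,
}

# Marginal frequencies of the analysis covariates (raw codes). Chosen as
# plausible for a seriously-injured, predominantly elderly transfer
# population; no claim of demographic fidelity is made.
COVARIATE_MARGINALS = {
    "age_band": (vocab.AGE_BANDS, [0.047, 0.059, 0.060, 0.091, 0.141, 0.167, 0.240, 0.195]),
    "sex": (("MALE", "FEMALE"), [0.592, 0.408]),
    "race_raw": (
        ("white", "black", "asian", "other", "unknown"),
        [0.743, 0.046, 0.070, 0.100, 0.041],
    ),
    "ethnicity_raw": (("hispanic", "non-hispanic"), [0.216, 0.784]),
    "insurance_raw": (
        (
            "self-pay",
            "blue-cross-blue-shield",
            "commercial",
            "medicare",
            "medi-cal",
            "federal",
            "hmo-unspecified",
            "other",
        ),
        [0.071, 0.032, 0.042, 0.576, 0.111, 0.010, 0.131, 0.027],
    ),
    "mechanism_raw": (
        ("mvc", "fall", "struck", "other", "unspecified"),
        [0.152, 0.643, 0.057, 0.108, 0.040],
    ),
    "body_region": (vocab.BODY_REGIONS, [0.046, 0.878, 0.029, 0.020, 0.027]),
}

AGE_BAND_RANGES = {
    "18-24": (18, 24), "25-34": (25, 34), "35-44": (35, 44), "45-54": (45, 54),
    "55-64": (55, 64), "65-74": (65, 74), "75-84": (75, 84), "85-89": (85, 89),
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study population.

    The probabilities describe the generative cascade: a patient presents to
    a low-level center (vs directly to a level I/II center), is re-triaged
    within the 1-day window with probability ``p_retriage_within_1day``, and
    the receiving center is low-level (suboptimal) with a probability driven
    by ``p_suboptimal_given_retriage`` on the logit scale. Edge-case rates
    inject records that must be caught by each exclusion rule. The seed fully
    determines the output.
    """

    n_patients: int = 20_000
    year_start: int = 2009
    year_end: int = 2018
    # facilities per level per region; nonacute facilities give the
    # rehab/psych/long-term exclusion path somewhere to point
    hospitals_per_rtcc: dict = field(
        default_factory=lambda: {
            vocab.NONTRAUMA: 8,
            vocab.LEVEL_I: 1,
            vocab.LEVEL_II: 2,
            vocab.LEVEL_III: 2,
            vocab.LEVEL_IV: 1,
        }
    )
    nonacute_per_rtcc: int = 2
    lemsas_per_rtcc: int = 4
    level_changes: list = field(default_factory=list)  # (facility_id, year, new_level)

    p_undertriage_to_low: float = 0.8
    p_retriage_within_1day: float = 0.206
    p_suboptimal_given_retriage: dict | float = field(
        default_factory=lambda: dict(DEFAULT_P_SUBOPTIMAL)
    )
    p_missing_rln: float = 0.25
    p_duplicate: float = 0.05

    # edge-case injection rates (each fires one exclusion rule downstream)
    p_age_out_of_range: float = 0.02
    p_no_injury: float = 0.01
    p_minor_injury: float = 0.04
    p_burn: float = 0.01
    p_interfacility: float = 0.05
    p_nonacute_receiving: float = 0.02
    p_elective_admission: float = 0.02
    p_excluded_disposition: float = 0.02

    # hospital-course generation at the receiving center
    mean_los_days: float = 4.0
    p_readmission: float = 0.15
    surgery_class_probs: dict = field(
        default_factory=lambda: {
            "NONE": 0.72, "MINOR_THERAPEUTIC": 0.14,
            "MAJOR_THERAPEUTIC": 0.10, "DIAGNOSTIC": 0.04,
        }
    )
    receiving_disposition_probs: dict = field(
        default_factory=lambda: {
            "home": 0.55, "snf": 0.25, "rehab": 0.08, "hospice": 0.02,
            "expired": 0.05, "transfer to short-term general hospital": 0.05,
        }
    )

    # suboptimality model used for ground-truth assignment
    covariate_effects: dict = field(default_factory=dict)  # factor -> level -> log-odds
    center_sigma: float = 0.0
    year_sigma: float = 0.0

    covariate_marginals: dict = field(default_factory=lambda: dict(COVARIATE_MARGINALS))
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [
            self.p_undertriage_to_low, self.p_retriage_within_1day, self.p_missing_rln,
            self.p_duplicate, self.p_age_out_of_range, self.p_no_injury,
            self.p_minor_injury, self.p_burn, self.p_interfacility,
            self.p_nonacute_receiving, self.p_elective_admission,
            self.p_excluded_disposition, self.p_readmission,
        ]
        sub = self.p_suboptimal_given_retriage
        probs += list(sub.values()) if isinstance(sub, dict) else [sub]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.center_sigma < 0 or self.year_sigma < 0:
            raise ValueError("random-intercept sigmas must be nonnegative")
        if self.year_end < self.year_start:
            raise ValueError("year_end precedes year_start")
        for factor, levels in self.covariate_effects.items():
            if factor not in vocab.FACTOR_LEVELS:
                raise ValueError(f"unknown covariate factor {factor!r}")
            bad = set(levels) - set(vocab.FACTOR_LEVELS[factor])
            if bad:
                raise ValueError(f"unknown levels for {factor!r}: {sorted(bad)}")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    def p_suboptimal_for(self, rtcc: str) -> float:
        sub = self.p_suboptimal_given_retriage
        return float(sub[rtcc]) if isinstance(sub, dict) else float(sub)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# --------------------------------------------------------------------------
# hospital directory generation
# --------------------------------------------------------------------------

def generate_hospital_directory(config: SimulationConfig) -> HospitalDirectory:
    """Place the configured number of facilities per level inside each
    region's bounding box, assign LEMSA membership, and give every facility a
    trauma-level designation for every year of the horizon (with any
    configured mid-horizon level changes applied from their year onward)."""
    rng = np.random.default_rng(config.seed)
    years = list(config.years)
    records = []
    counter = 0
    for rtcc in vocab.RTCCS:
        lat0, lat1, lon0, lon1 = vocab.RTCC_BOUNDING_BOXES[rtcc]
        lemsas = [f"{rtcc}-L{j + 1}" for j in range(config.lemsas_per_rtcc)]
        plan = [(lvl, vocab.SHORT_TERM_ACUTE, n) for lvl, n in config.hospitals_per_rtcc.items()]
        plan.append((vocab.NONTRAUMA, vocab.REHAB, config.nonacute_per_rtcc))
        for level, ftype, n in plan:
            for _ in range(n):
                counter += 1
                fid = f"H{counter:04d}"
                records.append(
                    {
                        "facility_id": fid,
                        "name": f"{rtcc.title().replace('_', ' ')} {ftype.title()} {counter}",
                        "latitude": float(rng.uniform(lat0, lat1)),
                        "longitude": float(rng.uniform(lon0, lon1)),
                        "facility_type": ftype,
                        "lemsa_id": lemsas[int(rng.integers(len(lemsas)))],
                        "rtcc_id": rtcc,
                        "level_by_year": {y: level for y in years},
                    }
                )
    by_id = {r["facility_id"]: r for r in records}
    for fid, change_year, new_level in config.level_changes:
        if fid not in by_id:
            raise ValueError(f"level change references unknown facility {fid!r}")
        for y in years:
            if y >= change_year:
                by_id[fid]["level_by_year"][y] = new_level
    return HospitalDirectory.from_records(records)


# --------------------------------------------------------------------------
# encounter generation
# --------------------------------------------------------------------------

def _draw(rng, values, probs, n):
    probs = np.asarray(probs, dtype=float)
    return rng.choice(np.asarray(values, dtype=object), size=n, p=probs / probs.sum())


def _random_dates(rng, years, n) -> np.ndarray:
    """Uniform admission dates, leaving headroom before year-end so the 1-day
    window never crosses the horizon."""
    year = rng.choice(np.asarray(years), size=n)
    day = rng.integers(0, 360, size=n)
    return np.array(
        [dt.date(int(y), 1, 1) + dt.timedelta(days=int(d)) for y, d in zip(year, day)],
        dtype=object,
    )


def generate_encounters(
    config: SimulationConfig, directory: HospitalDirectory
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate patients through presentation, re-triage, and hospital course.

    Returns ``(ed_records, inpatient_records, truth)``. The truth table has
    one row per patient with the scenario drawn for them, whether they form a
    true re-triage pair, and the true optimality of that pair.
    """
    if directory.facilities.empty:
        raise ValueError("hospital directory is empty")
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_patients
    years = list(config.years)

    fac = directory.facilities
    sta = fac[fac["facility_type"] == vocab.SHORT_TERM_ACUTE]
    nonacute_ids = fac.loc[fac["facility_type"] != vocab.SHORT_TERM_ACUTE, "facility_id"].to_numpy()

    # per-year pools of low-level and high-level short-term acute centers
    lvl = directory.levels.merge(
        fac[["facility_id", "rtcc_id", "facility_type"]], on="facility_id"
    )
    lvl = lvl[lvl["facility_type"] == vocab.SHORT_TERM_ACUTE]
    low_pool = {
        (y, r): g["facility_id"].to_numpy()
        for (y, r), g in lvl[lvl["level"].isin(vocab.LOW_LEVELS)].groupby(["year", "rtcc_id"])
    }
    high_pool = {
        (y, r): g["facility_id"].to_numpy()
        for (y, r), g in lvl[lvl["level"].isin(vocab.HIGH_LEVELS)].groupby(["year", "rtcc_id"])
    }
    high_pool_any = {
        y: g["facility_id"].to_numpy()
        for y, g in lvl[lvl["level"].isin(vocab.HIGH_LEVELS)].groupby("year")
    }
    fac_rtcc = dict(zip(fac["facility_id"], fac["rtcc_id"]))

    # ---- covariates ----------------------------------------------------------
    m = config.covariate_marginals
    band = _draw(rng, *m["age_band"], n)
    age = np.array(
        [int(rng.integers(AGE_BAND_RANGES[b][0], AGE_BAND_RANGES[b][1] + 1)) for b in band]
    )
    sex = _draw(rng, *m["sex"], n)
    race_raw = _draw(rng, *m["race_raw"], n)
    ethnicity_raw = _draw(rng, *m["ethnicity_raw"], n)
    insurance_raw = _draw(rng, *m["insurance_raw"], n)
    mechanism_raw = _draw(rng, *m["mechanism_raw"], n)
    body_region = _draw(rng, *m["body_region"], n)
    riss = np.where(rng.random(n) < 0.919, rng.integers(16, 26, n), rng.integers(26, 46, n))
    riss = riss.astype(float)
    burn = np.zeros(n, dtype=bool)

    # ---- edge-case mutations -------------------------------------------------
    scenario = np.full(n, "ELIGIBLE", dtype=object)

    def mutate(p, name):
        mask = (scenario == "ELIGIBLE") & (rng.random(n) < p)
        scenario[mask] = name
        return mask

    age_out = mutate(config.p_age_out_of_range, "AGE_OUT_OF_RANGE")
    if age_out.any():
        k = int(age_out.sum())
        age[age_out] = np.where(rng.random(k) < 0.5, rng.integers(1, 18, k), rng.integers(90, 100, k))
    no_injury = mutate(config.p_no_injury, "NO_INJURY")
    riss[no_injury] = np.nan
    minor = mutate(config.p_minor_injury, "MINOR_INJURY")
    riss[minor] = rng.integers(1, 16, int(minor.sum()))
    burn_mask = mutate(config.p_burn, "BURN")
    burn[burn_mask] = True

    # ---- presentation --------------------------------------------------------
    to_low = rng.random(n) < config.p_undertriage_to_low
    scenario[~to_low & (scenario == "ELIGIBLE")] = "DIRECT_TO_HIGH_LEVEL"

    sending = np.empty(n, dtype=object)
    admit = _random_dates(rng, years, n)
    year = np.array([d.year for d in admit])
    rtcc = np.empty(n, dtype=object)
    for i in range(n):
        y = year[i]
        r = vocab.RTCCS[int(rng.integers(len(vocab.RTCCS)))]
        pool = low_pool.get((y, r)) if to_low[i] else high_pool.get((y, r))
        if pool is None or len(pool) == 0:
            pool = np.concatenate(
                [v for (yy, _), v in (low_pool if to_low[i] else high_pool).items() if yy == y]
                or [sta["facility_id"].to_numpy()]
            )
        sending[i] = pool[int(rng.integers(len(pool)))]
        rtcc[i] = fac_rtcc[sending[i]]

    # ---- transfer decision ---------------------------------------------------
    eligible = scenario == "ELIGIBLE"
    transferred = eligible & (rng.random(n) < config.p_retriage_within_1day)
    scenario[eligible & ~transferred] = "NOT_TRANSFERRED"

    # receiving-side edge cases among transferred patients
    def mutate_t(p, name):
        mask = (scenario == "ELIGIBLE") & transferred & (rng.random(n) < p)
        scenario[mask] = name
        return mask

    interfac = mutate_t(config.p_interfacility, "INTERFACILITY")
    nonacute = mutate_t(config.p_nonacute_receiving, "NONACUTE_RECEIVING")
    elective = mutate_t(config.p_elective_admission, "ELECTIVE_ADMISSION")
    bad_dispo = mutate_t(config.p_excluded_disposition, "EXCLUDED_DISPOSITION")
    retriage = (scenario == "ELIGIBLE") & transferred
    scenario[retriage] = "RETRIAGE"
    any_transfer = transferred  # all transferred variants emit a receiving record

    # ---- true suboptimality on the logit scale -------------------------------
    baseline = np.array([config.p_suboptimal_for(r) for r in rtcc])
    baseline = np.clip(baseline, 1e-9, 1 - 1e-9)
    eta = np.log(baseline / (1 - baseline))
    covs = {
        "age_band": band, "sex": sex, "body_region": body_region,
        "race": np.array([vocab.RACE_CODE_MAP[c] for c in race_raw], dtype=object),
        "ethnicity": np.array([vocab.ETHNICITY_CODE_MAP[c] for c in ethnicity_raw], dtype=object),
        "insurance": np.array([vocab.INSURANCE_CODE_MAP[c] for c in insurance_raw], dtype=object),
        "mechanism": np.array([vocab.MECHANISM_CODE_MAP[c] for c in mechanism_raw], dtype=object),
        "riss_band": np.array(
            ["16-25" if (np.isnan(v) or v <= 25) else ">25" for v in riss], dtype=object
        ),
        "rtcc_id": rtcc,
    }
    for factor, levels in config.covariate_effects.items():
        for level, beta in levels.items():
            eta = eta + beta * (covs[factor] == level)
    center_ids = sorted(set(sending))
    center_re = dict(zip(center_ids, rng.normal(0.0, config.center_sigma, len(center_ids))))
    year_re = dict(zip(years, rng.normal(0.0, config.year_sigma, len(years))))
    eta = eta + np.array([center_re[s] for s in sending]) + np.array([year_re[y] for y in year])
    true_subopt = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))

    # ---- receiving facility + dates ------------------------------------------
    receiving = np.full(n, None, dtype=object)
    gap = np.full(n, -1)
    for i in np.flatnonzero(any_transfer):
        y = year[i]
        if nonacute[i]:
            pool = nonacute_ids
        elif true_subopt[i]:
            pool = low_pool.get((y, rtcc[i]), np.array([], dtype=object))
            pool = pool[pool != sending[i]]
            if len(pool) == 0:
                pool = np.concatenate(
                    [v for (yy, _), v in low_pool.items() if yy == y] or [np.array([])]
                )
                pool = pool[pool != sending[i]]
        else:
            pool = high_pool.get((y, rtcc[i]), np.array([], dtype=object))
            if len(pool) == 0:
                pool = high_pool_any.get(y, np.array([], dtype=object))
        if len(pool) == 0:  # no receiving candidate exists: patient stays put
            scenario[i] = "NOT_TRANSFERRED"
            any_transfer[i] = False
            continue
        receiving[i] = pool[int(rng.integers(len(pool)))]
        gap[i] = int(rng.integers(2, 6)) if interfac[i] else int(rng.integers(0, 2))

    ed_discharge = admit.copy()  # ED stays are same-day; dates are date-only
    recv_admit = np.array(
        [d + dt.timedelta(days=int(g)) if g >= 0 else None for d, g in zip(ed_discharge, gap)],
        dtype=object,
    )
    los = rng.poisson(config.mean_los_days, n)
    recv_discharge = np.array(
        [a + dt.timedelta(days=int(l)) if a is not None else None for a, l in zip(recv_admit, los)],
        dtype=object,
    )

    # ---- identifiers ---------------------------------------------------------
    rln = np.array([f"P{i:07d}" for i in range(n)], dtype=object)
    rln_ed = rln.copy()
    rln_ed[rng.random(n) < config.p_missing_rln] = None

    # ---- assemble ED records -------------------------------------------------
    ed_dispo = np.where(any_transfer, "acute-transfer", "admitted-or-home")
    if bad_dispo.any():
        choices = np.array(sorted(vocab.EXCLUDED_SENDING_DISPOSITIONS), dtype=object)
        ed_dispo = ed_dispo.astype(object)
        ed_dispo[bad_dispo] = rng.choice(choices, size=int(bad_dispo.sum()))

    def frame(mask, kind, fid, a, d, dispo, adm_type, rlns):
        idx = np.flatnonzero(mask)
        return pd.DataFrame(
            {
                "rln": rlns[idx],
                "facility_id": fid[idx],
                "record_kind": kind,
                "admit_date": a[idx],
                "discharge_date": d[idx],
                "disposition": np.asarray(dispo, dtype=object)[idx]
                if not np.isscalar(dispo) else dispo,
                "admission_type": np.asarray(adm_type, dtype=object)[idx]
                if not np.isscalar(adm_type) else adm_type,
                "age": age[idx],
                "sex": sex[idx],
                "race": race_raw[idx],
                "ethnicity": ethnicity_raw[idx],
                "insurance": insurance_raw[idx],
                "riss": riss[idx],
                "mechanism": mechanism_raw[idx],
                "body_region": body_region[idx],
                "burn_flag": burn[idx],
                "year": year[idx],
                "patient_id": idx,
            }
        )

    ed = frame(
        np.ones(n, dtype=bool), vocab.ED, sending, admit, ed_discharge,
        ed_dispo, vocab.EMERGENT, rln_ed,
    )

    # ---- receiving inpatient records -----------------------------------------
    recv_dispo_vals, recv_dispo_p = zip(*config.receiving_disposition_probs.items())
    recv_dispo = _draw(rng, recv_dispo_vals, recv_dispo_p, n)
    recv_adm_type = np.where(elective, vocab.ELECTIVE, vocab.EMERGENT).astype(object)
    recv_year = np.array([a.year if a is not None else -1 for a in recv_admit])
    ip = frame(
        any_transfer, vocab.INPATIENT,
        np.array([r if r is not None else "" for r in receiving], dtype=object),
        recv_admit, recv_discharge, recv_dispo, recv_adm_type, rln,
    )
    ip["year"] = recv_year[ip["patient_id"].to_numpy()]

    # ---- readmission records (exercise the 10/30/60-day windows) -------------
    readmit_mask = any_transfer & (recv_dispo != "expired") & (rng.random(n) < config.p_readmission)
    re_rows = []
    for i in np.flatnonzero(readmit_mask):
        g = int(rng.integers(1, 71))
        a = recv_discharge[i] + dt.timedelta(days=g)
        pool = sta["facility_id"].to_numpy()
        fid2 = pool[int(rng.integers(len(pool)))]
        re_rows.append((rln[i], fid2, a, a + dt.timedelta(days=int(rng.poisson(3))), i))
    if re_rows:
        re_df = pd.DataFrame(
            re_rows, columns=["rln", "facility_id", "admit_date", "discharge_date", "patient_id"]
        )
        re_df["record_kind"] = vocab.INPATIENT
        re_df["disposition"] = "home"
        re_df["admission_type"] = vocab.EMERGENT
        pid = re_df["patient_id"].to_numpy()
        re_df["age"] = age[pid]
        re_df["sex"] = sex[pid]
        re_df["race"] = race_raw[pid]
        re_df["ethnicity"] = ethnicity_raw[pid]
        re_df["insurance"] = insurance_raw[pid]
        re_df["riss"] = riss[pid]
        re_df["mechanism"] = mechanism_raw[pid]
        re_df["body_region"] = body_region[pid]
        re_df["burn_flag"] = burn[pid]
        re_df["year"] = [a.year for a in re_df["admit_date"]]
        ip = pd.concat([ip, re_df[list(ip.columns)]], ignore_index=True)

    # surgery class assigned directly (procedure-code classification is out of
    # scope); carried on the receiving record
    surg_vals, surg_p = zip(*config.surgery_class_probs.items())
    ip["surgery_class"] = _draw(rng, surg_vals, surg_p, len(ip))

    # ---- duplicates ----------------------------------------------------------
    def inject_duplicates(df):
        dup = df[rng.random(len(df)) < config.p_duplicate]
        out = pd.concat([df, dup], ignore_index=True)
        return out.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)

    ed = inject_duplicates(ed)
    ip = inject_duplicates(ip)

    # ---- ground truth --------------------------------------------------------
    is_pair = scenario == "RETRIAGE"
    truth = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "rln": rln,
            "rln_on_ed_record": rln_ed,
            "scenario": scenario,
            "year": year,
            "rtcc_id": rtcc,
            "sending_facility_id": sending,
            "receiving_facility_id": receiving,
            "gap_days": gap,
            "is_retriage_pair": is_pair,
            "true_suboptimal": np.where(is_pair, true_subopt, None),
        }
    )
    return ed, ip, truth


def write_dataset(config, directory, ed, ip, truth, outdir) -> dict:
    """Write the four CSVs plus a data dictionary; returns the path manifest."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "hospitals": os.path.join(outdir, "hospitals.csv"),
        "ed": os.path.join(outdir, "ed_encounters.csv"),
        "inpatient": os.path.join(outdir, "inpatient_encounters.csv"),
        "truth": os.path.join(outdir, "ground_truth.csv"),
        "dictionary": os.path.join(outdir, "data_dictionary.md"),
    }
    directory.to_csv(paths["hospitals"])
    ed.to_csv(paths["ed"], index=False)
    ip.to_csv(paths["inpatient"], index=False)
    truth.to_csv(paths["truth"], index=False)
    with open(paths["dictionary"], "w") as fh:
        fh.write(DATA_DICTIONARY)
    return paths


DATA_DICTIONARY = """\
# Data dictionary

## hospitals.csv (one row per facility-year)
facility_id, name, latitude, longitude (WGS84), facility_type
(SHORT_TERM_ACUTE/REHAB/PSYCH/LONG_TERM/OTHER), lemsa_id, rtcc_id,
year, level (NONTRAUMA/LEVEL_I..LEVEL_IV; annual designation).

## ed_encounters.csv / inpatient_encounters.csv
rln (pseudonymous patient identifier; blank = missing), facility_id,
record_kind (ED/INPATIENT), admit_date, discharge_date (ISO-8601, date only),
disposition (coded string), admission_type (EMERGENT/ELECTIVE/OTHER),
age (years), sex, race, ethnicity, insurance, mechanism (raw codes),
riss (injury severity score; blank = no injury diagnosis), body_region,
burn_flag, year (= year of admit_date), patient_id (simulation bookkeeping),
surgery_class (inpatient only; pre-classified procedure class).

## ground_truth.csv (one row per simulated patient)
patient_id, rln, rln_on_ed_record, scenario, year, rtcc_id,
sending_facility_id, receiving_facility_id, gap_days,
is_retriage_pair (true cohort membership), true_suboptimal.
"""
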