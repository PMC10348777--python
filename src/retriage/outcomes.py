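"""Hospital course at the receiving center and suboptimal-vs-optimal contrasts.

Covers the descriptive outcome battery: the four-way collapse of receiving
discharge dispositions, length of stay, readmission within 10/30/60 days of
discharge (survivors only, identified through RLN-wide linkage), crude 2x2
odds ratios with Woolf intervals, Pearson chi-square contrasts, and the
region-by-surgery-class rate table.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from . import vocab
from .cohort import SUBOPTIMAL

READMISSION_WINDOWS = (10, 30, 60)


def collapse_disposition(raw_code: str, mapping: dict | None = None) -> str:
    """Collapse a raw receiving-disposition code into one of four groups:
    HOME, DIED, SHORT_TERM_ACUTE, POST_ACUTE."""
    mapping = vocab.DISPOSITION_GROUP_MAP if mapping is None else mapping
    key = str(raw_code).lower()
    if key not in mapping:
        raise ValueError(f"unmapped disposition code {raw_code!r}")
    return mapping[key]


def compute_los(admit_date, discharge_date) -> int:
    """Length of stay in whole days; same-day discharge is 0."""
    a, d = pd.Timestamp(admit_date), pd.Timestamp(discharge_date)
    los = (d - a).days
    if los < 0:
        raise ValueError(f"discharge {discharge_date} precedes admission {admit_date}")
    return int(los)


def attach_hospital_course(events: pd.DataFrame, mapping: dict | None = None) -> pd.DataFrame:
    """Add disposition_group and los_days from the receiving-side columns."""
    out = events.copy()
    out["disposition_group"] = [
        collapse_disposition(c, mapping) for c in out["recv_disposition"]
    ]
    out["los_days"] = [
        compute_los(a, d)
        for a, d in zip(out["recv_admit_date"], out["recv_discharge_date"])
    ]
    return out


def flag_readmissions(
    events: pd.DataFrame,
    all_encounters: pd.DataFrame,
    directory,
    windows: tuple = READMISSION_WINDOWS,
) -> pd.DataFrame:
    """Flag readmission within each window after receiving-center discharge.

    A readmission is any later inpatient encounter under the same RLN at any
    short-term acute facility with an admission 1..W days after the
    receiving discharge (day 0 is a transfer, not a readmission; day W
    counts). Patients who died before discharge get null flags and are
    excluded from readmission denominators.
    """
    out = events.copy()
    ip = all_encounters[all_encounters["record_kind"] == vocab.INPATIENT]
    ip = ip[ip["rln"].notna()]
    sta = set(
        directory.facilities.loc[
            directory.facilities["facility_type"] == vocab.SHORT_TERM_ACUTE, "facility_id"
        ]
    )
    ip = ip[ip["facility_id"].isin(sta)]
    admits_by_rln: dict = {}
    for rln, g in ip.groupby("rln"):
        admits_by_rln[rln] = np.sort(pd.to_datetime(g["admit_date"]).to_numpy())

    died = out["disposition_group"] == "DIED"
    discharge = pd.to_datetime(out["recv_discharge_date"])
    for w in windows:
        flags = []
        for rln, disc, dead in zip(out["rln"], discharge, died):
            if dead:
                flags.append(None)
                continue
            admits = admits_by_rln.get(rln)
            if admits is None:
                flags.append(False)
                continue
            delta = (admits - disc.to_numpy()).astype("timedelta64[D]").astype(int)
            flags.append(bool(((delta >= 1) & (delta <= w)).any()))
        out[f"readmitted_{w}"] = flags
    return out


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> dict:
    """Crude odds ratio with a 95% Woolf (log-normal) interval.

    Cells follow the usual exposure-by-outcome layout: OR = (a*d)/(b*c).
    Any zero cell triggers the Haldane-Anscombe 0.5 correction, reported via
    the ``corrected`` flag.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be nonnegative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("a margin of the 2x2 table is zero")
    corrected = any(x == 0 for x in cells)
    if corrected:
        cells = [x + 0.5 for x in cells]
    a_, b_, c_, d_ = cells
    log_or = math.log((a_ * d_) / (b_ * c_))
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    z = stats.norm.ppf(0.975)
    return {
        "or": math.exp(log_or),
        "ci_low": math.exp(log_or - z * se),
        "ci_high": math.exp(log_or + z * se),
        "corrected": corrected,
    }


def chi_square_test(contingency) -> dict:
    """Pearson chi-square of independence, no continuity correction."""
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a row or column sums to zero")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return {"statistic": float(stat), "df": int(dof), "p": float(p)}


def contrast_2x2(events: pd.DataFrame, flag_col: str) -> dict:
    """Suboptimal-vs-optimal 2x2 for a boolean outcome column: OR, CI, and
    the chi-square test. Null flags (e.g. died before discharge) drop out."""
    sub = events["optimality"] == SUBOPTIMAL
    flags = events[flag_col]
    keep = flags.notna()
    f = flags[keep].astype(bool)
    s = sub[keep]
    a = int((s & f).sum())
    b = int((s & ~f).sum())
    c = int((~s & f).sum())
    d = int((~s & ~f).sum())
    res = odds_ratio_2x2(a, b, c, d)
    res.update(chi_square_test([[a, b], [c, d]]))
    res.update({"a": a, "b": b, "c": c, "d": d})
    return res


def surgery_rate_table(events: pd.DataFrame) -> pd.DataFrame:
    """Region x surgery-class x optimality counts with percentages of the
    optimality-stratum totals (suboptimal and optimal column totals serve as
    denominators, not the region's own size)."""
    totals = events.groupby("optimality").size()
    rows = []
    for (rtcc, surg, opt), g in events.groupby(
        ["rtcc_id", "recv_surgery_class", "optimality"], sort=True
    ):
        denom = totals.get(opt, 0)
        rows.append(
            {
                "rtcc_id": rtcc,
                "surgery_class": surg,
                "optimality": opt,
                "n": len(g),
                "percent": 100.0 * len(g) / denom if denom else None,
            }
        )
    return pd.DataFrame(rows)
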