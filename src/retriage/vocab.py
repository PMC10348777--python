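"""Controlled vocabularies shared across the pipeline.

Trauma-center levels, facility types, regional units, covariate categories,
and the raw-code-to-category mappings used when encoding administrative
records. Raw code vocabularies follow common discharge-data dialects; they
are configurable at the call sites that consume them.
"""

from __future__ import annotations

# --- trauma levels -----------------------------------------------------------

NONTRAUMA = "NONTRAUMA"
LEVEL_I = "LEVEL_I"
LEVEL_II = "LEVEL_II"
LEVEL_III = "LEVEL_III"
LEVEL_IV = "LEVEL_IV"

TRAUMA_LEVELS = (NONTRAUMA, LEVEL_I, LEVEL_II, LEVEL_III, LEVEL_IV)

#: Levels providing definitive trauma care; a re-triage ending here is optimal.
HIGH_LEVELS = frozenset({LEVEL_I, LEVEL_II})
#: Nontrauma and low-level centers; sending side of a re-triage, and the
#: receiving side of a suboptimal one.
LOW_LEVELS = frozenset({NONTRAUMA, LEVEL_III, LEVEL_IV})

# --- facility types ----------------------------------------------------------

SHORT_TERM_ACUTE = "SHORT_TERM_ACUTE"
REHAB = "REHAB"
PSYCH = "PSYCH"
LONG_TERM = "LONG_TERM"
OTHER_FACILITY = "OTHER"

FACILITY_TYPES = (SHORT_TERM_ACUTE, REHAB, PSYCH, LONG_TERM, OTHER_FACILITY)

# --- regional units ----------------------------------------------------------

RTCCS = ("NORTH", "BAY_AREA", "CENTRAL", "SOUTH_EAST", "SOUTH_WEST")

# Rough bounding boxes (lat_min, lat_max, lon_min, lon_max) used by the
# synthetic hospital generator; they mimic the relative geography of the five
# regional trauma coordinating committees (dense south-west vs sparse north).
RTCC_BOUNDING_BOXES = {
    "NORTH": (39.0, 42.0, -124.2, -120.0),
    "BAY_AREA": (37.0, 38.6, -123.0, -121.5),
    "CENTRAL": (35.0, 39.0, -121.2, -118.5),
    "SOUTH_EAST": (32.8, 35.0, -117.0, -114.3),
    "SOUTH_WEST": (33.0, 34.9, -119.5, -117.2),
}

# --- record kinds / admission types ------------------------------------------

ED = "ED"
INPATIENT = "INPATIENT"

EMERGENT = "EMERGENT"
ELECTIVE = "ELECTIVE"
OTHER_ADMISSION = "OTHER"

# --- covariate categories (analysis vocabularies) ----------------------------

AGE_BANDS = ("18-24", "25-34", "35-44", "45-54", "55-64", "65-74", "75-84", "85-89")
SEXES = ("MALE", "FEMALE")
RACES = ("WHITE", "BLACK", "ASIAN", "OTHER")
ETHNICITIES = ("NON_HISPANIC", "HISPANIC")
INSURANCES = (
    "SELF_PAY",
    "PRIVATE",
    "MEDICARE",
    "MEDICAID",
    "MANAGED_CARE_UNSPECIFIED",
    "OTHER",
)
MECHANISMS = ("ALL_TRANSPORT", "FALL", "STRUCK", "OTHER")
BODY_REGIONS = ("TORSO", "TBI", "OTHER_HEAD_FACE_NECK", "EXTREMITIES", "OTHER")
RISS_BANDS = ("16-25", ">25")

#: Reference level of each fixed-effect factor in the suboptimality model.
REFERENCE_LEVELS = {
    "age_band": "18-24",
    "sex": "MALE",
    "race": "WHITE",
    "ethnicity": "NON_HISPANIC",
    "insurance": "SELF_PAY",
    "mechanism": "ALL_TRANSPORT",
    "body_region": "TORSO",
    "riss_band": "16-25",
    "rtcc_id": "CENTRAL",
}

FACTOR_LEVELS = {
    "age_band": AGE_BANDS,
    "sex": SEXES,
    "race": RACES,
    "ethnicity": ETHNICITIES,
    "insurance": INSURANCES,
    "mechanism": MECHANISMS,
    "body_region": BODY_REGIONS,
    "riss_band": RISS_BANDS,
    "rtcc_id": RTCCS,
}

# --- raw insurance codes -> analysis categories ------------------------------
# Managed-care plan codes map to PRIVATE, except the unspecified managed-care
# category, which is kept distinct because payers cannot be disambiguated
# (it may hide Medicare-managed-care patients).
INSURANCE_CODE_MAP = {
    "self-pay": "SELF_PAY",
    "uninsured": "SELF_PAY",
    "commercial": "PRIVATE",
    "blue-cross-blue-shield": "PRIVATE",
    "epo": "PRIVATE",
    "private": "PRIVATE",
    "hmo": "PRIVATE",
    "ppo": "PRIVATE",
    "pos": "PRIVATE",
    "hmo-unspecified": "MANAGED_CARE_UNSPECIFIED",
    "managed-care-unspecified": "MANAGED_CARE_UNSPECIFIED",
    "medicare": "MEDICARE",
    "medicare-risk": "MEDICARE",
    "medicare-part-a": "MEDICARE",
    "medicare-part-b": "MEDICARE",
    "medicaid": "MEDICAID",
    "medi-cal": "MEDICAID",
    "workers-comp": "OTHER",
    "federal": "OTHER",
    "county": "OTHER",
    "other": "OTHER",
}

RACE_CODE_MAP = {
    "white": "WHITE",
    "black": "BLACK",
    "african-american": "BLACK",
    "asian": "ASIAN",
    "other": "OTHER",
    "unknown": "OTHER",
    "native-american": "OTHER",
    "pacific-islander": "OTHER",
}

ETHNICITY_CODE_MAP = {
    "hispanic": "HISPANIC",
    "non-hispanic": "NON_HISPANIC",
    "unknown": "NON_HISPANIC",
}

MECHANISM_CODE_MAP = {
    "mvc": "ALL_TRANSPORT",
    "motorcycle": "ALL_TRANSPORT",
    "pedestrian": "ALL_TRANSPORT",
    "bicycle": "ALL_TRANSPORT",
    "transport-other": "ALL_TRANSPORT",
    "fall": "FALL",
    "struck": "STRUCK",
    "struck-by-against": "STRUCK",
    "machinery": "OTHER",
    "firearm": "OTHER",
    "cut-pierce": "OTHER",
    "other": "OTHER",
    "unspecified": "OTHER",
}

#: Precedence when an encounter flags several affected body regions: traumatic
#: brain injury dominates, then torso, other head/face/neck, extremities.
BODY_REGION_PRECEDENCE = ("TBI", "TORSO", "OTHER_HEAD_FACE_NECK", "EXTREMITIES", "OTHER")

# --- discharge dispositions --------------------------------------------------

# Sending-ED dispositions that remove an encounter from the re-triage cohort.
DISPOSITION_EXPIRED = "expired"
DISPOSITION_AMA = "left-against-medical-advice"
DISPOSITION_REHAB_PLANNED_READMIT = "rehab-with-planned-readmission"

EXCLUDED_SENDING_DISPOSITIONS = frozenset(
    {DISPOSITION_EXPIRED, DISPOSITION_AMA, DISPOSITION_REHAB_PLANNED_READMIT}
)

#: Default collapse of receiving-center discharge disposition codes into the
#: four analysis groups.
DISPOSITION_GROUP_MAP = {
    "routine home": "HOME",
    "home": "HOME",
    "home-health": "HOME",
    "expired": "DIED",
    "died": "DIED",
    "transfer to short-term general hospital": "SHORT_TERM_ACUTE",
    "short-term-acute": "SHORT_TERM_ACUTE",
    "snf": "POST_ACUTE",
    "skilled-nursing": "POST_ACUTE",
    "rehab": "POST_ACUTE",
    "intermediate-care": "POST_ACUTE",
    "long-term-care": "POST_ACUTE",
    "hospice": "POST_ACUTE",
}

DISPOSITION_GROUPS = ("HOME", "DIED", "SHORT_TERM_ACUTE", "POST_ACUTE")

SURGERY_CLASSES = ("DIAGNOSTIC", "MINOR_THERAPEUTIC", "MAJOR_THERAPEUTIC", "NONE")


def age_band(age: int) -> str:
    """Map an age in years to its analysis band (18-24 reference, then
    10-year intervals up to 85-89)."""
    if age < 18 or age > 89:
        raise ValueError(f"age {age} outside the 18-89 study range")
    if age <= 24:
        return "18-24"
    if age >= 85:
        return "85-89"
    lo = 25 + 10 * ((age - 25) // 10)
    return f"{lo}-{lo + 9}"


def riss_band(riss: int) -> str:
    """Injury-severity band: 16-25 (reference) vs >25."""
    if riss <= 15:
        raise ValueError(f"riss {riss} below the >15 inclusion threshold")
    return "16-25" if riss <= 25 else ">25"
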