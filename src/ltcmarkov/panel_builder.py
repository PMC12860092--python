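"""Care-level taxonomy and one-year panel construction.

Japan's LTCI certifies eight care levels from the estimated minutes of
total care demanded: independent (ineligible), support-required SL1–SL2 and
care-required CL1–CL5.  The minute bands tile [0, ∞); SL2 and CL1 share the
32–50 minute band and are distinguished only by an explicit certification
decision, never by minutes.

Coarse LTC-status collapses the levels to four states — no-disability,
light (SL1..CL2), heavy (CL3..CL5), death — and, among service users, to
five states crossing severity with the service type (cognitive if any
dementia-related service was used, physical otherwise).

:func:`build_panel` turns the appended analysis file into one observation
per person per January with the status one year later attached (a linked
death counting as the outcome; persons lost without a death record are
right-censored and contribute no transition for that year).
"""

from __future__ import annotations

import enum
import math

import numpy as np
import pandas as pd

from .synthetic_data import HEAVY_LEVELS, LIGHT_LEVELS


class CareLevel(enum.Enum):
    """The eight certified care levels with their standard-minutes bands."""

    INDEPENDENT = "independent"
    SL1 = "SL1"
    SL2 = "SL2"
    CL1 = "CL1"
    CL2 = "CL2"
    CL3 = "CL3"
    CL4 = "CL4"
    CL5 = "CL5"

    @property
    def standard_minutes_band(self) -> tuple[float, float]:
        """Half-open ``[lo, hi)`` band of estimated total care minutes."""
        return _BANDS[self]


_BANDS = {
    CareLevel.INDEPENDENT: (0.0, 25.0),
    CareLevel.SL1: (25.0, 32.0),
    CareLevel.SL2: (32.0, 50.0),
    CareLevel.CL1: (32.0, 50.0),  # shared band, see classify_care_level
    CareLevel.CL2: (50.0, 70.0),
    CareLevel.CL3: (70.0, 90.0),
    CareLevel.CL4: (90.0, 110.0),
    CareLevel.CL5: (110.0, math.inf),
}

_SHARED_BAND = (32.0, 50.0)


class Status4(enum.Enum):
    NO_DISABILITY = "no_disability"
    LIGHT = "light"
    HEAVY = "heavy"
    DEATH = "death"


class Status5(enum.Enum):
    LIGHT_PHYSICAL = "light_physical"
    LIGHT_COGNITIVE = "light_cognitive"
    HEAVY_PHYSICAL = "heavy_physical"
    HEAVY_COGNITIVE = "heavy_cognitive"
    DEATH = "death"


def classify_care_level(
    minutes: float,
    sl2_cl1_disambiguator: CareLevel | str | None = None,
) -> CareLevel:
    """Map estimated total care minutes to the certified care level.

    Bands (minutes): independent < 25, SL1 25–32, SL2/CL1 32–50, CL2 50–70,
    CL3 70–90, CL4 90–110, CL5 ≥ 110; lower bounds inclusive.  Within the
    shared 32–50 band the certification decision itself — passed as
    ``sl2_cl1_disambiguator`` — picks SL2 or CL1.
    """
    if not np.isfinite(minutes) or minutes < 0:
        raise ValueError(f"care minutes must be finite and >= 0, got {minutes}")
    if _SHARED_BAND[0] <= minutes < _SHARED_BAND[1]:
        if sl2_cl1_disambiguator is None:
            raise ValueError(
                "minutes in the shared 32-50 band need an explicit SL2/CL1 "
                "certification decision"
            )
        level = CareLevel(
            sl2_cl1_disambiguator.value
            if isinstance(sl2_cl1_disambiguator, CareLevel)
            else sl2_cl1_disambiguator
        )
        if level not in (CareLevel.SL2, CareLevel.CL1):
            raise ValueError(f"disambiguator must be SL2 or CL1, got {level}")
        return level
    for level, (lo, hi) in _BANDS.items():
        if level in (CareLevel.SL2, CareLevel.CL1):
            continue
        if lo <= minutes < hi:
            return level
    raise AssertionError("minute bands must tile [0, inf)")  # pragma: no cover


def classify_status4(care_level: CareLevel | str, deceased: bool = False) -> Status4:
    """Collapse a care level to coarse LTC-status; death dominates."""
    if deceased:
        return Status4.DEATH
    level = care_level if isinstance(care_level, CareLevel) else CareLevel(care_level)
    if level is CareLevel.INDEPENDENT:
        return Status4.NO_DISABILITY
    if level.value in LIGHT_LEVELS:
        return Status4.LIGHT
    return Status4.HEAVY


def classify_status5(status4: Status4, dementia_service_flag: bool) -> Status5:
    """Cross severity with service type; death passes through.

    The no-disability state has no service record and is outside the
    five-state classification (ineligible persons file no claims).
    """
    if status4 is Status4.DEATH:
        return Status5.DEATH
    if status4 is Status4.NO_DISABILITY:
        raise ValueError(
            "no-disability observations are excluded from the five-state "
            "classification (ineligible for LTCI)"
        )
    if status4 is Status4.LIGHT:
        return Status5.LIGHT_COGNITIVE if dementia_service_flag else Status5.LIGHT_PHYSICAL
    return Status5.HEAVY_COGNITIVE if dementia_service_flag else Status5.HEAVY_PHYSICAL


_LEVEL_TO_STATUS4 = {lv: "light" for lv in LIGHT_LEVELS}
_LEVEL_TO_STATUS4.update({lv: "heavy" for lv in HEAVY_LEVELS})
_LEVEL_TO_STATUS4["independent"] = "no_disability"


def build_panel(appended: pd.DataFrame) -> pd.DataFrame:
    """One-year-interval panel of January observations.

    Input is the flowchart-filtered appended file (columns ``person_id,
    year, age, sex, municipality, care_level, dementia_service_flag`` and a
    ``death_date`` for the deceased).  Output has one row per (person,
    January) with ``status4``/``status5`` and the one-year-later outcomes
    ``next_status4``/``next_status5``:

    * the next January's statuses when the person is observed again,
    * ``death`` when the linked death date falls before the next snapshot,
    * missing (censored) when the person is lost without a death record.

    Duplicate (person, year) rows are an error.
    """
    needed = ["person_id", "year", "age", "sex", "municipality", "care_level"]
    missing = [c for c in needed if c not in appended.columns]
    if missing:
        raise ValueError(f"appended file is missing columns {missing}")
    if appended.duplicated(["person_id", "year"]).any():
        dup = appended[appended.duplicated(["person_id", "year"], keep=False)]
        raise ValueError(
            f"duplicate (person, year) rows in appended file, e.g.\n"
            f"{dup.head(4)[['person_id', 'year']]}"
        )

    panel = appended[needed].copy()
    panel["status4"] = appended["care_level"].map(_LEVEL_TO_STATUS4)
    if panel["status4"].isna().any():
        bad = appended.loc[panel["status4"].isna(), "care_level"].unique()
        raise ValueError(f"unknown care levels {bad}")
    flag = appended.get(
        "dementia_service_flag", pd.Series(False, index=appended.index)
    ).fillna(False).astype(bool)
    sev = panel["status4"].map({"light": "light", "heavy": "heavy"})
    panel["status5"] = np.where(
        sev.notna(),
        sev.astype(str) + np.where(flag, "_cognitive", "_physical"),
        None,
    )
    death_date = pd.to_datetime(
        appended.get("death_date", pd.Series(pd.NaT, index=appended.index))
    )

    nxt = panel[["person_id", "year", "status4", "status5"]].copy()
    nxt["year"] -= 1
    nxt = nxt.rename(
        columns={"status4": "next_status4", "status5": "next_status5"}
    )
    panel = panel.merge(nxt, on=["person_id", "year"], how="left")

    next_snapshot = pd.to_datetime((panel["year"] + 1).astype(str) + "-01-01")
    this_snapshot = pd.to_datetime(panel["year"].astype(str) + "-01-01")
    dd = death_date.reset_index(drop=True)
    dies = (
        panel["next_status4"].isna()
        & dd.notna()
        & (dd >= this_snapshot)
        & (dd < next_snapshot)
    )
    panel.loc[dies, "next_status4"] = "death"
    panel.loc[dies, "next_status5"] = "death"
    return panel


def status_shares(panel: pd.DataFrame, scheme: int = 4) -> dict[str, float]:
    """Observation shares per status (a partition summing to one)."""
    col = "status4" if scheme == 4 else "status5"
    shares = panel[col].value_counts(normalize=True, dropna=True)
    return {k: float(v) for k, v in shares.items()}
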