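"""Reading, deterministic death linkage, and the inclusion flowchart.

Claims tables record a disqualification date instead of a death date:
municipalities strike recipients from the insurance register upon receiving
the death notice.  The date of death is recovered by deterministically
linking disqualified claims records to death certificates on
(municipality, sex, birth date) with the disqualification date equal to —
or within a configurable lag after — the certificate's death date.

The inclusion flowchart then assembles the analysis file: exclude under-65
records, split into disqualified / non-disqualified, link the disqualified
to certificates, append the non-disqualified and deceased records, restrict
to ages 65–94 and the configured birth cohorts, and keep only persons
traceable for two consecutive January snapshots (death counting as the
second-year outcome).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import (
    AGE_MAX,
    AGE_MIN,
    CLAIMS_COLUMNS,
    COHORT_MAX,
    COHORT_MIN,
    DEATHS_COLUMNS,
)

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """An input table is missing mandatory columns."""


# --------------------------------------------------------------------------
# readers (explicit dtypes; dates ISO-8601)

_CLAIMS_DTYPES = {
    "person_id": str,
    "municipality": np.int64,
    "sex": str,
    "record_month": str,
    "care_level": str,
    "dementia_service_flag": bool,
}


def read_claims(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype=_CLAIMS_DTYPES,
        parse_dates=["birth_date", "disqualification_date"],
    )
    _require(df, CLAIMS_COLUMNS, "claims")
    return df


def read_deaths(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"municipality": np.int64, "sex": str},
        parse_dates=["birth_date", "death_date"],
    )
    _require(df, DEATHS_COLUMNS, "deaths")
    return df


def read_population(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["year", "municipality", "sex", "age", "count"], "population")
    return df


def read_mortality(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["year", "sex", "age", "rate"], "mortality")
    return df


def _require(df: pd.DataFrame, columns, name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing columns {missing}")


def record_year(claims: pd.DataFrame) -> pd.Series:
    """Calendar year of each claims record (from its ``record_month``)."""
    return claims["record_month"].str.slice(0, 4).astype(int)


def age_at_january(year: pd.Series | np.ndarray, birth_date: pd.Series) -> pd.Series:
    """Completed years of age at the January-1 snapshot of ``year``."""
    birth_date = pd.to_datetime(birth_date)
    before_jan1 = (birth_date.dt.month == 1) & (birth_date.dt.day == 1)
    return np.asarray(year) - birth_date.dt.year - (~before_jan1).astype(int)


# --------------------------------------------------------------------------
# split and link


def split_claims(claims: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition claims into (disqualified, non-disqualified) files.

    A record is disqualified iff it carries a disqualification date.  The
    partition is exhaustive and disjoint.
    """
    _require(claims, CLAIMS_COLUMNS, "claims")
    mask = claims["disqualification_date"].notna()
    return claims.loc[mask].copy(), claims.loc[~mask].copy()


@dataclass
class LinkageReport:
    """Outcome counts of the deterministic linkage."""

    n_input: int = 0
    n_linked: int = 0
    n_ambiguous: int = 0
    n_unmatched: int = 0
    n_relocation_skipped: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def link_deaths(
    disqualified: pd.DataFrame,
    deaths: pd.DataFrame,
    lag_days: int = 0,
) -> tuple[pd.DataFrame, LinkageReport]:
    """Deterministically link disqualified claims to death certificates.

    A record links iff exactly one certificate shares its (municipality,
    sex, birth date) and ``0 <= disqualification_date - death_date <=
    lag_days``.  Records disqualified for relocation are never candidates
    (the register records the move itself, not a death).  Ambiguous
    multi-matches are excluded and counted — a deterministic rule cannot
    resolve them.

    Returns the deceased file (input rows plus a ``death_date`` column) and
    a :class:`LinkageReport`.  The operation is idempotent and
    order-independent.
    """
    report = LinkageReport(n_input=len(disqualified))
    reloc = disqualified["disqualification_reason"] == "relocation"
    report.n_relocation_skipped = int(reloc.sum())
    cand = disqualified.loc[~reloc].copy()
    if cand.empty or deaths.empty:
        report.n_unmatched = len(cand)
        out = disqualified.iloc[0:0].copy()
        out["death_date"] = pd.Series(dtype="datetime64[ns]")
        return out, report

    cand = cand.reset_index(drop=False).rename(columns={"index": "_row"})
    merged = cand.merge(
        deaths[["municipality", "sex", "birth_date", "death_date"]],
        on=["municipality", "sex", "birth_date"],
        how="inner",
    )
    delta = (merged["disqualification_date"] - merged["death_date"]).dt.days
    merged = merged.loc[(delta >= 0) & (delta <= lag_days)]
    n_matches = merged.groupby("_row").size()

    unique_rows = n_matches[n_matches == 1].index
    report.n_linked = len(unique_rows)
    report.n_ambiguous = int((n_matches > 1).sum())
    report.n_unmatched = len(cand) - report.n_linked - report.n_ambiguous
    if report.n_ambiguous:
        logger.warning(
            "linkage: %d disqualified records matched more than one death "
            "certificate and were excluded",
            report.n_ambiguous,
        )

    linked = merged[merged["_row"].isin(unique_rows)].set_index("_row")
    deceased = disqualified.loc[linked.index].copy()
    deceased["death_date"] = linked["death_date"]
    deceased = deceased.sort_index().reset_index(drop=True)
    return deceased, report


# --------------------------------------------------------------------------
# flowchart


@dataclass
class FlowchartReport:
    """Stage-by-stage record counts of the inclusion flowchart.

    Each stage satisfies ``n_in = n_out + n_excluded`` and consecutive
    stages telescope (``n_out`` of one equals ``n_in`` of the next, except
    across the split/link/append stages where the disqualified branch is
    accounted for explicitly).
    """

    stages: list[dict] = field(default_factory=list)
    linkage: LinkageReport | None = None
    n_deaths_input: int = 0
    n_deaths_under65: int = 0
    final_records: int = 0
    final_unique_persons: int = 0

    def add(self, name: str, n_in: int, n_out: int) -> None:
        self.stages.append(
            {"stage": name, "n_in": int(n_in), "n_out": int(n_out),
             "n_excluded": int(n_in - n_out)}
        )

    def validate(self) -> None:
        for st in self.stages:
            if st["n_in"] != st["n_out"] + st["n_excluded"] or st["n_excluded"] < 0:
                raise ValueError(f"flowchart stage does not reconcile: {st}")

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "linkage": self.linkage.to_dict() if self.linkage else None,
            "n_deaths_input": self.n_deaths_input,
            "n_deaths_under65": self.n_deaths_under65,
            "final_records": self.final_records,
            "final_unique_persons": self.final_unique_persons,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def apply_flowchart(
    claims: pd.DataFrame,
    deaths: pd.DataFrame,
    window: tuple[int, int] = (2007, 2018),
    cohort_range: tuple[int, int] = (COHORT_MIN, COHORT_MAX),
    age_range: tuple[int, int] = (AGE_MIN, AGE_MAX),
    lag_days: int = 0,
) -> tuple[pd.DataFrame, FlowchartReport]:
    """Run the full inclusion flowchart over raw claims and certificates.

    Returns the appended analysis file (January records of included persons,
    with ``year``, ``age``, ``birth_year`` and — for the deceased — a
    ``death_date`` column) and the telescoping :class:`FlowchartReport`.
    An empty final file is reported with a warning, not an error.
    """
    report = FlowchartReport()
    a_lo, a_hi = age_range

    claims = claims.copy()
    claims["year"] = record_year(claims)
    claims["age"] = age_at_january(claims["year"], claims["birth_date"])
    claims["birth_year"] = pd.to_datetime(claims["birth_date"]).dt.year

    # 1. under-65 exclusions, claims and certificates alike
    n0 = len(claims)
    claims = claims[claims["age"] >= a_lo]
    report.add("age_under_minimum", n0, len(claims))
    report.n_deaths_input = len(deaths)
    death_age = age_at_january(
        pd.to_datetime(deaths["death_date"]).dt.year, deaths["birth_date"]
    )
    deaths65 = deaths[np.asarray(death_age) >= a_lo - 1]
    report.n_deaths_under65 = len(deaths) - len(deaths65)

    # 2. split into disqualified / non-disqualified
    disq, nondisq = split_claims(claims)
    report.add("split_disqualified", len(claims), len(nondisq))
    # the excluded branch here is the disqualified file, re-entering below

    # 3. deterministic linkage; unlinked disqualified records drop out
    deceased, link_rep = link_deaths(disq, deaths65, lag_days=lag_days)
    report.linkage = link_rep
    report.add("link_disqualified_to_deaths", len(disq), len(deceased))

    # 4. append
    nondisq = nondisq.copy()
    nondisq["death_date"] = pd.NaT
    appended = pd.concat([nondisq, deceased], ignore_index=True)
    report.add(
        "append_nondisqualified_and_deceased",
        len(nondisq) + len(deceased),
        len(appended),
    )

    # 5. age ceiling and birth-cohort window
    n_in = len(appended)
    c_lo, c_hi = cohort_range
    appended = appended[
        (appended["age"] <= a_hi)
        & appended["birth_year"].between(c_lo, c_hi)
    ]
    report.add("age_and_cohort_window", n_in, len(appended))

    # 6. January records only (a no-op when inputs are January snapshots)
    n_in = len(appended)
    appended = appended[appended["record_month"].str.endswith("-01")]
    report.add("january_records", n_in, len(appended))

    # 7. traceable for two consecutive years; a linked death counts as the
    #    second-year outcome
    n_in = len(appended)
    years_by_person = appended.groupby("person_id")["year"].agg(["min", "max", "nunique"])
    consec = appended[["person_id", "year"]].drop_duplicates()
    nxt = consec.copy()
    nxt["year"] += 1
    has_pair = consec.merge(nxt, on=["person_id", "year"], how="inner")[
        "person_id"
    ].unique()
    death_next = appended.loc[
        appended["death_date"].notna()
        & (pd.to_datetime(appended["death_date"]).dt.year >= appended["year"]),
        "person_id",
    ].unique()
    traced = set(has_pair) | set(death_next)
    appended = appended[appended["person_id"].isin(traced)]
    report.add("traced_two_consecutive_years", n_in, len(appended))
    del years_by_person

    # 8. extract the panel window; claims begin one year earlier so that
    #    opening-year recipients are traceable, but those lead-in records
    #    are not panel observations
    n_in = len(appended)
    appended = appended[appended["year"].between(window[0], window[1])]
    report.add("panel_window_years", n_in, len(appended))

    appended = appended.reset_index(drop=True)
    report.final_records = len(appended)
    report.final_unique_persons = appended["person_id"].nunique()
    report.validate()
    if appended.empty:
        logger.warning("flowchart produced an empty analysis file")
    return appended, report
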