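"""Synthetic long-term-care claims world.

Japan's public long-term care insurance (LTCI) certifies residents aged 65+
into eight care levels; claims, death certificates, and resident-registration
population counts are restricted administrative data.  This module generates
a statistically analogous world from a known parametric transition model so
that every downstream stage (linkage, panel construction, Markov estimation,
microsimulation) can be tested against retained ground truth.

The latent process is a yearly six-state chain on
``no_disability, light_physical, light_cognitive, heavy_physical,
heavy_cognitive, death`` evaluated at January snapshots:

* incidence of first eligibility rises logistically with age,
* severity progression is near-irreversible (no recovery to lighter states),
* death is absorbing, with Gompertz one-year probabilities ordered
  no-disability < light < heavy,
* males die more, females accumulate more late-life disability,
* dementia-related (cognitive) service use is assigned at first eligibility
  and persists; it multiplies the light→heavy progression hazard.

Outputs mirror the schemas of the four administrative sources: a claims
table (eligible person-months), a death-certificate table, and aggregated
population / mortality tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

# --------------------------------------------------------------------------
# constants shared across the package

SEXES = ("M", "F")

#: latent six-state codes
ND, LP, LC, HP, HC, DEAD = range(6)
STATE6_LABELS = (
    "no_disability",
    "light_physical",
    "light_cognitive",
    "heavy_physical",
    "heavy_cognitive",
    "death",
)

AGE_MIN, AGE_MAX = 65, 94
N_AGES = AGE_MAX - AGE_MIN + 1  # 30 January snapshots per person at most
AGES = np.arange(AGE_MIN, AGE_MAX + 1)

COHORT_MIN, COHORT_MAX = 1912, 1951

LIGHT_LEVELS = ("SL1", "SL2", "CL1", "CL2")
HEAVY_LEVELS = ("CL3", "CL4", "CL5")
LEVEL_NAMES = LIGHT_LEVELS + HEAVY_LEVELS
# within-severity certified-level mix, drawn once per severity spell
_LIGHT_LEVEL_W = np.array([0.30, 0.25, 0.25, 0.20])
_HEAVY_LEVEL_W = np.array([0.40, 0.35, 0.25])

#: one-year probabilities are capped away from 1 so rows stay proper
PROB_CAP = 0.97

CLAIMS_COLUMNS = [
    "person_id",
    "municipality",
    "sex",
    "birth_date",
    "record_month",
    "care_level",
    "dementia_service_flag",
    "disqualification_date",
    "disqualification_reason",
]
DEATHS_COLUMNS = ["municipality", "sex", "birth_date", "death_date"]
POPULATION_COLUMNS = ["year", "municipality", "sex", "age", "count"]
MORTALITY_COLUMNS = ["year", "sex", "age", "rate", "deaths", "at_risk"]


class InvalidParameterError(ValueError):
    """A generator parameter is outside its valid range.

    Carries the offending field name so callers can report it.
    """

    def __init__(self, fieldname: str, message: str):
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


# --------------------------------------------------------------------------
# the true transition model


@dataclass(frozen=True)
class TrueModel:
    """Parametric one-year transition kernel the synthetic world obeys.

    Parameters
    ----------
    incidence_base
        Annual probability at age 65 that a non-disabled person becomes
        eligible (enters a light state).
    incidence_slope
        Per-year-of-age increment on the log-odds of incidence.
    progression_light_to_heavy
        Annual probability (conditional on surviving) that a light recipient
        progresses to a heavy state.
    mortality_gompertz_a, mortality_gompertz_b
        Gompertz baseline (age 65) and age rate of the one-year death
        probability for the no-disability state.
    mortality_multiplier_*
        Per-state multipliers on the Gompertz curve; must be strictly
        ordered no-disability < light < heavy.
    sex_incidence, sex_mortality
        Multiplicative sex modifiers (keys "M", "F") on incidence and
        mortality.
    cognitive_fraction
        Probability that a newly eligible person is a dementia-related
        (cognitive) service user; the type persists for life.
    cognitive_progression_boost
        Multiplier on light→heavy progression for cognitive users.
    """

    incidence_base: float = 0.004
    incidence_slope: float = 0.155
    progression_light_to_heavy: float = 0.10
    mortality_gompertz_a: float = 0.010
    mortality_gompertz_b: float = 0.095
    mortality_multiplier_no_disability: float = 1.0
    mortality_multiplier_light: float = 1.5
    mortality_multiplier_heavy: float = 2.8
    sex_incidence: Mapping[str, float] = field(
        default_factory=lambda: {"M": 1.0, "F": 1.25}
    )
    sex_mortality: Mapping[str, float] = field(
        default_factory=lambda: {"M": 1.0, "F": 0.65}
    )
    cognitive_fraction: float = 0.12
    cognitive_progression_boost: float = 2.0

    # -- elementary hazards ------------------------------------------------

    def incidence(self, ages, sex: str) -> np.ndarray:
        """Annual no-disability → eligibility probability at ``ages``."""
        ages = np.asarray(ages, dtype=float)
        p = expit(logit(self.incidence_base) + self.incidence_slope * (ages - AGE_MIN))
        return np.minimum(p * self.sex_incidence[sex], PROB_CAP)

    def mortality(self, ages, sex: str, severity: str) -> np.ndarray:
        """One-year death probability by age, sex and severity class."""
        mult = {
            "no_disability": self.mortality_multiplier_no_disability,
            "light": self.mortality_multiplier_light,
            "heavy": self.mortality_multiplier_heavy,
        }[severity]
        ages = np.asarray(ages, dtype=float)
        q = self.mortality_gompertz_a * np.exp(
            self.mortality_gompertz_b * (ages - AGE_MIN)
        )
        return np.minimum(q * mult * self.sex_mortality[sex], PROB_CAP)

    def progression(self, cognitive: bool) -> float:
        p = self.progression_light_to_heavy
        if cognitive:
            p *= self.cognitive_progression_boost
        return min(p, PROB_CAP)

    # -- implied kernels ---------------------------------------------------

    def kernel6(self, sex: str) -> np.ndarray:
        """Six-state kernel, shape (30, 6, 6), origin ages 65..94.

        Rows sum to one by construction; death is absorbing.
        """
        q_nd = self.mortality(AGES, sex, "no_disability")
        q_l = self.mortality(AGES, sex, "light")
        q_h = self.mortality(AGES, sex, "heavy")
        inc = self.incidence(AGES, sex)
        prog_p = self.progression(cognitive=False)
        prog_c = self.progression(cognitive=True)
        cf = self.cognitive_fraction

        K = np.zeros((N_AGES, 6, 6))
        K[:, ND, DEAD] = q_nd
        K[:, ND, LP] = (1 - q_nd) * inc * (1 - cf)
        K[:, ND, LC] = (1 - q_nd) * inc * cf
        K[:, ND, ND] = 1.0 - K[:, ND, LP] - K[:, ND, LC] - K[:, ND, DEAD]
        K[:, LP, DEAD] = q_l
        K[:, LP, HP] = (1 - q_l) * prog_p
        K[:, LP, LP] = 1.0 - K[:, LP, HP] - K[:, LP, DEAD]
        K[:, LC, DEAD] = q_l
        K[:, LC, HC] = (1 - q_l) * prog_c
        K[:, LC, LC] = 1.0 - K[:, LC, HC] - K[:, LC, DEAD]
        K[:, HP, DEAD] = q_h
        K[:, HP, HP] = 1.0 - q_h
        K[:, HC, DEAD] = q_h
        K[:, HC, HC] = 1.0 - q_h
        K[:, DEAD, DEAD] = 1.0
        return K

    def occupancy6(self, sex: str) -> np.ndarray:
        """State occupancy at each age, shape (30, 6), starting all-ND at 65."""
        K = self.kernel6(sex)
        occ = np.zeros((N_AGES, 6))
        occ[0, ND] = 1.0
        for k in range(N_AGES - 1):
            occ[k + 1] = occ[k] @ K[k]
        return occ

    def implied_kernel4(self, sex: str) -> np.ndarray:
        """Population-level four-state kernel, shape (30, 4, 4).

        States are (no_disability, light, heavy, death).  The light row is
        the occupancy-weighted mixture of the physical and cognitive light
        rows, i.e. exactly the expected one-year transition frequency a
        panel of this cohort exhibits at each age.
        """
        K6 = self.kernel6(sex)
        occ = self.occupancy6(sex)
        cf = self.cognitive_fraction
        K4 = np.zeros((N_AGES, 4, 4))
        for k in range(N_AGES):
            nd = K6[k, ND]
            K4[k, 0] = [nd[ND], nd[LP] + nd[LC], nd[HP] + nd[HC], nd[DEAD]]
            w = occ[k, [LP, LC]]
            w = w / w.sum() if w.sum() > 0 else np.array([1 - cf, cf])
            light = w @ K6[k, [LP, LC]]
            K4[k, 1] = [
                light[ND],
                light[LP] + light[LC],
                light[HP] + light[HC],
                light[DEAD],
            ]
            # heavy-physical and heavy-cognitive rows are identical, so the
            # mixture weight is irrelevant
            heavy = K6[k, HP]
            K4[k, 2] = [
                heavy[ND],
                heavy[LP] + heavy[LC],
                heavy[HP] + heavy[HC],
                heavy[DEAD],
            ]
        K4[:, 3, 3] = 1.0
        return K4

    def implied_kernel5(self, sex: str) -> np.ndarray:
        """Five-state kernel over the eligible states, shape (30, 5, 5).

        States are (light_physical, light_cognitive, heavy_physical,
        heavy_cognitive, death); the no-disability origin is outside this
        chain (ineligible persons file no claims).
        """
        K6 = self.kernel6(sex)
        idx = [LP, LC, HP, HC, DEAD]
        return K6[:, idx][:, :, idx]

    def cumulative_eligibility(self, sex: str) -> np.ndarray:
        """P(entered an eligible state at or before each age), shape (30,)."""
        K6 = self.kernel6(sex)
        still_nd = 1.0
        ever = np.zeros(N_AGES)
        for k in range(N_AGES):
            if k > 0:
                escape = K6[k - 1, ND, LP] + K6[k - 1, ND, LC]
                ever[k] = ever[k - 1] + still_nd * escape
                still_nd = still_nd * K6[k - 1, ND, ND]
        return ever


def make_true_model(config: Mapping[str, object] | None = None, **overrides) -> TrueModel:
    """Build and validate a :class:`TrueModel`.

    Raises :class:`InvalidParameterError` naming the offending field when a
    parameter is out of range or the implied kernel violates an invariant
    (rows not in [0,1]/summing to 1, non-monotone incidence or mortality,
    mis-ordered per-state mortality multipliers).
    """
    params = dict(config or {})
    params.update(overrides)
    model = TrueModel(**params)

    for name in ("incidence_base", "cognitive_fraction"):
        v = getattr(model, name)
        if not 0.0 <= v <= 1.0:
            raise InvalidParameterError(name, f"must be in [0, 1], got {v}")
    for name in (
        "incidence_slope",
        "mortality_gompertz_b",
        "cognitive_progression_boost",
    ):
        v = getattr(model, name)
        if v < 0:
            raise InvalidParameterError(name, f"must be non-negative, got {v}")
    if not 0.0 <= model.progression_light_to_heavy <= 1.0:
        raise InvalidParameterError(
            "progression_light_to_heavy",
            f"must be in [0, 1], got {model.progression_light_to_heavy}",
        )
    if model.mortality_gompertz_a <= 0:
        raise InvalidParameterError(
            "mortality_gompertz_a",
            f"must be positive, got {model.mortality_gompertz_a}",
        )
    m_nd = model.mortality_multiplier_no_disability
    m_l = model.mortality_multiplier_light
    m_h = model.mortality_multiplier_heavy
    if not (0 < m_nd < m_l):
        raise InvalidParameterError(
            "mortality_multiplier_light",
            f"multipliers must satisfy no_disability < light, got {m_nd} vs {m_l}",
        )
    if not m_l < m_h:
        raise InvalidParameterError(
            "mortality_multiplier_heavy",
            f"multipliers must satisfy light < heavy, got {m_l} vs {m_h}",
        )
    for name in ("sex_incidence", "sex_mortality"):
        d = getattr(model, name)
        if set(d) != set(SEXES) or any(v <= 0 for v in d.values()):
            raise InvalidParameterError(
                name, f"needs positive entries for {SEXES}, got {dict(d)}"
            )

    for sex in SEXES:
        K = model.kernel6(sex)
        if not np.allclose(K.sum(axis=2), 1.0, atol=1e-12):
            raise InvalidParameterError("kernel", f"rows do not sum to 1 for sex {sex}")
        if (K < -1e-15).any() or (K > 1 + 1e-15).any():
            raise InvalidParameterError(
                "kernel", f"entries outside [0, 1] for sex {sex}"
            )
        if np.any(np.diff(model.incidence(AGES, sex)) < -1e-12):
            raise InvalidParameterError(
                "incidence_slope", f"incidence not non-decreasing in age for {sex}"
            )
        for sev in ("no_disability", "light", "heavy"):
            if np.any(np.diff(model.mortality(AGES, sex, sev)) < -1e-12):
                raise InvalidParameterError(
                    "mortality_gompertz_b",
                    f"mortality not non-decreasing in age for {sex}/{sev}",
                )
    return model


# --------------------------------------------------------------------------
# simulation configuration


@dataclass(frozen=True)
class SimConfig:
    """World-generation settings.

    Defaults encode the analysis frame of the emulated data: January
    snapshots 2007–2018 on the 1912–1951 birth cohorts, with everyone
    re-identified (new person id) when they relocate to another
    municipality.
    """

    n_individuals: int = 100_000
    n_municipalities: int = 50
    birth_cohorts: tuple[int, int] = (COHORT_MIN, COHORT_MAX)
    observation_window: tuple[int, int] = (2007, 2018)
    seed: int = 0
    relocation_rate: float = 0.02
    coverage_fraction: float = 1.0
    disqualification_lag_days: int = 0

    def __post_init__(self):
        if self.n_individuals <= 0:
            raise InvalidParameterError("n_individuals", "must be positive")
        if self.n_municipalities <= 0:
            raise InvalidParameterError("n_municipalities", "must be positive")
        c0, c1 = self.birth_cohorts
        if not (COHORT_MIN <= c0 <= c1 <= COHORT_MAX):
            raise InvalidParameterError(
                "birth_cohorts",
                f"must lie within [{COHORT_MIN}, {COHORT_MAX}], got {self.birth_cohorts}",
            )
        w0, w1 = self.observation_window
        if w0 > w1:
            raise InvalidParameterError("observation_window", "start exceeds end")
        if not 0.0 <= self.relocation_rate <= 1.0:
            raise InvalidParameterError("relocation_rate", "must be in [0, 1]")
        if not 0.0 < self.coverage_fraction <= 1.0:
            raise InvalidParameterError("coverage_fraction", "must be in (0, 1]")
        if self.disqualification_lag_days < 0:
            raise InvalidParameterError("disqualification_lag_days", "must be >= 0")


@dataclass
class TruthData:
    """Retained ground truth for parameter-recovery and reconciliation tests.

    ``state_paths`` holds the latent six-state path of every simulated person
    at ages 65..94 (death absorbing).  ``observations`` is the long table of
    alive in-window person-January rows — including the non-disabled, who
    never appear in claims — with the person id and municipality in force at
    that snapshot.
    """

    persons: pd.DataFrame
    observations: pd.DataFrame
    state_paths: np.ndarray
    covered_municipalities: np.ndarray
    model: TrueModel
    config: SimConfig


# --------------------------------------------------------------------------
# population simulation


def _person_ids(latent: np.ndarray, segment: np.ndarray) -> pd.Series:
    # opaque but reversible in tests: latent id * 100 + relocation segment
    code = latent.astype(np.int64) * 100 + segment.astype(np.int64)
    return "P" + pd.Series(code).astype(str)


def simulate_population(
    model: TrueModel, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, TruthData]:
    """Simulate the cohort and emit claims and death-certificate tables.

    Returns ``(claims, deaths, truth)``.  Claims rows exist only for
    eligible person-Januaries in covered municipalities; every in-window
    death yields a death certificate (regardless of eligibility or
    coverage) and, when the person was an enrolled recipient, a
    disqualification with reason ``death`` on their final claims row.
    Relocations produce a disqualification with reason ``relocation`` and a
    new person id in another municipality.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    n_mun = config.n_municipalities
    w0, w1 = config.observation_window
    c0, c1 = config.birth_cohorts

    sex_idx = rng.integers(0, 2, n)  # 0 = M, 1 = F
    birth_year = rng.integers(c0, c1 + 1, n)
    # births kept off January 1 so "completed years at the January snapshot"
    # is simply year - birth_year - 1
    birth_month = rng.integers(2, 13, n)
    birth_day = rng.integers(1, 29, n)
    birth_date = pd.to_datetime(
        {"year": birth_year, "month": birth_month, "day": birth_day}
    )
    muni0 = rng.integers(0, n_mun, n)
    n_cov = max(1, int(round(config.coverage_fraction * n_mun)))
    covered_munis = np.sort(rng.permutation(n_mun)[:n_cov])
    covered_set = np.zeros(n_mun, dtype=bool)
    covered_set[covered_munis] = True

    kernels = (model.kernel6("M"), model.kernel6("F"))

    # latent six-state paths at ages 65..94
    paths = np.zeros((n, N_AGES), dtype=np.int8)
    for k in range(N_AGES - 1):
        u = rng.random(n)
        cur = paths[:, k]
        nxt = np.empty(n, dtype=np.int8)
        for s in (0, 1):
            m = sex_idx == s
            rows = kernels[s][k][cur[m]]
            cum = np.cumsum(rows, axis=1)
            cum[:, -1] = 1.0
            nxt[m] = (u[m, None] >= cum).sum(axis=1)
        paths[:, k + 1] = nxt

    alive = paths != DEAD
    eligible = (paths >= LP) & (paths <= HC)
    is_light = (paths == LP) | (paths == LC)
    is_heavy = (paths == HP) | (paths == HC)
    year_mat = birth_year[:, None] + AGES[None, :] + 1  # calendar year per column

    # municipality / person-id segment / certified level per column
    muni_mat = np.zeros((n, N_AGES), dtype=np.int32)
    seg_mat = np.zeros((n, N_AGES), dtype=np.int16)
    lev_mat = np.full((n, N_AGES), -1, dtype=np.int8)
    reloc_mat = np.zeros((n, N_AGES), dtype=bool)
    cur_muni = muni0.copy()
    cur_seg = np.zeros(n, dtype=np.int16)
    cur_lev = np.full(n, -1, dtype=np.int8)
    cum_lw = np.cumsum(_LIGHT_LEVEL_W)
    cum_hw = np.cumsum(_HEAVY_LEVEL_W)
    for k in range(N_AGES):
        if k == 0:
            enter_light = is_light[:, 0]
            enter_heavy = is_heavy[:, 0]
        else:
            enter_light = is_light[:, k] & ~is_light[:, k - 1]
            enter_heavy = is_heavy[:, k] & ~is_heavy[:, k - 1]
        ul = rng.random(n)
        uh = rng.random(n)
        cur_lev[enter_light] = np.searchsorted(cum_lw, ul[enter_light], side="right")
        cur_lev[enter_heavy] = 4 + np.searchsorted(
            cum_hw, uh[enter_heavy], side="right"
        )
        lev_mat[:, k] = np.where(eligible[:, k], cur_lev, -1)
        muni_mat[:, k] = cur_muni
        seg_mat[:, k] = cur_seg
        if k < N_AGES - 1 and n_mun > 1:
            ur = rng.random(n)
            in_win = (year_mat[:, k] >= w0 - 1) & (year_mat[:, k] <= w1)
            rel = (
                (ur < config.relocation_rate)
                & eligible[:, k]
                & alive[:, k + 1]
                & in_win
            )
            new_m = rng.integers(0, n_mun - 1, n)
            new_m = new_m + (new_m >= cur_muni)  # guaranteed different
            cur_muni = np.where(rel, new_m, cur_muni).astype(np.int32)
            cur_seg = (cur_seg + rel).astype(np.int16)
            reloc_mat[:, k] = rel

    # death timing: alive at Jan(y), dead at Jan(y+1) => death during year y
    died = (paths == DEAD).any(axis=1)
    death_step = np.where(died, np.argmax(paths == DEAD, axis=1), 0)
    last_alive_k = death_step - 1
    death_year = np.where(
        died, year_mat[np.arange(n), np.maximum(last_alive_k, 0)], 2000
    )
    death_month = rng.integers(2, 13, n)
    death_day = rng.integers(1, 29, n)
    death_date = pd.to_datetime(
        {"year": death_year, "month": death_month, "day": death_day}
    )
    death_date = death_date.where(pd.Series(died), pd.NaT)
    if config.disqualification_lag_days > 0:
        lag = rng.integers(0, config.disqualification_lag_days + 1, n)
    else:
        lag = np.zeros(n, dtype=int)
    disq_death_date = death_date + pd.to_timedelta(lag, unit="D")
    # relocation disqualification date: month/day drawn once per person,
    # reused for any relocation year (always after the January snapshot)
    reloc_month = rng.integers(2, 13, n)
    reloc_day = rng.integers(1, 29, n)

    dies_next = np.zeros((n, N_AGES), dtype=bool)
    dies_next[:, :-1] = (paths[:, 1:] == DEAD) & alive[:, :-1]

    # claims exist from one year before the first panel January: the panel
    # window's opening-year recipients must be traceable through pre-panel
    # claim months, which the January row of the lead-in year stands in for
    obs_mask = alive & (year_mat >= w0 - 1) & (year_mat <= w1)
    ii, kk = np.nonzero(obs_mask)
    obs = pd.DataFrame(
        {
            "latent_id": ii,
            "year": year_mat[ii, kk],
            "age": AGES[kk],
            "sex": np.asarray(SEXES)[sex_idx[ii]],
            "municipality": muni_mat[ii, kk],
            "segment": seg_mat[ii, kk],
            "state6": paths[ii, kk],
            "care_level": pd.Categorical.from_codes(
                lev_mat[ii, kk], categories=list(LEVEL_NAMES)
            ),
            "covered": covered_set[muni_mat[ii, kk]],
            "dies_before_next": dies_next[ii, kk],
            "relocates_after": reloc_mat[ii, kk],
        }
    )
    obs["person_id"] = _person_ids(obs["latent_id"].to_numpy(), obs["segment"].to_numpy())
    obs["eligible"] = obs["state6"].between(LP, HC)

    # ---- claims table ----------------------------------------------------
    cl = obs.loc[obs["eligible"] & obs["covered"]].copy()
    lat = cl["latent_id"].to_numpy()
    cl_birth = birth_date.iloc[lat].reset_index(drop=True)
    reason = np.where(
        cl["dies_before_next"].to_numpy(),
        "death",
        np.where(cl["relocates_after"].to_numpy(), "relocation", None),
    )
    dd = disq_death_date.iloc[lat].reset_index(drop=True)
    rd = pd.to_datetime(
        {
            "year": cl["year"].to_numpy(),
            "month": reloc_month[lat],
            "day": reloc_day[lat],
        }
    )
    disq_date = pd.Series(pd.NaT, index=np.arange(len(cl)), dtype="datetime64[ns]")
    disq_date[reason == "death"] = dd[reason == "death"]
    disq_date[reason == "relocation"] = rd[reason == "relocation"]
    claims = pd.DataFrame(
        {
            "person_id": cl["person_id"].to_numpy(),
            "municipality": cl["municipality"].to_numpy(),
            "sex": cl["sex"].to_numpy(),
            "birth_date": cl_birth.to_numpy(),
            "record_month": cl["year"].astype(str) + "-01",
            "care_level": cl["care_level"].astype(str).to_numpy(),
            "dementia_service_flag": cl["state6"].isin([LC, HC]).to_numpy(),
            "disqualification_date": disq_date.to_numpy(),
            "disqualification_reason": reason,
        }
    )

    # ---- death certificates ---------------------------------------------
    in_win_death = died & (death_year >= w0 - 1) & (death_year <= w1)
    di = np.nonzero(in_win_death)[0]
    deaths = pd.DataFrame(
        {
            "municipality": muni_mat[di, last_alive_k[di]],
            "sex": np.asarray(SEXES)[sex_idx[di]],
            "birth_date": birth_date.iloc[di].to_numpy(),
            "death_date": death_date.iloc[di].to_numpy(),
        }
    )

    persons = pd.DataFrame(
        {
            "latent_id": np.arange(n),
            "sex": np.asarray(SEXES)[sex_idx],
            "birth_year": birth_year,
            "birth_date": birth_date,
            "municipality0": muni0,
            "died": died,
            "last_alive_age": np.where(died, AGES[np.maximum(last_alive_k, 0)], -1),
            "death_year": np.where(died, death_year, -1),
            "death_date": death_date,
        }
    )

    truth = TruthData(
        persons=persons,
        observations=obs,
        state_paths=paths,
        covered_municipalities=covered_munis,
        model=model,
        config=config,
    )
    return claims, deaths, truth


def aggregate_truth(
    truth: TruthData, config: SimConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate the retained truth into population and mortality tables.

    Population counts are alive persons per (year, municipality, sex, age)
    across all municipalities (the resident registration covers everyone,
    also municipalities that do not report claims).  Mortality rates are the
    realized one-year death fractions per (year, sex, age), for origin ages
    65..93 (an age-94 snapshot has no in-scope successor).  Aggregates are
    published for the panel years only; the claims lead-in year is not
    included.
    """
    w0, w1 = truth.config.observation_window
    obs = truth.observations
    obs = obs[(obs["year"] >= w0) & (obs["year"] <= w1)]
    population = (
        obs.groupby(["year", "municipality", "sex", "age"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    sub = obs[obs["age"] <= AGE_MAX - 1]
    mort = (
        sub.groupby(["year", "sex", "age"], observed=True)
        .agg(deaths=("dies_before_next", "sum"), at_risk=("dies_before_next", "size"))
        .reset_index()
    )
    mort["rate"] = mort["deaths"] / mort["at_risk"]
    return population, mort[["year", "sex", "age", "rate", "deaths", "at_risk"]]


# --------------------------------------------------------------------------
# on-disk format


_MANIFEST = {
    "format": "ltcmarkov synthetic tables v1",
    "encoding": {"sex": ["M", "F"], "dates": "ISO-8601"},
    "tables": {
        "claims.csv": {
            "columns": CLAIMS_COLUMNS,
            "notes": "one row per eligible person per January snapshot; "
            "care_level in SL1..CL5 (never independent); disqualification "
            "reason in {death, relocation, independence, other} when present",
        },
        "deaths.csv": {"columns": DEATHS_COLUMNS},
        "population.csv": {"columns": POPULATION_COLUMNS},
        "mortality.csv": {"columns": MORTALITY_COLUMNS},
    },
}


def write_tables(
    outdir: str | Path,
    claims: pd.DataFrame,
    deaths: pd.DataFrame,
    population: pd.DataFrame,
    mortality: pd.DataFrame,
) -> None:
    """Write the four tables as CSV plus a YAML schema manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    claims.to_csv(outdir / "claims.csv", index=False, date_format="%Y-%m-%d")
    deaths.to_csv(outdir / "deaths.csv", index=False, date_format="%Y-%m-%d")
    population.to_csv(outdir / "population.csv", index=False)
    mortality.to_csv(outdir / "mortality.csv", index=False)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(_MANIFEST, fh, sort_keys=False)
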