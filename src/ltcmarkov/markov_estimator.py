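"""Age- and sex-stratified one-year transition matrix estimation.

The estimator is a first-order Markov chain: within each (sex, origin age,
year) stratum the transition probability to each destination is the
empirical frequency among persons at risk.  Per-year matrices are then
combined into a single matrix per (sex, age) by population-weighted
averaging, correcting for cohort and municipal population variation across
observation years.  Death is absorbing, its row fixed to a unit vector, so
a 4-state chain has 12 free transition patterns and a 5-state chain 20.

Claims only cover the insured; the no-disability row cannot be counted
directly.  It is completed residually from aggregated population and
mortality tables: new entrants over the non-disabled population for the
onset cells, and total cohort deaths minus deaths among the insured over
the non-disabled population for mortality.

Rows with fewer at-risk persons than ``min_cell`` are flagged unstable and
excluded from weighting (with weight renormalization); they are never
silently zero-filled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_data import AGE_MAX, AGE_MIN, SEXES

logger = logging.getLogger(__name__)

STATUS4_STATES = ("no_disability", "light", "heavy", "death")
STATUS5_STATES = (
    "light_physical",
    "light_cognitive",
    "heavy_physical",
    "heavy_cognitive",
    "death",
)

#: origin ages: a 94-year-old has no in-scope 95th-year destination
ORIGIN_AGES = np.arange(AGE_MIN, AGE_MAX)  # 65..93
N_ORIGIN_AGES = len(ORIGIN_AGES)

DEFAULT_MIN_CELL = 50


def states_for_scheme(scheme: int) -> tuple[str, ...]:
    if scheme == 4:
        return STATUS4_STATES
    if scheme == 5:
        return STATUS5_STATES
    raise ValueError(f"scheme must be 4 or 5, got {scheme}")


class AssemblyError(ValueError):
    """A complete matrix set cannot be assembled; lists the missing rows."""


# --------------------------------------------------------------------------
# containers


@dataclass
class TransitionCounts:
    """Observed (origin → destination) pair counts.

    ``counts`` has shape (n_years, 2 sexes, 29 origin ages, K, K); the
    death-origin row is structurally zero.  At-risk totals are the
    destination sums.
    """

    scheme: int
    years: np.ndarray
    counts: np.ndarray

    @property
    def states(self) -> tuple[str, ...]:
        return states_for_scheme(self.scheme)

    @property
    def at_risk(self) -> np.ndarray:
        return self.counts.sum(axis=-1)


@dataclass
class PerYearMatrices:
    """Per-year empirical transition matrices with stability flags."""

    scheme: int
    years: np.ndarray
    probs: np.ndarray  # (Y, 2, A, K, K); NaN where at-risk is zero
    at_risk: np.ndarray  # (Y, 2, A, K)
    flagged: np.ndarray  # (Y, 2, A, K) bool
    min_cell: int


@dataclass
class TransitionMatrixSet:
    """(sex, age) → row-stochastic K×K matrix with death absorbing.

    ``probs`` has shape (2, n_ages, K, K), indexed by sex (M, F) and origin
    age.  Flagged rows are unstable (insufficient at-risk persons) and hold
    NaN; downstream simulation refuses them unless explicitly allowed, in
    which case they carry the state (identity row).
    """

    scheme: int
    ages: np.ndarray
    probs: np.ndarray
    at_risk: np.ndarray  # (2, n_ages, K)
    flagged: np.ndarray  # (2, n_ages, K) bool
    metadata: dict = field(default_factory=dict)

    @property
    def states(self) -> tuple[str, ...]:
        return states_for_scheme(self.scheme)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_free_patterns(self) -> int:
        """Free transition patterns per (sex, age): all rows but death."""
        k = self.n_states
        return k * (k - 1)

    def sex_index(self, sex: str) -> int:
        return SEXES.index(sex)

    def matrix(self, sex: str, age: int) -> np.ndarray:
        return self.probs[self.sex_index(sex), int(np.searchsorted(self.ages, age))]

    def validate(self, atol: float = 1e-9) -> None:
        k = self.n_states
        death = k - 1
        if not (self.probs[:, :, death, death] == 1.0).all():
            raise ValueError("death row is not absorbing")
        if self.probs[:, :, death, :death].any():
            raise ValueError("death row leaks probability")
        ok = ~self.flagged
        rows = self.probs[ok]
        if rows.size:
            if not np.isfinite(rows).all():
                raise ValueError("unflagged rows contain non-finite entries")
            if (rows < -atol).any() or (rows > 1 + atol).any():
                raise ValueError("probabilities outside [0, 1]")
            if np.abs(rows.sum(axis=-1) - 1.0).max() > atol:
                raise ValueError("rows do not sum to 1")

    def effective_probs(self, allow_flagged: bool = False) -> np.ndarray:
        """Probabilities with flagged rows replaced by identity (carry state).

        Raises unless ``allow_flagged`` when any flagged row exists; callers
        that know flagged rows are unreachable pass ``allow_flagged=True``
        (the substitution then never fires for occupied states).
        """
        if not allow_flagged and self.flagged.any():
            idx = np.argwhere(self.flagged)
            s, a, o = idx[0]
            raise ValueError(
                f"flagged (unstable) rows present, e.g. sex={SEXES[s]} "
                f"age={self.ages[a]} origin={self.states[o]}; pass "
                f"allow_flagged=True to carry the state through them"
            )
        probs = self.probs.copy()
        si, ai, oi = np.nonzero(self.flagged)
        probs[si, ai, oi, :] = 0.0
        probs[si, ai, oi, oi] = 1.0
        return probs

    # -- serialization -----------------------------------------------------

    def to_long(self) -> pd.DataFrame:
        """Long-format frame (sex, age, origin, destination, probability,
        at_risk, flagged)."""
        k = self.n_states
        s_idx, a_idx, o_idx, d_idx = np.meshgrid(
            np.arange(2), np.arange(len(self.ages)), np.arange(k), np.arange(k),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "sex": np.asarray(SEXES)[s_idx.ravel()],
                "age": self.ages[a_idx.ravel()],
                "origin": np.asarray(self.states)[o_idx.ravel()],
                "destination": np.asarray(self.states)[d_idx.ravel()],
                "probability": self.probs.ravel(),
                "at_risk": self.at_risk[
                    s_idx.ravel(), a_idx.ravel(), o_idx.ravel()
                ],
                "flagged": self.flagged[
                    s_idx.ravel(), a_idx.ravel(), o_idx.ravel()
                ],
            }
        )

    def save(self, path: str | Path) -> None:
        payload = {
            "scheme": self.scheme,
            "states": list(self.states),
            "ages": self.ages.tolist(),
            "probs": np.where(np.isfinite(self.probs), self.probs, None).tolist(),
            "at_risk": self.at_risk.tolist(),
            "flagged": self.flagged.tolist(),
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "TransitionMatrixSet":
        with open(path) as fh:
            payload = json.load(fh)
        probs = np.array(
            [
                [[[np.nan if v is None else v for v in row] for row in mat]
                 for mat in per_sex]
                for per_sex in payload["probs"]
            ],
            dtype=float,
        )
        return cls(
            scheme=payload["scheme"],
            ages=np.asarray(payload["ages"]),
            probs=probs,
            at_risk=np.asarray(payload["at_risk"], dtype=float),
            flagged=np.asarray(payload["flagged"], dtype=bool),
            metadata=payload.get("metadata", {}),
        )


# --------------------------------------------------------------------------
# counting and per-year estimation


def count_transitions(panel: pd.DataFrame, scheme: int = 4) -> TransitionCounts:
    """Tabulate observed one-year (origin → destination) pairs.

    Counts are stratified by (year, sex, origin age); censored observations
    (missing next status) contribute nothing, and no transition ever
    originates from death.  Origin years without a successor snapshot in
    the panel (in particular the final observation year) are excluded
    outright: there the only observable outcome is death, so including
    them would condition the risk set on dying.
    """
    states = states_for_scheme(scheme)
    col, nxt_col = ("status4", "next_status4") if scheme == 4 else (
        "status5", "next_status5"
    )
    years = np.sort(panel["year"].unique())
    has_successor = {int(y) for y in years if (y + 1) in years}
    sub = panel.dropna(subset=[col, nxt_col])
    sub = sub[sub["year"].isin(has_successor)]
    sub = sub[sub["age"].between(ORIGIN_AGES[0], ORIGIN_AGES[-1])]
    counts = np.zeros(
        (len(years), 2, N_ORIGIN_AGES, len(states), len(states)), dtype=np.int64
    )
    if not sub.empty:
        state_code = {s: i for i, s in enumerate(states)}
        yi = np.searchsorted(years, sub["year"].to_numpy())
        si = (sub["sex"].to_numpy() == "F").astype(int)
        ai = sub["age"].to_numpy() - ORIGIN_AGES[0]
        oi = sub[col].map(state_code).to_numpy()
        di = sub[nxt_col].map(state_code).to_numpy()
        if (oi == len(states) - 1).any():
            raise ValueError("transitions originating from death are invalid")
        np.add.at(counts, (yi, si, ai, oi, di), 1)
    return TransitionCounts(scheme=scheme, years=years, counts=counts)


def counts_to_probabilities(
    counts: TransitionCounts, min_cell: int = DEFAULT_MIN_CELL
) -> PerYearMatrices:
    """Maximum-likelihood per-year matrices: count / at-risk per row.

    Rows with fewer than ``min_cell`` at-risk persons are flagged unstable;
    zero-at-risk rows are additionally marked undefined (NaN).  The death
    row is set to the absorbing unit vector and never flagged.
    """
    at_risk = counts.at_risk.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts.counts / at_risk[..., None]
    flagged = at_risk < min_cell
    k = len(counts.states)
    probs[..., k - 1, :] = 0.0
    probs[..., k - 1, k - 1] = 1.0
    flagged[..., k - 1] = False
    return PerYearMatrices(
        scheme=counts.scheme,
        years=counts.years,
        probs=probs,
        at_risk=at_risk,
        flagged=flagged,
        min_cell=min_cell,
    )


# --------------------------------------------------------------------------
# population weighting


@dataclass
class WeightTable:
    """(year, sex, age) → population weight, normalized per (sex, age)."""

    frame: pd.DataFrame  # columns year, sex, age, weight

    @classmethod
    def from_population(
        cls,
        population: pd.DataFrame,
        covered_municipalities=None,
        ages: np.ndarray = ORIGIN_AGES,
    ) -> "WeightTable":
        """Weights proportional to covered-strata resident population."""
        pop = population
        if covered_municipalities is not None:
            pop = pop[pop["municipality"].isin(np.asarray(covered_municipalities))]
        w = (
            pop[pop["age"].isin(ages)]
            .groupby(["year", "sex", "age"], observed=True)["count"]
            .sum()
            .rename("weight")
            .reset_index()
        )
        total = w.groupby(["sex", "age"], observed=True)["weight"].transform("sum")
        w["weight"] = w["weight"] / total
        return cls(frame=w)

    @classmethod
    def uniform(cls, years, ages: np.ndarray = ORIGIN_AGES) -> "WeightTable":
        grid = pd.MultiIndex.from_product(
            [years, SEXES, ages], names=["year", "sex", "age"]
        ).to_frame(index=False)
        grid["weight"] = 1.0 / len(years)
        return cls(frame=grid)

    def as_array(self, years: np.ndarray, ages: np.ndarray = ORIGIN_AGES) -> np.ndarray:
        """Dense (n_years, 2, n_ages) array; missing strata get weight 0."""
        out = np.zeros((len(years), 2, len(ages)))
        yi = {int(y): i for i, y in enumerate(years)}
        ai = {int(a): i for i, a in enumerate(ages)}
        for row in self.frame.itertuples(index=False):
            if int(row.year) in yi and int(row.age) in ai:
                out[yi[int(row.year)], SEXES.index(row.sex), ai[int(row.age)]] = (
                    row.weight
                )
        return out


def weight_average(
    per_year: PerYearMatrices, weights: WeightTable
) -> TransitionMatrixSet:
    """Population-weighted convex combination of per-year matrices.

    Unstable (flagged) per-year rows are excluded with weight
    renormalization over the remaining years; if every contributing row is
    unstable the output row is flagged.  With uniform weights and no flags
    this reduces to the pooled-count estimator.
    """
    Y, _, A, K, _ = per_year.probs.shape
    W = weights.as_array(per_year.years)  # (Y, 2, A)
    usable = ~per_year.flagged  # (Y, 2, A, K)
    w_eff = W[..., None] * usable
    norm = w_eff.sum(axis=0)  # (2, A, K)
    num = np.nansum(
        w_eff[..., None] * np.nan_to_num(per_year.probs, nan=0.0), axis=0
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = num / norm[..., None]
    flagged = norm <= 0.0
    probs[flagged] = np.nan

    death = K - 1
    probs[:, :, death, :] = 0.0
    probs[:, :, death, death] = 1.0
    flagged[:, :, death] = False

    # renormalize away floating-point drift on unflagged live rows
    sums = probs.sum(axis=-1, keepdims=True)
    good = (~flagged)[..., None] & np.isfinite(sums) & (sums > 0)
    probs = np.where(good, probs / np.where(good, sums, 1.0), probs)

    mset = TransitionMatrixSet(
        scheme=per_year.scheme,
        ages=ORIGIN_AGES.copy() if A == N_ORIGIN_AGES else np.arange(A) + AGE_MIN,
        probs=probs,
        at_risk=per_year.at_risk.sum(axis=0),
        flagged=flagged,
        metadata={
            "weighting": "population",
            "min_cell": per_year.min_cell,
            "years": per_year.years.tolist(),
        },
    )
    return mset


# --------------------------------------------------------------------------
# residual no-disability row


@dataclass
class NoDisabilityRows:
    """Per-(sex, age) transition row out of the uninsured no-disability state."""

    probs: np.ndarray  # (2, A, 4) in STATUS4_STATES order
    at_risk: np.ndarray  # (2, A) total non-disabled person-years
    flagged: np.ndarray  # (2, A) bool
    diagnostics: dict = field(default_factory=dict)


def _nd_row_from_counts(
    n_nd: float,
    light_entrants: float,
    heavy_entrants: float,
    residual_deaths: float,
) -> np.ndarray:
    """The residual no-disability row given stratum counts.

    P(→light) and P(→heavy) are new-entrant fractions of the non-disabled
    population; P(→death) is the residual death fraction (total cohort
    deaths minus deaths among the insured), floored at zero; P(→stay) is
    the complement.
    """
    if n_nd <= 0:
        raise ValueError(f"non-disabled population must be positive, got {n_nd}")
    p_light = light_entrants / n_nd
    p_heavy = heavy_entrants / n_nd
    p_death = max(residual_deaths, 0.0) / n_nd
    p_stay = 1.0 - p_light - p_heavy - p_death
    return np.array([p_stay, p_light, p_heavy, p_death])


def estimate_nodisability_row(
    panel: pd.DataFrame,
    population: pd.DataFrame,
    mortality: pd.DataFrame,
    covered_municipalities=None,
    min_cell: int = DEFAULT_MIN_CELL,
    max_origin_year: int | None = None,
) -> NoDisabilityRows:
    """Complete the no-disability row from aggregated population data.

    For each (year, sex, origin age): the non-disabled population is the
    resident population minus the insured count from the panel; onset
    probabilities are new panel entrants (person ids absent the year
    before) over that denominator; mortality is total cohort deaths (rate ×
    population) minus deaths observed among the insured, floored at zero
    when negative (and logged).  Per-year rows are averaged with weights
    proportional to the non-disabled population.

    Entrants first seen in the final observation January cannot be told
    apart from never-traced records dropped by the two-consecutive-year
    rule, so origin years are capped at two before the last panel year
    (override with ``max_origin_year``).
    """
    years = np.sort(panel["year"].unique())
    if max_origin_year is None:
        max_origin_year = int(years.max()) - 2
    origin_years = [int(y) for y in years if y <= max_origin_year and (y + 1) in years]

    pop = population
    if covered_municipalities is not None:
        pop = pop[pop["municipality"].isin(np.asarray(covered_municipalities))]
    pop_ysa = (
        pop.groupby(["year", "sex", "age"], observed=True)["count"].sum().to_dict()
    )
    rate_ysa = {
        (int(r.year), r.sex, int(r.age)): r.rate
        for r in mortality.itertuples(index=False)
    }

    elig = panel.groupby(["year", "sex", "age"], observed=True).size().to_dict()
    elig_deaths = (
        panel[panel["next_status4"] == "death"]
        .groupby(["year", "sex", "age"], observed=True)
        .size()
        .to_dict()
    )

    # new entrants: panel persons with no record in the preceding year
    prev = panel[["person_id", "year"]].drop_duplicates().copy()
    prev["year"] += 1
    prev["seen_before"] = True
    ent = panel.merge(prev, on=["person_id", "year"], how="left")
    ent = ent[ent["seen_before"].isna() & ent["year"].isin([y + 1 for y in origin_years])]
    ent_counts = (
        ent.groupby(["year", "sex", "age", "status4"], observed=True).size().to_dict()
    )

    A = N_ORIGIN_AGES
    probs = np.full((2, A, 4), np.nan)
    at_risk = np.zeros((2, A))
    flagged = np.ones((2, A), dtype=bool)
    n_neg_residual = 0
    n_nonpos_nd = 0

    for s_i, sex in enumerate(SEXES):
        for a_i, age in enumerate(ORIGIN_AGES):
            rows, wts = [], []
            for y in origin_years:
                n_pop = pop_ysa.get((y, sex, int(age)), 0)
                n_elig = elig.get((y, sex, int(age)), 0)
                n_nd = n_pop - n_elig
                rate = rate_ysa.get((y, sex, int(age)))
                if n_nd <= 0 or rate is None:
                    n_nonpos_nd += n_nd <= 0
                    continue
                lights = ent_counts.get((y + 1, sex, int(age) + 1, "light"), 0)
                heavies = ent_counts.get((y + 1, sex, int(age) + 1, "heavy"), 0)
                total_deaths = rate * n_pop
                resid = total_deaths - elig_deaths.get((y, sex, int(age)), 0)
                if resid < 0:
                    n_neg_residual += 1
                rows.append(_nd_row_from_counts(n_nd, lights, heavies, resid))
                wts.append(n_nd)
            if rows:
                wts = np.asarray(wts, dtype=float)
                probs[s_i, a_i] = (np.asarray(rows) * (wts / wts.sum())[:, None]).sum(
                    axis=0
                )
                at_risk[s_i, a_i] = wts.sum()
                flagged[s_i, a_i] = at_risk[s_i, a_i] < min_cell

    if n_neg_residual:
        logger.warning(
            "no-disability row: %d strata had negative residual deaths "
            "(floored at zero)",
            n_neg_residual,
        )
    return NoDisabilityRows(
        probs=probs,
        at_risk=at_risk,
        flagged=flagged,
        diagnostics={
            "origin_years": origin_years,
            "negative_residual_strata": n_neg_residual,
            "nonpositive_nd_strata": int(n_nonpos_nd),
        },
    )


# --------------------------------------------------------------------------
# assembly


def assemble(
    eligible: TransitionMatrixSet,
    nd_rows: NoDisabilityRows | None = None,
) -> TransitionMatrixSet:
    """Assemble the complete matrix set, inserting the no-disability row.

    For the 4-state scheme the claims-based matrices carry no information
    on the no-disability origin, so ``nd_rows`` is mandatory; omitting it
    raises :class:`AssemblyError` listing the missing (sex, age, origin)
    rows.  The 5-state scheme has no such row.
    """
    probs = eligible.probs.copy()
    at_risk = eligible.at_risk.copy().astype(float)
    flagged = eligible.flagged.copy()
    if eligible.scheme == 4:
        if nd_rows is None:
            missing = [
                (sex, int(age), "no_disability")
                for sex in SEXES
                for age in eligible.ages
            ]
            raise AssemblyError(
                f"no-disability rows missing for {len(missing)} strata, "
                f"e.g. {missing[:3]}"
            )
        probs[:, :, 0, :] = nd_rows.probs
        at_risk[:, :, 0] = nd_rows.at_risk
        flagged[:, :, 0] = nd_rows.flagged
    out = TransitionMatrixSet(
        scheme=eligible.scheme,
        ages=eligible.ages,
        probs=probs,
        at_risk=at_risk,
        flagged=flagged,
        metadata={**eligible.metadata, "assembled": True},
    )
    out.validate()
    return out
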