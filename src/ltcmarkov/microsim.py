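"""Monte Carlo trajectory simulation, its exact oracle, and validation.

Given the estimated one-year transition matrices, lifetime disability and
mortality profiles can be computed two ways:

* exactly, by Chapman–Kolmogorov forward propagation of the state
  occupancy vector through the age-ordered matrices, and
* by Monte Carlo, sampling individual state paths from age 65 onward
  (the emulated analysis uses 500,000 trials).

Both yield :class:`RateProfile` objects — eligibility prevalence among
survivors, one-year mortality, and per-state prevalence by (sex, age) —
which are compared against the observed raw-data profiles with a
maximum-absolute-difference statistic in percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov_estimator import TransitionMatrixSet
from .synthetic_data import AGE_MIN, SEXES

PROFILE_KINDS = ("eligibility_prevalence", "one_year_mortality", "state_prevalence")


@dataclass
class RateProfile:
    """(sex, age) → rate in [0, 1] of a given kind and source."""

    kind: str
    source: str  # observed | simulated | analytic
    ages: np.ndarray
    rates: np.ndarray  # (2, n_ages), row order (M, F)
    metadata: dict = field(default_factory=dict)

    def rate(self, sex: str, age: int) -> float:
        return float(self.rates[SEXES.index(sex), np.searchsorted(self.ages, age)])

    def to_frame(self) -> pd.DataFrame:
        s, a = np.meshgrid(np.arange(2), np.arange(len(self.ages)), indexing="ij")
        return pd.DataFrame(
            {
                "sex": np.asarray(SEXES)[s.ravel()],
                "age": self.ages[a.ravel()],
                "kind": self.kind,
                "source": self.source,
                "rate": self.rates.ravel(),
            }
        )


@dataclass
class ProfileSet:
    """Occupancy plus the derived rate profiles from one computation."""

    source: str
    states: tuple[str, ...]
    ages: np.ndarray  # occupancy ages (origins plus one)
    occupancy: np.ndarray  # (2, n_ages, K)
    eligibility: RateProfile
    mortality: RateProfile
    state_prevalence: RateProfile  # rates (2, n_ages, K_live) among survivors


@dataclass
class TrajectorySample:
    """Monte Carlo state paths, ages 65..(last origin + 1), death absorbing."""

    paths: np.ndarray  # (2, n_trials, n_ages) int8 state codes
    states: tuple[str, ...]
    ages: np.ndarray
    n_trials: int
    seed: int
    init: np.ndarray  # (2, K)


def _live_slice(states: tuple[str, ...]) -> slice:
    return slice(0, len(states) - 1)  # death is always last


def _eligible_indices(states: tuple[str, ...]) -> list[int]:
    return [i for i, s in enumerate(states) if s not in ("no_disability", "death")]


def _profiles_from_occupancy(
    occupancy: np.ndarray, states: tuple[str, ...], ages: np.ndarray, source: str
) -> ProfileSet:
    k = len(states)
    death = k - 1
    alive = 1.0 - occupancy[..., death]  # (2, n_ages)
    elig_idx = _eligible_indices(states)
    with np.errstate(invalid="ignore", divide="ignore"):
        elig = occupancy[..., elig_idx].sum(axis=-1) / alive
        live_prev = occupancy[..., :death] / alive[..., None]
        mort = (occupancy[:, 1:, death] - occupancy[:, :-1, death]) / alive[:, :-1]
    eligibility = RateProfile(
        kind="eligibility_prevalence",
        source=source,
        ages=ages,
        rates=elig,
        metadata={"denominator": "alive"},
    )
    mortality = RateProfile(
        kind="one_year_mortality", source=source, ages=ages[:-1], rates=mort
    )
    state_prev = RateProfile(
        kind="state_prevalence",
        source=source,
        ages=ages,
        rates=live_prev,
        metadata={"states": list(states[:death]), "denominator": "alive"},
    )
    return ProfileSet(
        source=source,
        states=states,
        ages=ages,
        occupancy=occupancy,
        eligibility=eligibility,
        mortality=mortality,
        state_prevalence=state_prev,
    )


def _as_init(init, k: int) -> np.ndarray:
    init = np.asarray(init, dtype=float)
    if init.shape == (k,):
        init = np.tile(init, (2, 1))
    if init.shape != (2, k):
        raise ValueError(f"init must have shape ({k},) or (2, {k}), got {init.shape}")
    if not np.allclose(init.sum(axis=1), 1.0, atol=1e-9) or (init < 0).any():
        raise ValueError("init rows must be distributions summing to 1")
    return init


def forward_propagate(
    matrices: TransitionMatrixSet,
    init,
    allow_flagged: bool = False,
) -> ProfileSet:
    """Exact Chapman–Kolmogorov propagation of the age-65 distribution.

    The occupancy vector at each age is the initial distribution
    left-multiplied by the age-ordered matrices.  Flagged rows raise unless
    ``allow_flagged`` (they then carry the state, an identity row).
    """
    k = matrices.n_states
    init = _as_init(init, k)
    probs = matrices.effective_probs(allow_flagged=allow_flagged)
    n_ages = len(matrices.ages) + 1
    occ = np.zeros((2, n_ages, k))
    occ[:, 0, :] = init
    for a in range(n_ages - 1):
        for s in range(2):
            occ[s, a + 1] = occ[s, a] @ probs[s, a]
    ages = np.concatenate([matrices.ages, [matrices.ages[-1] + 1]])
    return _profiles_from_occupancy(occ, matrices.states, ages, source="analytic")


def simulate_trajectories(
    matrices: TransitionMatrixSet,
    n_trials: int = 500_000,
    init=None,
    seed: int = 0,
    allow_flagged: bool = False,
) -> TrajectorySample:
    """Monte Carlo sampling of individual state paths from age 65.

    Each trial draws its age-65 state from ``init`` and then successive
    states from the (sex, age) matrices; reproducible given ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    k = matrices.n_states
    init = _as_init(init, k)
    probs = matrices.effective_probs(allow_flagged=allow_flagged)
    rng = np.random.default_rng(seed)
    n_ages = len(matrices.ages) + 1
    paths = np.zeros((2, n_trials, n_ages), dtype=np.int8)
    for s in range(2):
        cum0 = np.cumsum(init[s])
        cum0[-1] = 1.0
        paths[s, :, 0] = np.searchsorted(cum0, rng.random(n_trials), side="right")
        for a in range(n_ages - 1):
            cur = paths[s, :, a]
            nxt = cur.copy()
            for state in range(k - 1):  # death is absorbing
                m = cur == state
                if not m.any():
                    continue
                cum = np.cumsum(probs[s, a, state])
                cum[-1] = 1.0
                nxt[m] = np.searchsorted(cum, rng.random(int(m.sum())), side="right")
            paths[s, :, a + 1] = nxt
    ages = np.concatenate([matrices.ages, [matrices.ages[-1] + 1]])
    return TrajectorySample(
        paths=paths,
        states=matrices.states,
        ages=ages,
        n_trials=n_trials,
        seed=seed,
        init=init,
    )


def profile_from_sample(sample: TrajectorySample) -> ProfileSet:
    """Empirical occupancy and rate profiles from a trajectory sample.

    Rates at ages where no trial remains alive are undefined (NaN).
    """
    k = len(sample.states)
    occ = np.zeros((2, len(sample.ages), k))
    for s in range(2):
        for a in range(len(sample.ages)):
            occ[s, a] = np.bincount(sample.paths[s, :, a], minlength=k)
    occ /= sample.n_trials
    return _profiles_from_occupancy(
        occ, sample.states, sample.ages, source="simulated"
    )


def max_abs_difference(simulated: RateProfile, observed: RateProfile) -> float:
    """Maximum over (sex, age) of |simulated − observed|, in percentage points.

    The two profiles must share their (sex, age) support exactly and be
    fully defined on it.
    """
    if simulated.ages.shape != observed.ages.shape or not np.array_equal(
        simulated.ages, observed.ages
    ):
        raise ValueError(
            f"age support mismatch: {simulated.ages} vs {observed.ages}"
        )
    if simulated.rates.shape != observed.rates.shape:
        raise ValueError("rate array shapes differ")
    diff = simulated.rates - observed.rates
    if not np.isfinite(diff).all():
        raise ValueError("profiles contain undefined rates on the shared support")
    return float(np.abs(diff).max() * 100.0)


# --------------------------------------------------------------------------
# observed (raw-data) profiles


def observed_profiles(
    panel: pd.DataFrame,
    population: pd.DataFrame,
    mortality: pd.DataFrame,
    covered_municipalities=None,
    ages: np.ndarray | None = None,
) -> tuple[RateProfile, RateProfile]:
    """Raw eligibility-prevalence and mortality profiles by (sex, age).

    Prevalence is insured persons over resident population (covered strata),
    pooled over observation years; mortality is the population-weighted
    pooled death rate from the aggregated mortality table, covering origin
    ages only.
    """
    pop = population
    if covered_municipalities is not None:
        pop = pop[pop["municipality"].isin(np.asarray(covered_municipalities))]
    pop_sa = pop.groupby(["sex", "age"], observed=True)["count"].sum()
    if ages is None:
        ages = np.arange(AGE_MIN, int(panel["age"].max()) + 1)

    elig_sa = panel.groupby(["sex", "age"], observed=True).size()
    prev = np.full((2, len(ages)), np.nan)
    for s_i, sex in enumerate(SEXES):
        for a_i, age in enumerate(ages):
            denom = pop_sa.get((sex, int(age)), 0)
            if denom > 0:
                prev[s_i, a_i] = elig_sa.get((sex, int(age)), 0) / denom
    eligibility = RateProfile(
        kind="eligibility_prevalence",
        source="observed",
        ages=ages,
        rates=prev,
        metadata={"denominator": "alive"},
    )

    pop_ysa = pop.groupby(["year", "sex", "age"], observed=True)["count"].sum()
    m = mortality.copy()
    m["pop"] = [
        pop_ysa.get((int(r.year), r.sex, int(r.age)), 0)
        for r in m.itertuples(index=False)
    ]
    m["expected_deaths"] = m["rate"] * m["pop"]
    pooled = m.groupby(["sex", "age"], observed=True)[["expected_deaths", "pop"]].sum()
    mort_ages = ages[:-1]
    mort = np.full((2, len(mort_ages)), np.nan)
    for s_i, sex in enumerate(SEXES):
        for a_i, age in enumerate(mort_ages):
            if (sex, int(age)) in pooled.index:
                row = pooled.loc[(sex, int(age))]
                if row["pop"] > 0:
                    mort[s_i, a_i] = row["expected_deaths"] / row["pop"]
    mortality_profile = RateProfile(
        kind="one_year_mortality", source="observed", ages=mort_ages, rates=mort
    )
    return eligibility, mortality_profile


def initial_distribution(
    panel: pd.DataFrame,
    population: pd.DataFrame,
    scheme: int = 4,
    covered_municipalities=None,
) -> np.ndarray:
    """Observed cross-sectional state distribution at age 65, per sex.

    For the 4-state scheme the non-disabled complement comes from the
    population table; the 5-state scheme (insured persons only) uses the
    panel shares at 65, falling back to all-light-physical when no insured
    65-year-old is observed.
    """
    from .markov_estimator import states_for_scheme

    states = states_for_scheme(scheme)
    pop = population
    if covered_municipalities is not None:
        pop = pop[pop["municipality"].isin(np.asarray(covered_municipalities))]
    pop65 = pop[pop["age"] == AGE_MIN].groupby("sex", observed=True)["count"].sum()
    at65 = panel[panel["age"] == AGE_MIN]
    col = "status4" if scheme == 4 else "status5"
    counts = at65.groupby(["sex", col], observed=True).size()

    init = np.zeros((2, len(states)))
    for s_i, sex in enumerate(SEXES):
        per_state = np.array(
            [counts.get((sex, st), 0) for st in states[:-1]], dtype=float
        )
        if scheme == 4:
            denom = float(pop65.get(sex, 0))
            if denom <= 0:
                init[s_i, 0] = 1.0
                continue
            per_state[0] = denom - per_state[1:].sum()  # non-disabled complement
            init[s_i, :-1] = per_state / denom
        else:
            total = per_state.sum()
            if total <= 0:
                init[s_i, 0] = 1.0
            else:
                init[s_i, :-1] = per_state / total
    return init
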