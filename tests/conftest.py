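"""Shared fixtures: synthetic worlds and independent truth-recount oracles.

The oracle functions re-derive inclusion, linkage and counting rules
directly from the retained ground truth (latent state paths and the
observation table) with plain pandas/numpy, independently of the package's
merge-based implementations, so tests can reconcile pipeline outputs
against brute-force recounts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import ltcmarkov as ltc


@dataclass
class World:
    model: ltc.TrueModel
    config: ltc.SimConfig
    claims: pd.DataFrame
    deaths: pd.DataFrame
    truth: ltc.TruthData
    population: pd.DataFrame
    mortality: pd.DataFrame


def build_world(**kwargs) -> World:
    model_params = kwargs.pop("model_params", {})
    config = ltc.SimConfig(**kwargs)
    model = ltc.make_true_model(model_params)
    claims, deaths, truth = ltc.simulate_population(model, config)
    population, mortality = ltc.aggregate_truth(truth)
    return World(model, config, claims, deaths, truth, population, mortality)


@pytest.fixture(scope="session")
def small_world() -> World:
    """Realistic defaults (relocation on), small enough for quick tests."""
    return build_world(n_individuals=3000, seed=11)


@pytest.fixture(scope="session")
def small_pipeline(small_world):
    appended, flow = ltc.apply_flowchart(
        small_world.claims,
        small_world.deaths,
        window=small_world.config.observation_window,
    )
    panel = ltc.build_panel(appended)
    return appended, flow, panel


# --------------------------------------------------------------------------
# truth oracles (brute-force recounts)


def oracle_claims_universe(truth: ltc.TruthData) -> pd.DataFrame:
    """All person-January rows that must appear as claims records."""
    obs = truth.observations
    return obs[obs["eligible"] & obs["covered"]].copy()


def oracle_deceased_set(truth: ltc.TruthData) -> pd.DataFrame:
    """Claims rows whose person dies before the next January (the linkable
    death-disqualification rows), with the true death date attached."""
    uni = oracle_claims_universe(truth)
    dying = uni[uni["dies_before_next"]].copy()
    death_dates = truth.persons.set_index("latent_id")["death_date"]
    dying["death_date"] = dying["latent_id"].map(death_dates)
    return dying


def oracle_unique_key_deaths(deaths: pd.DataFrame) -> pd.DataFrame:
    """Death certificates whose full linkage key (municipality, sex, birth
    date, death date) is unique — the subset any deterministic rule can
    resolve."""
    key = ["municipality", "sex", "birth_date", "death_date"]
    return deaths[~deaths.duplicated(key, keep=False)]


def oracle_flowchart(truth: ltc.TruthData, deaths: pd.DataFrame) -> dict:
    """Independent re-derivation of the inclusion flowchart from truth.

    Returns the expected record count after each stage plus the final
    unique-person count, using set logic over the observation table rather
    than the package's merge implementation.
    """
    w0, w1 = truth.config.observation_window
    uni = oracle_claims_universe(truth)

    # disqualification rows: death or relocation on the final segment row
    is_disq = uni["dies_before_next"] | uni["relocates_after"]
    disq = uni[is_disq]
    nondisq = uni[~is_disq]

    # linkage: death rows whose certificate key is unique
    dd = oracle_deceased_set(truth)
    cert_counts = deaths.groupby(
        ["municipality", "sex", "birth_date", "death_date"]
    ).size()
    bdates = truth.persons.set_index("latent_id")["birth_date"]
    key = pd.MultiIndex.from_arrays(
        [
            dd["municipality"].to_numpy(),
            dd["sex"].to_numpy(),
            dd["latent_id"].map(bdates).to_numpy(),
            dd["death_date"].to_numpy(),
        ]
    )
    n_match = cert_counts.reindex(key).fillna(0).to_numpy()
    linked = dd[n_match == 1]

    appended = pd.concat([nondisq, linked.drop(columns=["death_date"])])

    # traced two consecutive years (death counts as the second year)
    years = appended.groupby("person_id")["year"].agg(sorted)
    has_pair = years[years.map(lambda ys: any(b - a == 1 for a, b in zip(ys, ys[1:])))]
    died_persons = set(linked["person_id"])
    traced = set(has_pair.index) | died_persons
    traced_rows = appended[appended["person_id"].isin(traced)]

    final = traced_rows[traced_rows["year"].between(w0, w1)]
    return {
        "n_claims": len(uni),
        "n_disqualified": len(disq),
        "n_nondisqualified": len(nondisq),
        "n_linked": len(linked),
        "n_ambiguous": int((n_match > 1).sum()),
        "n_appended": len(appended),
        "n_traced": len(traced_rows),
        "final_records": len(final),
        "final_unique_persons": final["person_id"].nunique(),
    }


def oracle_transition_counts(
    truth: ltc.TruthData, panel: pd.DataFrame, sex: str, age: int
) -> np.ndarray:
    """Brute-force 4-state pair tabulation from latent paths, restricted to
    the persons and years actually present in the panel at (sex, age)."""
    paths = truth.state_paths
    to4 = np.array([0, 1, 1, 2, 2, 3])
    k = age - 65
    sub = panel[
        (panel["sex"] == sex) & (panel["age"] == age) & panel["next_status4"].notna()
    ]
    years = np.sort(panel["year"].unique())
    sub = sub[sub["year"].isin([y for y in years if y + 1 in years])]
    lat = sub["person_id"].str.slice(1).astype(np.int64) // 100
    counts = np.zeros((4, 4), dtype=int)
    np.add.at(counts, (to4[paths[lat, k]], to4[paths[lat, k + 1]]), 1)
    return counts


@pytest.fixture(scope="session")
def oracles():
    """Namespace handle for the truth-recount helpers."""
    import conftest

    return conftest
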