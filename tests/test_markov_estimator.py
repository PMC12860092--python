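"""Transition counting, per-year estimation, weighting, assembly."""

import numpy as np
import pandas as pd
import pytest

import ltcmarkov as ltc
from ltcmarkov.markov_estimator import (
    N_ORIGIN_AGES,
    ORIGIN_AGES,
    PerYearMatrices,
    _nd_row_from_counts,
    states_for_scheme,
)

from conftest import oracle_transition_counts


def _panel(rows):
    return pd.DataFrame(
        rows,
        columns=["person_id", "year", "age", "sex", "municipality",
                 "status4", "status5", "next_status4", "next_status5"],
    )


class TestCountTransitions:
    def test_hand_counts(self):
        rows = [("P%d" % i, 2010, 75, "F", 1, "light", "light_physical",
                 "light", "light_physical") for i in range(3)]
        rows.append(("P9", 2010, 75, "F", 1, "light", "light_physical",
                     "death", "death"))
        # a successor year must exist for 2010 origins to count
        rows.append(("P0", 2011, 76, "F", 1, "light", "light_physical",
                     None, None))
        counts = ltc.count_transitions(_panel(rows), scheme=4)
        yi = list(counts.years).index(2010)
        ai = 75 - 65
        cell = counts.counts[yi, 1, ai]  # sex F
        assert cell[1, 1] == 3 and cell[1, 3] == 1
        assert counts.at_risk[yi, 1, ai, 1] == 4

    def test_empty_panel_all_zero(self):
        counts = ltc.count_transitions(_panel([]), scheme=4)
        assert counts.counts.sum() == 0

    def test_final_year_origins_are_excluded(self):
        """The last observed year has no successor snapshot: only deaths
        would be visible there, so those origins must not enter the risk
        set."""
        rows = [
            ("PA", 2018, 80, "M", 1, "light", "light_physical", "death", "death"),
            ("PB", 2017, 80, "M", 1, "light", "light_physical", "light",
             "light_physical"),
            ("PB", 2018, 81, "M", 1, "light", "light_physical", None, None),
        ]
        counts = ltc.count_transitions(_panel(rows), scheme=4)
        yi = list(counts.years).index(2018)
        assert counts.counts[yi].sum() == 0

    def test_counts_match_truth_paths(self, small_world, small_pipeline):
        _, _, panel = small_pipeline
        counts = ltc.count_transitions(panel, scheme=4)
        for sex, age in [("F", 80), ("M", 85), ("F", 90)]:
            expected = oracle_transition_counts(small_world.truth, panel, sex, age)
            si = 0 if sex == "M" else 1
            got = counts.counts[:, si, age - 65].sum(axis=0)
            assert (got == expected).all()


class TestCountsToProbabilities:
    def _counts(self, cell, year=2010, sex_i=0, age_i=0, origin=1):
        arr = np.zeros((1, 2, N_ORIGIN_AGES, 4, 4), dtype=np.int64)
        arr[0, sex_i, age_i, origin] = cell
        return ltc.TransitionCounts(scheme=4, years=np.array([year]), counts=arr)

    def test_normalization(self):
        per_year = ltc.counts_to_probabilities(self._counts([3, 0, 1, 0]),
                                               min_cell=1)
        row = per_year.probs[0, 0, 0, 1]
        assert np.allclose(row, [0.75, 0.0, 0.25, 0.0])
        assert not per_year.flagged[0, 0, 0, 1]

    def test_zero_at_risk_flagged_and_undefined(self):
        per_year = ltc.counts_to_probabilities(self._counts([0, 0, 0, 0]))
        assert per_year.flagged[0, 0, 0, 1]
        assert np.isnan(per_year.probs[0, 0, 0, 1]).all()

    def test_below_min_cell_flagged_but_defined(self):
        per_year = ltc.counts_to_probabilities(self._counts([3, 0, 1, 0]),
                                               min_cell=50)
        assert per_year.flagged[0, 0, 0, 1]
        assert np.allclose(per_year.probs[0, 0, 0, 1], [0.75, 0, 0.25, 0])

    def test_death_row_absorbing_never_flagged(self):
        per_year = ltc.counts_to_probabilities(self._counts([1, 0, 0, 0]))
        assert (per_year.probs[..., 3, 3] == 1.0).all()
        assert not per_year.flagged[..., 3].any()


def _per_year_from_rows(rows_by_year, at_risk_by_year, min_cell=1):
    """Two-year, single-(sex, age) PerYearMatrices for weighting tests."""
    Y = len(rows_by_year)
    probs = np.full((Y, 2, N_ORIGIN_AGES, 4, 4), np.nan)
    at_risk = np.zeros((Y, 2, N_ORIGIN_AGES, 4))
    flagged = np.ones((Y, 2, N_ORIGIN_AGES, 4), dtype=bool)
    for y, (row, n) in enumerate(zip(rows_by_year, at_risk_by_year)):
        for s in range(2):
            for a in range(N_ORIGIN_AGES):
                probs[y, s, a, 1] = row
                at_risk[y, s, a, 1] = n
                flagged[y, s, a, 1] = n < min_cell
                probs[y, s, a, 3] = [0, 0, 0, 1]
                flagged[y, s, a, 3] = False
    return PerYearMatrices(
        scheme=4, years=np.arange(2010, 2010 + Y), probs=probs,
        at_risk=at_risk, flagged=flagged, min_cell=min_cell,
    )


class TestWeightAverage:
    def test_equal_weights_arithmetic_mean(self):
        per_year = _per_year_from_rows(
            [[1, 0, 0, 0], [0, 1, 0, 0]], [10, 10]
        )
        weights = ltc.WeightTable.uniform(per_year.years)
        out = ltc.weight_average(per_year, weights)
        assert np.allclose(out.probs[0, 0, 1], [0.5, 0.5, 0, 0])

    def test_single_year_identity_passthrough(self):
        per_year = _per_year_from_rows([[0.2, 0.5, 0.2, 0.1]], [10])
        weights = ltc.WeightTable.uniform(per_year.years)
        out = ltc.weight_average(per_year, weights)
        assert np.allclose(out.probs[0, 0, 1], [0.2, 0.5, 0.2, 0.1])

    def test_population_weights_hand_computed(self):
        """Two unequal strata combine as the hand-computed convex mix."""
        per_year = _per_year_from_rows(
            [[0.9, 0.1, 0, 0], [0.5, 0.5, 0, 0]], [100, 300]
        )
        pop = pd.DataFrame(
            [
                (2010, 0, s, a, 100)
                for s in ("M", "F") for a in ORIGIN_AGES
            ] + [
                (2011, 0, s, a, 300)
                for s in ("M", "F") for a in ORIGIN_AGES
            ],
            columns=["year", "municipality", "sex", "age", "count"],
        )
        weights = ltc.WeightTable.from_population(pop)
        out = ltc.weight_average(per_year, weights)
        expected = 0.25 * np.array([0.9, 0.1, 0, 0]) + 0.75 * np.array(
            [0.5, 0.5, 0, 0]
        )
        assert np.allclose(out.probs[0, 0, 1], expected)

    def test_uniform_weights_equal_pooling_under_equal_strata(self):
        """With equal per-year risk sets, the weighted average is exactly the
        pooled-count estimator."""
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 20, size=(3, 2, N_ORIGIN_AGES, 4, 4))
        counts[..., 3, :] = 0
        # equalize at-risk across years per (sex, age, origin)
        counts[..., :3, :] = counts[:1, ..., :3, :]
        tc = ltc.TransitionCounts(4, np.array([2010, 2011, 2012]), counts)
        per_year = ltc.counts_to_probabilities(tc, min_cell=1)
        out = ltc.weight_average(per_year, ltc.WeightTable.uniform(tc.years))
        pooled = counts.sum(axis=0)
        with np.errstate(invalid="ignore"):
            pooled_p = pooled / pooled.sum(axis=-1, keepdims=True)
        live = ~out.flagged[..., :3]
        assert np.allclose(
            out.probs[..., :3, :][live], pooled_p[..., :3, :][live]
        )

    def test_all_years_unstable_gives_flagged_row(self):
        per_year = _per_year_from_rows(
            [[1, 0, 0, 0], [0, 1, 0, 0]], [2, 3], min_cell=50
        )
        out = ltc.weight_average(per_year, ltc.WeightTable.uniform(per_year.years))
        assert out.flagged[0, 0, 1]
        assert np.isnan(out.probs[0, 0, 1]).all()


class TestNoDisabilityRow:
    def test_worked_example(self):
        row = _nd_row_from_counts(1000, 10, 2, 8)
        assert np.allclose(row, [0.98, 0.01, 0.002, 0.008])

    def test_no_entrants_no_deaths(self):
        assert np.allclose(_nd_row_from_counts(500, 0, 0, 0), [1, 0, 0, 0])

    def test_negative_residual_floored(self):
        row = _nd_row_from_counts(1000, 10, 0, -5)
        assert row[3] == 0.0
        assert np.isclose(row.sum(), 1.0)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            _nd_row_from_counts(0, 1, 1, 1)

    def test_synthetic_rows_are_distributions(self, small_world, small_pipeline):
        _, _, panel = small_pipeline
        nd = ltc.estimate_nodisability_row(
            panel, small_world.population, small_world.mortality,
            small_world.truth.covered_municipalities, min_cell=5,
        )
        ok = ~nd.flagged
        rows = nd.probs[ok]
        assert np.isfinite(rows).all()
        assert (rows >= 0).all() and (rows <= 1).all()
        assert np.allclose(rows.sum(axis=1), 1.0)
        # staying non-disabled dominates at every age in this world
        assert (rows[:, 0] > 0.5).all()


class TestAssemble:
    def _estimated(self, small_world, small_pipeline, scheme):
        _, _, panel = small_pipeline
        counts = ltc.count_transitions(panel, scheme)
        per_year = ltc.counts_to_probabilities(counts, min_cell=5)
        weights = ltc.WeightTable.from_population(
            small_world.population, small_world.truth.covered_municipalities
        )
        return ltc.weight_average(per_year, weights)

    def test_four_state_exposes_12_free_patterns(self, small_world, small_pipeline):
        _, _, panel = small_pipeline
        averaged = self._estimated(small_world, small_pipeline, 4)
        nd = ltc.estimate_nodisability_row(
            panel, small_world.population, small_world.mortality,
            small_world.truth.covered_municipalities, min_cell=5,
        )
        full = ltc.assemble(averaged, nd)
        assert full.n_free_patterns == 12
        full.validate()

    def test_five_state_exposes_20_free_patterns(self, small_world, small_pipeline):
        full = ltc.assemble(self._estimated(small_world, small_pipeline, 5))
        assert full.n_free_patterns == 20
        full.validate()

    def test_missing_nodisability_rows_error(self, small_world, small_pipeline):
        averaged = self._estimated(small_world, small_pipeline, 4)
        with pytest.raises(ltc.AssemblyError, match="no_disability"):
            ltc.assemble(averaged)

    def test_roundtrip_serialization(self, small_world, small_pipeline, tmp_path):
        full = ltc.assemble(self._estimated(small_world, small_pipeline, 5))
        path = tmp_path / "m5.json"
        full.save(path)
        loaded = ltc.TransitionMatrixSet.load(path)
        assert loaded.scheme == full.scheme
        assert np.array_equal(loaded.ages, full.ages)
        assert np.allclose(loaded.probs, full.probs, equal_nan=True)
        assert (loaded.flagged == full.flagged).all()
        # long format covers every cell once
        long = full.to_long()
        assert len(long) == 2 * len(full.ages) * 25
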