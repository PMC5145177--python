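"""Connectivity matrices and derived statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reefdrift import (
    HabitatGrid,
    ProbabilityMatrix,
    ReleaseSchedule,
    SettlementMatrix,
    bin_by_island,
    dispersal_distance_summary,
    filter_by_release_months,
    forward_probability,
    island_mean_dispersal_distance,
    island_settlement_fraction,
    mantel_test,
    matrix_difference,
    pixel_distance_matrix,
    rearward_probability,
    self_recruitment,
    settlement_matrix,
    settlement_time_series,
    source_sink_index,
)


def island_matrix(vals):
    vals = np.asarray(vals, dtype=float)
    return SettlementMatrix(vals, [f"I{k}" for k in range(vals.shape[0])], "island")


def events_frame(rows):
    """rows: (release_pixel, fate, settle_pixel, displacement_km, replicate, date)"""
    return pd.DataFrame(
        [
            {
                "replicate": r[4] if len(r) > 4 else 0,
                "release_date": pd.Timestamp(r[5] if len(r) > 5 else "2009-05-02"),
                "release_pixel": r[0],
                "fate": r[1],
                "settle_pixel": r[2],
                "displacement_km": r[3],
            }
            for r in rows
        ]
    )


square_counts = st.integers(2, 6).flatmap(
    lambda n: st.lists(
        st.lists(st.integers(0, 50), min_size=n, max_size=n), min_size=n, max_size=n
    )
)


class TestSettlementMatrix:
    def test_counting(self, two_island_grid):
        ev = events_frame(
            [(0, "settled", 1, 105.0)] * 3 + [(0, "settled", 0, 0.0), (1, "lost_unsettled", -1, 40.0)]
        )
        S = settlement_matrix(ev, two_island_grid)
        assert S.values[0, 1] == 3
        assert S.values[0, 0] == 1
        assert S.total == 4  # lost particles excluded

    def test_no_settlers_all_zero(self, two_island_grid):
        ev = events_frame([(0, "lost_unsettled", -1, 10.0)])
        assert settlement_matrix(ev, two_island_grid).total == 0

    def test_replicates_pool_additively(self, two_island_grid):
        ev = events_frame([(0, "settled", 1, 105.0, 0), (0, "settled", 1, 105.0, 1)])
        S = settlement_matrix(ev, two_island_grid)
        assert S.values[0, 1] == 2
        S0 = settlement_matrix(ev, two_island_grid, replicate=0)
        assert S0.values[0, 1] == 1


class TestBinByIsland:
    def test_two_pixels_one_island_sums_everything(self):
        grid = HabitatGrid.from_arrays([200.0, 200.02], [20.0, 20.0], [0, 0])
        S = SettlementMatrix(np.array([[1.0, 2.0], [3.0, 4.0]]), [0, 1], "pixel")
        out = bin_by_island(S, grid)
        assert out.values.tolist() == [[10.0]]

    def test_identity_mapping_unchanged(self, two_island_grid):
        S = SettlementMatrix(np.array([[5.0, 1.0], [0.0, 2.0]]), [0, 1], "pixel")
        out = bin_by_island(S, two_island_grid)
        assert np.array_equal(out.values, S.values)

    @settings(derandomize=True, max_examples=30)
    @given(vals=square_counts, data=st.data())
    def test_grand_total_conserved(self, vals, data):
        vals = np.asarray(vals, dtype=float)
        n = vals.shape[0]
        islands = data.draw(st.lists(st.integers(0, 2), min_size=n, max_size=n))
        grid = HabitatGrid.from_arrays(200 + 0.1 * np.arange(n), [20.0] * n, islands)
        S = SettlementMatrix(vals, list(range(n)), "pixel")
        assert bin_by_island(S, grid).total == pytest.approx(S.total)


class TestProbabilityMatrices:
    def test_rearward_receiving_normalization(self):
        S = island_matrix([[8, 2], [0, 4]])
        P = rearward_probability(S)
        assert P.values[0].tolist() == [1.0, 0.0]
        assert P.values[1] == pytest.approx([2 / 6, 4 / 6])

    def test_forward_source_normalization(self):
        S = island_matrix([[8, 2], [0, 4]])
        P = forward_probability(S)
        assert P.values[0] == pytest.approx([0.8, 0.2])
        assert P.values[1].tolist() == [0.0, 1.0]

    def test_diagonal_only_matrix_gives_identity_pattern(self):
        S = island_matrix(np.diag([3.0, 7.0, 1.0]))
        for P in (rearward_probability(S), forward_probability(S)):
            assert np.array_equal(P.values, np.eye(3))

    def test_zero_settler_rows_flagged_not_nan(self):
        S = island_matrix([[0, 5], [0, 3]])
        P = rearward_probability(S)  # island 0 receives nothing
        assert P.zero_rows[0] and not P.zero_rows[1]
        assert np.all(P.values[0] == 0)
        assert np.all(np.isfinite(P.values))

    @settings(derandomize=True, max_examples=50)
    @given(vals=square_counts)
    def test_row_sums_are_zero_or_one(self, vals):
        S = island_matrix(vals)
        for P in (rearward_probability(S), forward_probability(S)):
            sums = P.values.sum(axis=1)
            assert np.all((np.abs(sums - 1) < 1e-12) | (sums == 0))
            assert np.all((P.values >= 0) & (P.values <= 1))

    @settings(derandomize=True, max_examples=30)
    @given(vals=square_counts)
    def test_rearward_diagonal_equals_self_recruitment(self, vals):
        S = island_matrix(vals)
        diag = np.diag(rearward_probability(S).values)
        sr = self_recruitment(S)
        ok = ~np.isnan(sr)
        assert np.allclose(diag[ok], sr[ok])
        assert np.all(diag[~ok] == 0)


class TestMatrixDifference:
    def test_arithmetic(self):
        A = ProbabilityMatrix(np.eye(2), ["a", "b"], "forward")
        B = ProbabilityMatrix(np.array([[0.5, 0.5], [0.0, 1.0]]), ["a", "b"], "forward")
        assert matrix_difference(A, B).tolist() == [[0.5, -0.5], [0.0, 0.0]]
        assert np.all(matrix_difference(A, A) == 0)

    def test_direction_mismatch_is_hard_error(self):
        A = ProbabilityMatrix(np.eye(2), ["a", "b"], "forward")
        B = ProbabilityMatrix(np.eye(2), ["a", "b"], "rearward")
        with pytest.raises(ValueError, match="direction"):
            matrix_difference(A, B)


class TestSelfRecruitmentAndSourceSink:
    def test_hand_computed_example(self):
        S = island_matrix([[8, 2], [0, 4]])
        assert self_recruitment(S) == pytest.approx([1.0, 4 / 6])
        assert source_sink_index(S) == pytest.approx([(10 - 8) / 18, (4 - 6) / 10])

    def test_pure_exporter_and_importer_attain_bounds(self):
        S = island_matrix([[0, 10], [0, 0]])
        ssi = source_sink_index(S)
        assert ssi[0] == 1.0 and ssi[1] == -1.0

    def test_pure_self_recruiters_score_zero(self):
        # export equals import when all settlers are local recruits
        S = island_matrix(np.diag([40.0, 7.0]))
        assert np.all(source_sink_index(S) == 0.0)
        assert self_recruitment(S) == pytest.approx([1.0, 1.0])

    def test_island_receiving_only_imports_has_zero_sr(self):
        S = island_matrix([[0, 3], [0, 0]])
        sr = self_recruitment(S)
        assert np.isnan(sr[0])  # no settlers at island 0
        assert sr[1] == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(vals=square_counts)
    def test_ssi_bounds_and_two_island_antisymmetry(self, vals):
        S = island_matrix(vals)
        ssi = source_sink_index(S)
        assert np.all(ssi >= -1) and np.all(ssi <= 1)
        flux = np.array([[0, 7], [3, 0]], dtype=float)
        anti = source_sink_index(island_matrix(flux))
        assert anti[0] == pytest.approx(-anti[1])


class TestDispersalDistances:
    def test_island_mean_weighted(self):
        grid = HabitatGrid.from_arrays([200.0, 201.0, 202.0], [20.0, 20.0, 20.0], [0, 1, 2])
        D = np.array([[0.0, 100.0, 200.0], [100.0, 0.0, 100.0], [200.0, 100.0, 0.0]])
        S = SettlementMatrix(np.array([[0, 0, 5], [0, 0, 5], [0, 0, 0]]), [0, 1, 2], "pixel")
        mean = island_mean_dispersal_distance(S, D, grid)
        assert mean[2] == pytest.approx(150.0)  # 5 at 200 km, 5 at 100 km
        assert np.isnan(mean[0]) and np.isnan(mean[1])

    def test_single_connection(self):
        grid = HabitatGrid.from_arrays([200.0, 201.0], [20.0, 20.0], [0, 1])
        D = np.array([[0.0, 100.0], [100.0, 0.0]])
        S = SettlementMatrix(np.array([[0, 5], [0, 0]]), [0, 1], "pixel")
        assert island_mean_dispersal_distance(S, D, grid)[1] == pytest.approx(100.0)

    def test_pure_retention_gives_zero(self, two_island_grid):
        D = pixel_distance_matrix(two_island_grid)
        S = SettlementMatrix(np.diag([4.0, 2.0]), [0, 1], "pixel")
        assert island_mean_dispersal_distance(S, D, two_island_grid) == pytest.approx([0.0, 0.0])

    def test_weighted_mean_identity_with_events(self, two_island_grid):
        # settler-weighted island means recombine to the event-level total
        D = pixel_distance_matrix(two_island_grid)
        ev = events_frame(
            [(0, "settled", 1, D[0, 1])] * 3 + [(1, "settled", 1, 0.0)] * 2
        )
        S = settlement_matrix(ev, two_island_grid)
        mean = island_mean_dispersal_distance(S, D, two_island_grid)
        settlers = bin_by_island(S, two_island_grid).values.sum(axis=0)
        total = np.nansum(mean * settlers)
        assert total == pytest.approx(ev["displacement_km"].sum(), rel=1e-4)

    def test_summary_statistics(self):
        ev = events_frame(
            [(0, "settled", 0, 0.0)] * 3 + [(0, "settled", 1, 400.0)]
        )
        s = dispersal_distance_summary(ev)
        assert s.mean_km == pytest.approx(100.0)
        assert s.median_km == pytest.approx(0.0)  # right-tail drives up the mean
        assert s.n == 4

    def test_summary_singleton_and_empty(self):
        one = dispersal_distance_summary(events_frame([(0, "settled", 0, 100.0)]))
        assert one.mean_km == one.median_km == 100.0
        assert np.isnan(one.se_km)
        with pytest.raises(ValueError, match="no settled"):
            dispersal_distance_summary(events_frame([(0, "lost_unsettled", -1, 5.0)]))


class TestTimeSeriesAndFractions:
    def test_daily_fraction(self):
        rows = [(0, "settled", 0, 0.0, 0, "2009-05-02")] * 7
        rows += [(0, "lost_unsettled", -1, 1.0, 0, "2009-05-02")] * 93
        rows += [(0, "lost_unsettled", -1, 1.0, 0, "2009-05-03")] * 100
        ts = settlement_time_series(
            events_frame(rows), ReleaseSchedule.daily("2009-05-02", "2009-05-03")
        )
        assert ts["fraction"].tolist() == pytest.approx([0.07, 0.0])

    def test_replicate_mean_fraction(self):
        rows = [(0, "settled", 0, 0.0, 0)] * 7 + [(0, "lost_unsettled", -1, 1.0, 0)] * 93
        rows += [(0, "settled", 0, 0.0, 1)] * 9 + [(0, "lost_unsettled", -1, 1.0, 1)] * 91
        ts = settlement_time_series(
            events_frame(rows), ReleaseSchedule.daily("2009-05-02", "2009-05-02")
        )
        assert ts["fraction"].iloc[0] == pytest.approx(0.08)

    def test_island_fraction_partition(self, two_island_grid):
        rows = [(0, "settled", 1, 100.0)] * 20 + [(0, "lost_unsettled", -1, 1.0)] * 980
        ev = events_frame(rows)
        frac = island_settlement_fraction(ev, two_island_grid)
        assert frac[1] == pytest.approx(0.02)
        assert frac[0] == 0.0
        overall = (ev["fate"] == "settled").mean()
        assert frac.sum() == pytest.approx(overall)


class TestSeasonalFilter:
    def test_calendar_month_subset(self):
        sched = ReleaseSchedule.daily("2009-05-02", "2009-07-31")
        assert filter_by_release_months(sched, {5, 6}).n_dates == 60

    def test_identity_and_empty_subset(self):
        ev = events_frame([(0, "settled", 0, 0.0, 0, "2009-05-10")])
        assert len(filter_by_release_months(ev, set(range(1, 13)))) == 1
        assert len(filter_by_release_months(ev, {2})) == 0

    def test_empty_month_set_rejected(self):
        ev = events_frame([(0, "settled", 0, 0.0)])
        with pytest.raises(ValueError):
            filter_by_release_months(ev, set())


class TestMantel:
    def test_identical_matrices(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(size=(8, 8))
        res = mantel_test(A, A, n_perm=199, seed=1)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p == pytest.approx(1 / 200)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(size=(6, 6))
        res = mantel_test(A, 2.0 * A + 0.3, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_constant_matrix_gives_undefined_r(self):
        A = np.ones((5, 5))
        B = np.random.default_rng(2).uniform(size=(5, 5))
        res = mantel_test(A, B, n_perm=99, seed=0)
        assert np.isnan(res.r) and np.isnan(res.p)

    def test_too_small_or_too_few_perms_rejected(self):
        A = np.eye(2)
        with pytest.raises(ValueError):
            mantel_test(A, A)
        with pytest.raises(ValueError):
            mantel_test(np.eye(3), np.eye(3), n_perm=10)
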