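"""Assay plumbing: tables, optima, binning, rankings, reproducibility.

The heavier end-to-end recovery properties (state count, populations,
titration trends, corruption detection) live in the acceptance suite;
these tests exercise the assay mechanics on small budgets.
"""

import numpy as np
import pandas as pd
import pytest

from mscorval import assays
from mscorval.assays import AssayError, distance_profile, loo_ranking, states_scan, titration
from mscorval.correlation import CorrelationMatrix, correlation_matrix
from mscorval.restraints import RestraintSet
from mscorval.synthetic import sample_ensemble

from conftest import small_config, study_model, study_restraints

TINY = dict(n_conformers_calculated=4, n_conformers_kept=3, n_steps=120)


@pytest.fixture(scope="module")
def tiny_system():
    model = study_model(seed=1, length=16)
    return model, study_restraints(model), model.sequence


class TestStatesScan:
    def test_row_per_condition_and_mu_absent_for_one_state(self, tiny_system):
        _, rset, seq = tiny_system
        res = states_scan(rset, seq, state_range=range(1, 4), seed=0, config=small_config(**TINY))
        assert list(res.summary["n_states"]) == [1, 2, 3]
        assert np.isnan(res.detail.loc[res.detail.n_states == 1, "mu"]).all()
        assert np.isfinite(res.detail.loc[res.detail.n_states >= 2, "mu"]).all()
        assert res.optimum in (2, 3)

    def test_empty_range_rejected(self, tiny_system):
        _, rset, seq = tiny_system
        with pytest.raises(AssayError):
            states_scan(rset, seq, state_range=[], config=small_config(**TINY))


class TestPopulationScan:
    def test_group_size_zero_rejected(self, tiny_system):
        _, rset, seq = tiny_system
        with pytest.raises(AssayError, match="empty group"):
            assays.population_scan(rset, seq, total_states=4, group_sizes=[0], config=small_config(**TINY))

    def test_conditions_and_population_column(self, tiny_system):
        _, rset, seq = tiny_system
        res = assays.population_scan(
            rset, seq, total_states=4, group_sizes=[1, 2, 3], seed=1, config=small_config(**TINY)
        )
        assert list(res.summary["group_a_size"]) == [1, 2, 3]
        np.testing.assert_allclose(res.summary["population_a"], [0.25, 0.5, 0.75])
        assert res.optimum in (1, 2, 3)


class TestTitration:
    def test_full_fraction_uses_whole_set(self, tiny_system):
        _, rset, seq = tiny_system
        rng = np.random.default_rng(0)
        sub = assays._subsample(rset, 1.0, rng)
        assert len(sub) == len(rset)
        assert [str(r) for r in sub] == [str(r) for r in rset]

    def test_subsample_sizes(self, tiny_system):
        _, rset, seq = tiny_system
        rng = np.random.default_rng(0)
        sub = assays._subsample(rset, 0.4, rng)
        assert len(sub) == round(0.4 * len(rset))

    def test_rows_and_replicate_variation(self, tiny_system):
        _, rset, seq = tiny_system
        res = titration(
            rset, seq, fractions=(0.5, 1.0), replicates=2, seed=1, config=small_config(**TINY)
        )
        assert len(res.detail) == 4
        half = res.detail[res.detail.fraction == 0.5]
        assert half.n_restraints.nunique() == 1  # same size, fresh draw
        assert (res.detail[res.detail.fraction == 1.0].n_restraints == len(rset)).all()

    def test_invalid_fraction_rejected(self, tiny_system):
        _, rset, seq = tiny_system
        with pytest.raises(AssayError):
            titration(rset, seq, fractions=(1.5,), replicates=1, config=small_config(**TINY))


class TestLooRanking:
    def test_total_ordering_over_all_restraints(self, tiny_system):
        _, rset, seq = tiny_system
        small = rset.subset(range(12))  # 6 exact distances (upper+lower pairs)
        res = loo_ranking(
            small, seq, long_range_only=False, set_size=3, seed=2, config=small_config(**TINY)
        )
        assert len(res.table) == 6
        assert res.table["mu_without"].is_monotonic_increasing
        assert len(res.top_set) == len(res.bottom_set) == 3
        assert not (set(map(str, res.top_set)) & set(map(str, res.bottom_set)))
        assert np.isfinite(res.baseline_mu)

    def test_empty_scope_rejected(self, tiny_system):
        _, rset, seq = tiny_system
        with pytest.raises(AssayError):
            loo_ranking(rset, seq, min_separation=10_000, config=small_config(**TINY))


class TestDistanceProfile:
    def test_uniform_matrix_gives_flat_profile(self, two_state_ensemble):
        L = two_state_ensemble.sequence_length
        mat = CorrelationMatrix(np.full((L, L), 0.37), 2, 0.5)
        prof = distance_profile(two_state_ensemble, mat, n_bins=10)
        assert len(prof) == 10
        np.testing.assert_allclose(prof["mean_correlation"], 0.37)
        assert prof["mean_distance"].is_monotonic_increasing

    def test_equal_count_bins_with_remainder_to_last(self, two_state_ensemble):
        L = two_state_ensemble.sequence_length
        n_pairs = L * (L - 1) // 2
        mat = CorrelationMatrix(np.zeros((L, L)), 2, 0.5)
        prof = distance_profile(two_state_ensemble, mat, n_bins=7)
        assert prof["n_pairs"].sum() == n_pairs
        sizes = prof["n_pairs"].tolist()
        assert max(sizes) - min(sizes) <= 1
        assert sizes == sorted(sizes)  # remainder goes to the last bins

    def test_local_motion_gives_declining_profile(self, two_state_model, two_state_ensemble):
        mat = correlation_matrix(two_state_ensemble, 2, seed=5)
        prof = distance_profile(two_state_ensemble, mat, n_bins=10)
        assert prof["mean_correlation"].iloc[0] > prof["mean_correlation"].iloc[-1]

    def test_too_few_pairs_rejected(self, two_state_ensemble):
        L = two_state_ensemble.sequence_length
        mat = CorrelationMatrix(np.zeros((L, L)), 2, 0.5)
        with pytest.raises(AssayError):
            distance_profile(two_state_ensemble, mat, n_bins=L * L)


class TestConvergenceScan:
    def test_single_cell_trivially_converged(self, tiny_system):
        _, rset, seq = tiny_system
        res = assays.convergence_scan(
            rset, seq, step_counts=[100], conformer_counts=[4], seed=0, config=small_config(**TINY)
        )
        assert res.optimum == (100, 4)

    def test_grid_shape_and_flagged_cell(self, tiny_system):
        _, rset, seq = tiny_system
        res = assays.convergence_scan(
            rset,
            seq,
            step_counts=[60, 400],
            conformer_counts=[4, 8],
            seed=0,
            config=small_config(**TINY),
        )
        assert len(res.detail) == 4
        assert res.optimum in {(s, c) for s in (60, 400) for c in (4, 8)}


class TestCompareWithWithout:
    def test_missing_target_rejected(self, tiny_system):
        from mscorval.restraints import AtomRef, DistanceRestraint

        _, rset, seq = tiny_system
        other = DistanceRestraint(AtomRef(1, "ALA", "CA"), AtomRef(9, "ALA", "CA"), 42.0)
        assert other not in rset.restraints
        with pytest.raises(AssayError, match="not in set"):
            assays.compare_with_without(rset, other, seq, config=small_config(**TINY))

    def test_paired_report(self, tiny_system):
        _, rset, seq = tiny_system
        target = max(rset.restraints, key=lambda r: r.sequence_separation)
        rep = assays.compare_with_without(rset, target, seq, seed=3, config=small_config(**TINY))
        assert np.isfinite(rep.mu_with) and np.isfinite(rep.mu_without)
        assert rep.target_function_with >= 0 and rep.target_function_without >= 0


class TestReproducibility:
    def test_states_scan_byte_identical(self, tiny_system):
        _, rset, seq = tiny_system
        kw = dict(state_range=range(1, 3), seed=7, config=small_config(**TINY))
        a = states_scan(rset, seq, **kw)
        b = states_scan(rset, seq, **kw)
        assert a.detail.to_csv() == b.detail.to_csv()
        assert a.summary.to_csv() == b.summary.to_csv()

    def test_titration_byte_identical(self, tiny_system):
        _, rset, seq = tiny_system
        kw = dict(fractions=(0.6,), replicates=2, seed=7, config=small_config(**TINY))
        assert (
            titration(rset, seq, **kw).detail.to_csv()
            == titration(rset, seq, **kw).detail.to_csv()
        )
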