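"""CCA solver, grouped permutation inference, cross-validation, sweep."""

import itertools

import numpy as np
import pytest

import fcmodes as fm
from fcmodes.cca_modes import _grouped_permutation


class TestCCA:
    def test_identity_gives_unit_correlations(self):
        X = np.random.default_rng(0).standard_normal((40, 3))
        assert np.allclose(fm.cca(X, X.copy()).correlations, 1.0, atol=1e-10)

    def test_matches_orthonormal_basis_svd_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            X = rng.standard_normal((40, 3))
            Y = rng.standard_normal((40, 2))
            res = fm.cca(X, Y)
            qx, _ = np.linalg.qr(X - X.mean(0))
            qy, _ = np.linalg.qr(Y - Y.mean(0))
            s = np.linalg.svd(qx.T @ qy, compute_uv=False)
            assert np.abs(res.correlations - s[:2]).max() <= 1e-8

    def test_independent_data_has_small_first_correlation(self):
        rng = np.random.default_rng(2)
        res = fm.cca(rng.standard_normal((10_000, 2)), rng.standard_normal((10_000, 2)))
        assert res.correlations[0] < 0.05

    def test_invariant_to_affine_transforms(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 4))
        Y = rng.standard_normal((60, 3))
        base = fm.cca(X, Y).correlations
        Tx = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        Ty = rng.standard_normal((3, 3)) + 4 * np.eye(3)
        moved = fm.cca(X @ Tx + 7.0, Y @ Ty - 2.0).correlations
        assert np.abs(base - moved).max() <= 1e-10

    def test_variates_mutually_uncorrelated_within_side(self):
        rng = np.random.default_rng(4)
        res = fm.cca(rng.standard_normal((80, 4)), rng.standard_normal((80, 4)))
        for side in (res.x_variates, res.y_variates):
            c = np.corrcoef(side.T)
            assert np.abs(c - np.eye(c.shape[0])).max() <= 1e-8


class TestGroupedPermutation:
    def test_singleton_blocks_reduce_to_row_permutation(self):
        """With all blocks of size 1 every row ordering is reachable."""
        groups = fm.GroupStructure(np.array(["a", "b", "c"]))
        rng = np.random.default_rng(5)
        seen = {tuple(_grouped_permutation(groups, rng)) for _ in range(500)}
        assert seen == set(itertools.permutations(range(3)))

    def test_blocks_move_as_units_within_size_classes(self):
        subs = np.array(["a", "a", "b", "b", "c", "c", "c"])
        groups = fm.GroupStructure(subs)
        rng = np.random.default_rng(6)
        for _ in range(50):
            perm = _grouped_permutation(groups, rng)
            assert sorted(perm.tolist()) == list(range(7))
            # c's 3-session block has no exchange partner -> stays put
            assert perm[4:].tolist() == [4, 5, 6]
            # a/b blocks keep their internal row order
            assert perm[0:2].tolist() in ([0, 1], [2, 3])

    def test_no_exchange_possible_rejected(self):
        X = np.random.default_rng(7).standard_normal((6, 2))
        Y = np.random.default_rng(8).standard_normal((6, 2))
        groups = fm.GroupStructure(np.array(["a", "b", "b", "c", "c", "c"]))
        with pytest.raises(ValueError, match="no exchange possible"):
            fm.permutation_test(X, Y, groups, n_perm=10)

    def test_smallest_attainable_p_is_add_one(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((30, 2))
        Y = X @ rng.standard_normal((2, 2)) + 0.01 * rng.standard_normal((30, 2))
        groups = fm.GroupStructure(np.arange(30))
        res = fm.permutation_test(X, Y, groups, n_perm=99, seed=0)
        assert res.p_values[0] == pytest.approx(1 / 100)

    def test_planted_mode_significant(self, planted_study):
        cfg, truth, behavior = planted_study
        sol = fm.fit_factors(behavior.table, 8)
        fo = truth.true_fo.filter(like="fo_state_").to_numpy()
        groups = fm.GroupStructure.from_frame(behavior.table)
        res = fm.permutation_test(fo, sol.score_matrix(), groups, n_perm=999, seed=1)
        assert res.p_values[0] <= 0.01


class TestCrossValidation:
    def test_train_and_test_subjects_disjoint(self, planted_study):
        cfg, truth, behavior = planted_study
        fo = truth.true_fo.filter(like="fo_state_").to_numpy()
        groups = fm.GroupStructure.from_frame(behavior.table)
        Y = behavior.factor_scores
        cv = fm.cross_validate(fo, Y, groups, n_folds=3, n_perm=20, seed=0)
        all_subjects = set(groups.subjects.tolist())
        for train in cv.train_subjects:
            test = all_subjects - set(train)
            assert set(train) & test == set()
            assert len(test) == 5

    def test_too_few_test_blocks_rejected(self):
        rng = np.random.default_rng(10)
        groups = fm.GroupStructure(np.repeat(np.arange(5), 2))
        with pytest.raises(ValueError, match="fewer than 3 blocks"):
            fm.cross_validate(rng.standard_normal((10, 2)), rng.standard_normal((10, 2)),
                              groups, n_folds=2, train_frac=0.8)


class TestPosthocLoadings:
    def test_variable_equal_to_variate_loads_one(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((50, 3))
        Y = rng.standard_normal((50, 2))
        res = fm.cca(X, Y)
        X2 = np.column_stack([X, res.x_variates[:, 0]])
        loads = fm.posthoc_loadings(fm.cca(X2, Y), X2, Y)
        r = loads[(loads.side == "x") & (loads.variable == "x4") & (loads["mode"] == 1)]["r"].iloc[0]
        assert abs(r) == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_variable_loads_near_zero(self):
        rng = np.random.default_rng(12)
        n = 10_000
        X = rng.standard_normal((n, 3))
        Y = np.column_stack([X[:, 0] + 0.5 * rng.standard_normal(n), rng.standard_normal(n)])
        res = fm.cca(X, Y)
        loads = fm.posthoc_loadings(res, X, Y)
        noise_r = loads[(loads.side == "y") & (loads.variable == "y2") & (loads["mode"] == 1)]["r"].iloc[0]
        assert abs(noise_r) < 0.05

    def test_planted_variables_outload_uncoupled_ones(self):
        """Measures defining the planted mode load higher than uncoupled ones."""
        wins = 0
        for rep in range(10):
            cfg = fm.SynthConfig(n_subjects=150, sessions_per_subject=[2] * 150,
                                 runs_per_session=1, timepoints_per_run=40,
                                 n_nodes=4, n_states=4, seed=100 + rep)
            _, truth = fm.generate_hmm_timeseries(cfg)
            beh = fm.generate_behavior(truth, cfg)
            fo = truth.true_fo.filter(like="fo_state_").to_numpy()
            measures = beh.table[list(fm.BEHAVIOR_MEASURES)].to_numpy()
            res = fm.cca(fo, measures[:, :8])  # planted RT group spans columns 2-5
            loads = fm.posthoc_loadings(res, fo, measures[:, :8],
                                        y_names=list(fm.BEHAVIOR_MEASURES[:8]))
            y1 = loads[(loads.side == "y") & (loads["mode"] == 1)].set_index("variable")["r"].abs()
            planted = {m for m in fm.BEHAVIOR_MEASURES[:8] if m.startswith("spatialwm_rt")}
            uncoupled = set(fm.BEHAVIOR_MEASURES[:8]) - set(
                m for m in fm.BEHAVIOR_MEASURES[:8] if m.startswith("spatialwm_rt"))
            if y1[list(planted)].min() > y1[list(uncoupled)].max():
                wins += 1
        assert wins >= 9


class TestModeStabilitySweep:
    def test_sweep_enumerates_180_configurations(self, planted_study):
        cfg, truth, behavior = planted_study
        fo = truth.true_fo.filter(like="fo_state_").to_numpy()
        sweep = fm.mode_stability_sweep(fo, behavior.table,
                                        factor_range=range(1, 10), pc_range=range(1, 21))
        assert len(sweep.configs) == 180
        assert sweep.measure_loadings.shape == (180, 31)
        assert sweep.similarity.shape == (180, 180)

    def test_planted_mode_is_stable_across_settings(self, planted_study):
        cfg, truth, behavior = planted_study
        fo = truth.true_fo.filter(like="fo_state_").to_numpy()
        sweep = fm.mode_stability_sweep(fo, behavior.table,
                                        factor_range=range(2, 6), pc_range=range(6, 12))
        diag = np.diag(sweep.similarity)
        assert np.allclose(diag[np.isfinite(diag)], 1.0, atol=1e-12)
        off = sweep.similarity[np.triu_indices(len(sweep.configs), k=1)]
        finite = off[np.isfinite(off)]
        assert np.median(np.abs(finite)) > 0.9
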