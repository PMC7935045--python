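"""FO, switching rate, metastates, overlap index, motion QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

import fcmodes as fm
from fcmodes.gauss_hmm import StateTimeCourse

from conftest import make_blocks


def _stc(probs, sizes, subjects=None):
    return StateTimeCourse(probs=np.asarray(probs, float), blocks=make_blocks(sizes, subjects))


def _random_stc(rng, n_blocks=4, t=30, k=5):
    p = rng.dirichlet(np.ones(k), size=n_blocks * t)
    return _stc(p, [t] * n_blocks)


class TestFractionalOccupancy:
    def test_hard_assignment_is_one_hot(self):
        probs = np.zeros((20, 3))
        probs[:, 2] = 1.0
        fo = fm.fractional_occupancy(_stc(probs, [20])).filter(like="fo_").to_numpy()
        assert np.array_equal(fo, [[0.0, 0.0, 1.0]])

    def test_hand_computed_three_frame_block(self):
        probs = [(1, 0), (0.5, 0.5), (0, 1)]
        fo = fm.fractional_occupancy(_stc(probs, [3])).filter(like="fo_").to_numpy()
        assert np.allclose(fo, [[0.5, 0.5]])

    def test_rows_sum_to_one(self):
        stc = _random_stc(np.random.default_rng(0))
        fo = fm.fractional_occupancy(stc).filter(like="fo_").to_numpy()
        assert np.abs(fo.sum(axis=1) - 1).max() <= 1e-10


class TestSwitchingRate:
    def test_constant_posteriors_give_zero(self):
        sr = fm.switching_rate(_stc(np.tile([0.3, 0.7], (10, 1)), [10]))
        assert sr["switching_rate"].iloc[0] == 0.0

    def test_hard_alternation_two_frames(self):
        stc = _stc([(1, 0), (0, 1)], [2])
        assert fm.switching_rate(stc)["switching_rate"].iloc[0] == pytest.approx(1.0)
        assert fm.switching_rate(stc, denominator="transitions")["switching_rate"].iloc[0] \
            == pytest.approx(2.0)

    def test_single_frame_block_rejected(self):
        with pytest.raises(ValueError, match="< 2 frames"):
            fm.switching_rate(_stc([[1.0]], [1]))

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounded_by_two(self, seed):
        stc = _random_stc(np.random.default_rng(seed), n_blocks=2, t=15, k=4)
        assert fm.switching_rate(stc)["switching_rate"].max() <= 2.0


class TestMetastates:
    def test_planted_partition_recovered_exactly(self):
        cfg = fm.SynthConfig(n_nodes=4, n_states=12, seed=0)  # default 2/9/1 blocks
        theta = fm.build_transition_matrix(cfg)
        part = fm.cluster_metastates(theta, n_clusters=3)
        assert part.as_sets() == {frozenset({0, 1}), frozenset(range(2, 11)), frozenset({11})}

    def test_two_states_two_singletons(self):
        theta = np.array([[0.9, 0.1], [0.2, 0.8]])
        part = fm.cluster_metastates(theta, n_clusters=2)
        assert part.as_sets() == {frozenset({0}), frozenset({1})}

    def test_identical_rows_merge_at_height_zero(self):
        theta = np.tile([0.5, 0.25, 0.25], (3, 1))
        part = fm.cluster_metastates(theta, n_clusters=2)
        assert part.linkage_tree[0, 2] == 0.0

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            fm.cluster_metastates(np.eye(3), n_clusters=4)

    def test_pooled_timecourse_conserves_probability(self):
        rng = np.random.default_rng(1)
        stc = _random_stc(rng, k=6)
        part = fm.MetastatePartition(labels=np.array([0, 0, 1, 1, 1, 2]),
                                     linkage_tree=np.empty((0, 4)))
        pooled = fm.metastate_timecourse(stc, part)
        assert np.abs(pooled.probs.sum(axis=1) - 1).max() <= 1e-10
        fo_states = fm.fractional_occupancy(stc).filter(like="fo_").to_numpy()
        fo_meta = fm.fractional_occupancy(pooled).filter(like="fo_").to_numpy()
        for m in range(3):
            assert np.allclose(fo_meta[:, m], fo_states[:, part.members(m)].sum(axis=1),
                               atol=1e-12)

    def test_singleton_partition_is_identity(self):
        stc = _random_stc(np.random.default_rng(2), k=4)
        part = fm.MetastatePartition(labels=np.arange(4), linkage_tree=np.empty((0, 4)))
        assert np.array_equal(fm.metastate_timecourse(stc, part).probs, stc.probs)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pooling_never_increases_switching_rate(self, seed):
        rng = np.random.default_rng(seed)
        stc = _random_stc(rng, n_blocks=2, t=12, k=5)
        labels = rng.integers(0, 2, size=5)
        labels[0] = 0
        labels[1] = 1  # both clusters nonempty
        labels = pd.factorize(labels)[0]
        part = fm.MetastatePartition(labels=labels, linkage_tree=np.empty((0, 4)))
        sr_states = fm.switching_rate(stc)["switching_rate"].to_numpy()
        sr_meta = fm.switching_rate(fm.metastate_timecourse(stc, part))["switching_rate"].to_numpy()
        assert np.all(sr_meta <= sr_states + 1e-12)


class TestOverlapIndex:
    def test_selection_equals_network(self):
        v = np.array([3.0, 2.0, 0.1, 0.1, 0.1])
        # top 40% of 5 positive values -> 2 nodes {0, 1}
        assert fm.overlap_index(v, {0, 1}) == 1.0

    def test_disjoint_selection(self):
        v = np.array([3.0, 2.0, 0.1, 0.1, 0.1])
        assert fm.overlap_index(v, {3, 4}) == 0.0

    def test_signed_ten_node_example_matches_brute_force(self):
        v = np.array([5, 4, 3, 2, 1, -1, -2, -3, -4, -5], dtype=float)
        # oracle: explicit top-40% of positives by value and negatives by |value|
        pos = sorted([i for i in range(10) if v[i] > 0], key=lambda i: -v[i])
        neg = sorted([i for i in range(10) if v[i] < 0], key=lambda i: -abs(v[i]))
        selected = set(pos[: round(0.4 * len(pos))]) | set(neg[: round(0.4 * len(neg))])
        assert selected == {0, 1, 8, 9}
        network = {0, 1, 9}  # nodes carrying values 5, 4, -5
        expected = len(selected & network) / len(network)
        assert expected == 1.0
        assert fm.overlap_index(v, network) == pytest.approx(expected)

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(30)
        network = set(rng.choice(30, size=8, replace=False).tolist())
        assert fm.overlap_index(v, network) == fm.overlap_index(5.0 * v, network)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fm.overlap_index(np.ones(5), set())


class TestMotionQC:
    def _features(self, rng, n_sub=8, sessions=("ses1", "ses2", "ses3"), k=12, m=3):
        rows = []
        for s in range(n_sub):
            for ses in sessions:
                fo = rng.dirichlet(np.ones(k))
                fo_m = rng.dirichlet(np.ones(m))
                rows.append({"subject": f"s{s}", "session": ses,
                             **{f"fo_state_{i+1}": fo[i] for i in range(k)},
                             **{f"fo_meta_{i+1}": fo_m[i] for i in range(m)},
                             "sr_states": rng.uniform(0, 2), "sr_metastates": rng.uniform(0, 2)})
        return pd.DataFrame(rows)

    def test_default_config_counts_51_tests(self):
        rng = np.random.default_rng(4)
        feats = self._features(rng)
        fd = feats[["subject", "session"]].copy()
        fd["mean_fd"] = rng.uniform(0.05, 0.3, size=len(fd))
        qc = fm.qc_confound_association(feats, fd)
        assert len(qc) == 17 * 3 == 51

    def test_feature_equal_to_fd_has_unit_correlation(self):
        rng = np.random.default_rng(5)
        feats = self._features(rng, sessions=("ses1",))
        fd = feats[["subject", "session"]].copy()
        fd["mean_fd"] = feats["sr_states"].to_numpy()
        qc = fm.qc_confound_association(feats, fd)
        r = qc.loc[qc.feature == "sr_states", "r"].iloc[0]
        assert r == pytest.approx(1.0)

    def test_constant_feature_reported_missing(self):
        rng = np.random.default_rng(6)
        feats = self._features(rng, sessions=("ses1",))
        feats["sr_states"] = 1.0
        fd = feats[["subject", "session"]].copy()
        fd["mean_fd"] = rng.uniform(0.05, 0.3, size=len(fd))
        qc = fm.qc_confound_association(feats, fd)
        assert np.isnan(qc.loc[qc.feature == "sr_states", "r"].iloc[0])

    def test_bh_adjustment_matches_hand_computed_oracle(self):
        # stepwise BH on {0.01, 0.02, 0.03, 0.5}: 0.01*4/1, 0.02*4/2, 0.03*4/3
        # then monotone enforcement from below -> (0.04, 0.04, 0.04, 0.5)
        p = np.array([0.01, 0.02, 0.03, 0.5])
        adj = multipletests(p, method="fdr_bh")[1]
        assert np.abs(adj - [0.04, 0.04, 0.04, 0.5]).max() <= 1e-12
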