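import numpy as np
import pytest

from dhsig.padic import assign_codes
from dhsig.pbdhs import (
    PbdhsConfig,
    block_series,
    compute_pbdhs,
    dual_threshold_counts,
    histograms,
    search_pbdhs,
)
from dhsig.pudhs import compute_pudhs
from dhsig.tree import build_tree
from oracles import random_binary_tree


class TestBlockSeries:
    def test_block_counts_per_block_size(self, event_matrix_factory):
        ev = event_matrix_factory(n_channels=19, n_windows=25, window_len=10)
        assert len(block_series(ev, 1)) == 25
        assert len(block_series(ev, 5)) == 5
        trees = block_series(ev, 5)
        assert all(t.n_leaves == 95 for t in trees)

    def test_trailing_partial_block_dropped(self, event_matrix_factory):
        # floor(25/3) = 8 blocks; last window discarded
        ev = event_matrix_factory(n_channels=4, n_windows=25, window_len=10)
        blocks = block_series(ev, 3)
        assert len(blocks) == 8
        assert all(b.n_leaves == 12 for b in blocks)

    def test_blocks_are_contiguous_row_slices(self, event_matrix_factory):
        ev = event_matrix_factory(n_channels=3, n_windows=4, window_len=8, seed=5)
        blocks = block_series(ev, 2)
        # rebuild the first block from the first 6 rows and compare topology
        manual = assign_codes(build_tree(ev.events[:6]))
        assert [c.value for c in blocks[0].codes] == [c.value for c in manual.codes]

    def test_too_few_windows_rejected(self, event_matrix_factory):
        ev = event_matrix_factory(n_channels=3, n_windows=2, window_len=8)
        with pytest.raises(ValueError, match="windows"):
            block_series(ev, 5)

    def test_invalid_block_windows(self, event_matrix_factory):
        ev = event_matrix_factory(n_channels=3, n_windows=4, window_len=8)
        with pytest.raises(ValueError, match="block_windows"):
            block_series(ev, 0)


class TestDualThresholdCounts:
    @pytest.fixture
    def blocks(self, event_matrix_factory):
        ev = event_matrix_factory(n_channels=5, n_windows=12, window_len=10, seed=2)
        return block_series(ev, 2)

    def test_single_block_global_equals_local(self, blocks):
        res = dual_threshold_counts(blocks[:1], z1=2, z2=2)
        assert res.global_max_ball == res.max_balls[0]
        assert res.E == res.E1

    def test_huge_z1_leaves_only_zero_valued_branch(self, blocks):
        res = dual_threshold_counts(blocks, z1=10_000, z2=1)
        assert all(e == 1 for e in res.E)  # exactly one V=0 leaf per tree

    def test_identical_blocks_identical_counts(self, event_matrix_factory):
        ev = event_matrix_factory(n_channels=4, n_windows=2, window_len=8, seed=9)
        ev.events[4 * 1 : 4 * 2] = ev.events[:4]  # duplicate window 0 into window 1
        blocks = block_series(ev, 1)
        res = dual_threshold_counts(blocks, z1=2, z2=2)
        assert res.E[0] == res.E[1]
        assert res.E1[0] == res.E1[1]

    def test_bounds(self, blocks):
        for z1 in (1, 3, 7):
            for z2 in (1, 3, 7):
                res = dual_threshold_counts(blocks, z1, z2)
                m = res.m
                assert all(0 <= e <= m for e in res.E)
                assert all(0 <= e <= m for e in res.E1)

    def test_invalid_z_rejected(self, blocks):
        with pytest.raises(ValueError, match="z1"):
            dual_threshold_counts(blocks, 0, 1)

    def test_single_block_E_matches_pudhs(self, event_matrix_factory):
        """One block covering all windows: E at z1 == PUDHS at z on the same tree."""
        ev = event_matrix_factory(n_channels=4, n_windows=6, window_len=10, seed=4)
        blocks = block_series(ev, 6)
        assert len(blocks) == 1
        for z in (1, 2, 3):
            res = dual_threshold_counts(blocks, z1=z, z2=z)
            assert res.E[0] == compute_pudhs(blocks[0], z).pudhs


class TestHistograms:
    def _result(self, E, E1, m):
        from dhsig.pbdhs import BlockSeriesResult

        return BlockSeriesResult(z1=1, z2=1, m=m, max_balls=[1] * len(E), E=E, E1=E1)

    def test_tabulation(self):
        res = histograms(self._result([2, 2, 5], [1, 1, 1], m=19))
        assert res.F[2 - 1] == 2
        assert res.F[5 - 1] == 1
        assert res.F.sum() == 3

    def test_all_zero_counts_fall_outside(self):
        res = histograms(self._result([0, 0], [0, 0], m=19))
        assert res.F.sum() == 0
        assert res.F1.sum() == 0

    def test_conservation(self):
        E = [0, 1, 3, 3, 0, 19]
        res = histograms(self._result(E, E, m=19))
        zeros = sum(1 for e in E if e == 0)
        assert res.F.sum() + zeros == len(E)


class TestComputePbdhs:
    def test_hand_example_ten_sevenths(self):
        cfg = PbdhsConfig(z1=1, z2=1, h=2, p=[1, 2], p1=[1, 2])
        value = compute_pbdhs(np.array([4, 0]), np.array([1, 3]), cfg)
        assert value == pytest.approx(10 / 7)

    def test_equal_products_give_one(self):
        cfg = PbdhsConfig(z1=1, z2=1, h=3, p=[1, 2, 3], p1=[1, 2, 3])
        assert compute_pbdhs(np.array([5, 5, 5]), np.array([2, 2, 2]), cfg) == 1.0

    def test_single_bin_always_one(self):
        cfg = PbdhsConfig(z1=1, z2=1, h=1, p=[4], p1=[2])
        assert compute_pbdhs(np.arange(10), np.arange(10), cfg) == 1.0

    def test_always_at_least_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = int(rng.integers(3, 20))
            F = rng.integers(0, 10, size=m)
            F1 = rng.integers(0, 10, size=m)
            h = int(rng.integers(1, m))
            cfg = PbdhsConfig.random(m, h, 1, 1, rng)
            assert compute_pbdhs(F, F1, cfg) >= 1.0

    def test_out_of_range_centre_rejected(self):
        cfg = PbdhsConfig(z1=1, z2=1, h=1, p=[5], p1=[1])
        with pytest.raises(ValueError, match="support"):
            compute_pbdhs(np.array([1, 2]), np.array([1, 2]), cfg)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="h"):
            PbdhsConfig(z1=1, z2=1, h=0, p=[], p1=[])


class TestSearch:
    @pytest.fixture(scope="class")
    def toy_subjects(self):
        """Six subjects, two structural families that separate trivially."""
        rng = np.random.default_rng(7)
        subjects, labels = [], []
        for s in range(3):  # tight single cluster -> shallow trees
            X = rng.standard_normal((24, 6)) * 0.01
            ev = X + rng.normal(scale=0.001, size=X.shape)
            subjects.append([assign_codes(build_tree(ev[i * 6 : (i + 1) * 6])) for i in range(4)])
            labels.append("tight")
        for s in range(3):  # two far-apart clusters per block
            X = np.concatenate([np.zeros((3, 6)), np.full((3, 6), 50.0)] * 4)
            X += rng.standard_normal(X.shape)
            subjects.append([assign_codes(build_tree(X[i * 6 : (i + 1) * 6])) for i in range(4)])
            labels.append("split")
        return subjects, labels

    def test_deterministic_given_seed(self, toy_subjects):
        subjects, labels = toy_subjects
        r1 = search_pbdhs(subjects, labels, z1_range=(1, 2), z2_range=(1, 2), h=3, n_reps=3, seed=5)
        r2 = search_pbdhs(subjects, labels, z1_range=(1, 2), z2_range=(1, 2), h=3, n_reps=3, seed=5)
        assert r1.best_config == r2.best_config
        assert r1.best_sum_auc == r2.best_sum_auc
        assert (r1.per_subject["pbdhs"] == r2.per_subject["pbdhs"]).all()

    def test_separable_groups_reach_auc_one(self, toy_subjects):
        subjects, labels = toy_subjects
        res = search_pbdhs(subjects, labels, z1_range=(1, 3), z2_range=(1, 3), h=2, n_reps=50, seed=0)
        assert res.best_sum_auc == pytest.approx(1.0)

    def test_three_group_objective_bound(self):
        rng = np.random.default_rng(1)
        subjects, labels = [], []
        for g in ("a", "b", "c"):
            for _ in range(2):
                X = rng.standard_normal((12, 5))
                subjects.append([assign_codes(build_tree(X[i * 6 : (i + 1) * 6])) for i in range(2)])
                labels.append(g)
        res = search_pbdhs(subjects, labels, z1_range=(1, 1), z2_range=(1, 1), h=2, n_reps=5, seed=2)
        assert len(res.pair_aucs) == 3
        assert res.best_sum_auc <= 3.0 + 1e-12

    def test_small_group_rejected(self, toy_subjects):
        subjects, labels = toy_subjects
        with pytest.raises(ValueError, match="< 2 subjects"):
            search_pbdhs(subjects[:4], labels[:3] + ["lonely"], n_reps=1)

    def test_single_group_rejected(self, toy_subjects):
        subjects, labels = toy_subjects
        with pytest.raises(ValueError, match="groups"):
            search_pbdhs(subjects[:3], ["x"] * 3, n_reps=1)


class TestPaperRegimeCounts:
    """Block arithmetic at the published scale, with cheap window vectors."""

    def test_500_windows_block_sizes(self, event_matrix_factory):
        ev = event_matrix_factory(n_channels=19, n_windows=500, window_len=4, seed=0)
        b1 = block_series(ev, 1)
        assert len(b1) == 500 and b1[0].n_leaves == 19
        b10 = block_series(ev, 10)
        assert len(b10) == 50 and b10[0].n_leaves == 190
        b3 = block_series(ev, 3)
        assert len(b3) == 166 and b3[0].n_leaves == 57  # floor(500/3)
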