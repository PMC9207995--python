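import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netbridge.connectome import EdgeTable, edge_labels
from netbridge.cpm import (brain_scores, consensus_edges, fit_cpm,
                           fit_cpm_sets, per_split_selections,
                           permutation_test, predict_cpm, select_edges,
                           total_brain_score, tune_cpm)
from netbridge.synthetic_data import (SyntheticSpec, make_behaviour,
                                      make_edge_table)


def edge_table_from(mat: np.ndarray, subjects=None) -> EdgeTable:
    n, e = mat.shape
    r = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    assert r * (r - 1) // 2 == e
    labels = edge_labels(r)
    iu = np.triu_indices(r, k=1)
    names = [f"n{i}" for i in range(r)]
    pairs = [(names[i], names[j]) for i, j in zip(*iu)]
    subjects = subjects or [f"s{i}" for i in range(n)]
    return EdgeTable(pd.DataFrame(mat, index=subjects, columns=labels), pairs)


def planted_fixture(n=200, n_roi=25, n_planted=10, rho=0.5, seed=0):
    spec = SyntheticSpec(
        n_subjects=n, trait_names=["t"], target_corr=np.eye(1),
        exact_corr=False, n_roi=n_roi,
        planted_effects=[(i, "t", rho) for i in range(n_planted)], seed=seed)
    bt = make_behaviour(spec)
    return make_edge_table(spec, bt), bt.data["t"]


class TestSelectEdges:
    def test_planted_edge_selected_positive(self):
        # oracle: r=0.8 at n=100 gives t ~ 13.2, p << 0.001
        et, y = planted_fixture(n=100, n_roi=5, n_planted=1, rho=0.8, seed=1)
        pos, neg = select_edges(et, y, 0.001)
        assert "0_1" in pos

    def test_sign_flip_goes_negative(self):
        et, y = planted_fixture(n=100, n_roi=5, n_planted=1, rho=0.8, seed=1)
        flipped = edge_table_from(-et.values(), subjects=list(et.data.index))
        pos, neg = select_edges(flipped, y, 0.001)
        assert "0_1" in neg

    def test_null_selection_rate(self):
        frac = []
        for seed in range(20):
            et, y = planted_fixture(n=500, n_roi=25, n_planted=0, seed=seed)
            pos, neg = select_edges(et, y, 0.001)
            frac.append((len(pos) + len(neg)) / et.n_edges)
        assert np.mean(frac) <= 0.005

    def test_constant_edge_skipped_with_warning(self):
        rng = np.random.default_rng(2)
        mat = rng.standard_normal((50, 3))
        mat[:, 1] = 1.0
        et = edge_table_from(mat)
        with pytest.warns(RuntimeWarning, match="constant"):
            pos, neg = select_edges(et, rng.standard_normal(50), 0.5)
        assert "0_2" not in pos + neg

    def test_constant_y_rejected(self):
        et, _ = planted_fixture(n=50, n_roi=4, n_planted=0)
        with pytest.raises(ValueError, match="constant"):
            select_edges(et, np.ones(50), 0.05)


class TestBrainScores:
    def test_singleton_set(self):
        et, _ = planted_fixture(n=30, n_roi=4, n_planted=0)
        sp, sn = brain_scores(et, ["0_1"], [])
        np.testing.assert_allclose(sp, et.data["0_1"])
        np.testing.assert_allclose(sn, 0.0)

    def test_empty_sets_zero(self):
        et, _ = planted_fixture(n=30, n_roi=4, n_planted=0)
        sp, sn = brain_scores(et, [], [])
        assert not sp.any() and not sn.any()

    def test_additivity_over_disjoint_sets(self):
        et, _ = planted_fixture(n=30, n_roi=5, n_planted=0)
        a, _ = brain_scores(et, ["0_1", "0_2"], [])
        b, _ = brain_scores(et, ["1_2"], [])
        u, _ = brain_scores(et, ["0_1", "0_2", "1_2"], [])
        np.testing.assert_allclose(u, a + b, atol=1e-12)

    def test_missing_edge_rejected(self):
        et, _ = planted_fixture(n=30, n_roi=4, n_planted=0)
        with pytest.raises(KeyError):
            brain_scores(et, ["99_100"], [])


class TestFitPredict:
    def test_exact_coefficient_recovery(self):
        et, y0 = planted_fixture(n=150, n_roi=6, n_planted=2, rho=0.6, seed=3)
        pos, neg = select_edges(et, y0, 0.01)
        assert pos or neg
        sp, sn = brain_scores(et, pos, neg)
        y = 2.0 * sp - 1.0 * sn + 3.0
        model = fit_cpm_sets(et, y, pos, neg)
        assert model.beta_pos == pytest.approx(2.0, abs=1e-8)
        assert model.intercept == pytest.approx(3.0, abs=1e-8)

    def test_matches_independent_lstsq(self):
        # oracle: direct pseudo-inverse on the same design
        et, y = planted_fixture(n=120, n_roi=6, n_planted=3, rho=0.5, seed=4)
        model = fit_cpm(et, y, 0.01)
        sp, sn = brain_scores(et, model.positive_edges, model.negative_edges)
        design = np.column_stack([sp, sn, np.ones(len(sp))])
        beta = np.linalg.pinv(design) @ y.to_numpy()
        assert model.beta_pos == pytest.approx(beta[0], abs=1e-10)
        assert model.beta_neg == pytest.approx(beta[1], abs=1e-10)
        assert model.intercept == pytest.approx(beta[2], abs=1e-10)

    def test_pure_noise_mean_holdout_near_zero(self):
        rs = []
        for seed in range(20):
            et, y = planted_fixture(n=80, n_roi=10, n_planted=0, seed=seed)
            tr = tune_cpm({(10, "pearson", False): et}, y, [0.05],
                          n_outer=5, inner_folds=0, seed=seed)
            rs.append(tr.best["mean_r_holdout"])
        assert abs(np.nanmean(rs)) < 0.1

    def test_empty_selection_degrades_to_intercept(self):
        et, y = planted_fixture(n=50, n_roi=4, n_planted=0, seed=5)
        model = fit_cpm(et, y, 1e-12)
        assert model.degenerate
        pred = predict_cpm(model, et)
        np.testing.assert_allclose(pred, y.mean(), atol=1e-12)

    def test_prediction_invariant_to_subject_order(self):
        et, y = planted_fixture(n=60, n_roi=6, n_planted=2, rho=0.6, seed=6)
        model = fit_cpm(et, y, 0.01)
        perm = np.random.default_rng(0).permutation(60)
        shuffled = EdgeTable(et.data.iloc[perm], et.pairs)
        pred = predict_cpm(model, et)
        pred_shuffled = predict_cpm(model, shuffled)
        np.testing.assert_allclose(pred_shuffled, pred[perm], atol=1e-12)


class TestTune:
    def test_signal_channel_wins(self):
        wins = 0
        for seed in range(20):
            spec = SyntheticSpec(
                n_subjects=120, trait_names=["t"], target_corr=np.eye(1),
                exact_corr=False, n_roi=10,
                planted_effects=[(i, "t", 0.5) for i in range(10)], seed=seed)
            bt = make_behaviour(spec)
            signal = make_edge_table(spec, bt)
            noise_spec = SyntheticSpec(
                n_subjects=120, trait_names=["t"], target_corr=np.eye(1),
                exact_corr=False, n_roi=10, seed=seed + 1000)
            noise = make_edge_table(noise_spec, bt)
            tr = tune_cpm({(10, "pearson", False): signal,
                           (10, "partial", False): noise},
                          bt.data["t"], [0.01], n_outer=5, inner_folds=0,
                          seed=seed)
            wins += tr.best["metric"] == "pearson"
        assert wins >= 18

    def test_same_seed_identical(self):
        et, y = planted_fixture(n=80, n_roi=8, n_planted=3, rho=0.5, seed=7)
        a = tune_cpm({(8, "pearson", False): et}, y, [0.01, 0.05],
                     n_outer=4, inner_folds=2, seed=42)
        b = tune_cpm({(8, "pearson", False): et}, y, [0.01, 0.05],
                     n_outer=4, inner_folds=2, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.best == b.best
        for (tr1, te1), (tr2, te2) in zip(a.splits, b.splits):
            np.testing.assert_array_equal(tr1, tr2)
            np.testing.assert_array_equal(te1, te2)

    def test_degenerate_grid_plain_evaluations(self):
        et, y = planted_fixture(n=80, n_roi=8, n_planted=3, rho=0.5, seed=8)
        tr = tune_cpm({(8, "pearson", False): et}, y, [0.01],
                      n_outer=10, inner_folds=0, seed=1)
        assert len(tr.table) == 10
        assert tr.best["p_threshold"] == 0.01


class TestConsensus:
    def test_seven_of_ten_retained(self):
        sels = [(["e1"], []) if i < 7 else ([], []) for i in range(10)]
        c = consensus_edges(sels, min_count=7)
        assert c.positive == ["e1"]

    def test_six_of_ten_dropped(self):
        sels = [(["e1"], []) if i < 6 else ([], []) for i in range(10)]
        c = consensus_edges(sels, min_count=7)
        assert c.positive == []

    def test_all_splits_retained(self):
        sels = [([], ["e9"])] * 10
        c = consensus_edges(sels, min_count=7)
        assert c.negative == ["e9"]

    def test_sign_conflict_excluded(self):
        sels = [(["e1"], []) if i < 8 else ([], ["e1"]) for i in range(10)]
        c = consensus_edges(sels, min_count=7)
        assert c.positive == [] and c.negative == []
        assert c.sign_conflicts == ["e1"]

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 5000))
    def test_monotone_in_min_count(self, seed):
        rng = np.random.default_rng(seed)
        sels = []
        for _ in range(10):
            pos = [f"e{i}" for i in range(8) if rng.random() < 0.5]
            neg = [f"f{i}" for i in range(8) if rng.random() < 0.5]
            sels.append((pos, neg))
        prev_pos, prev_neg = None, None
        for mc in range(1, 11):
            c = consensus_edges(sels, min_count=mc)
            if prev_pos is not None:
                assert set(c.positive) <= prev_pos
                assert set(c.negative) <= prev_neg
            prev_pos, prev_neg = set(c.positive), set(c.negative)

    def test_min_count_exceeding_splits_rejected(self):
        with pytest.raises(ValueError):
            consensus_edges([([], [])] * 5, min_count=7)


class TestPermutation:
    def test_perfect_signal_floor_p(self):
        et, y = planted_fixture(n=200, n_roi=25, n_planted=10, rho=0.5, seed=3)
        res = permutation_test(et, y, 0.001, n_outer=10, n_perm=199, seed=5)
        assert res.p_value == pytest.approx(1 / 200)

    def test_nothing_selected_gives_p_one(self):
        et, y = planted_fixture(n=40, n_roi=5, n_planted=0, seed=9)
        res = permutation_test(et, y, 1e-15, n_outer=3, n_perm=19, seed=9)
        assert res.p_value == 1.0

    def test_p_in_valid_range(self):
        et, y = planted_fixture(n=40, n_roi=5, n_planted=0, seed=10)
        res = permutation_test(et, y, 0.1, n_outer=3, n_perm=49, seed=10)
        assert 1 / 50 <= res.p_value <= 1.0

    def test_seed_reproducible(self):
        et, y = planted_fixture(n=50, n_roi=6, n_planted=1, rho=0.5, seed=11)
        a = permutation_test(et, y, 0.05, n_outer=3, n_perm=29, seed=3)
        b = permutation_test(et, y, 0.05, n_outer=3, n_perm=29, seed=3)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.null_stats, b.null_stats)


class TestTotalBrainScore:
    def test_beta_pos_only_equals_spos(self):
        et, y = planted_fixture(n=60, n_roi=6, n_planted=2, rho=0.6, seed=12)
        pos, neg = select_edges(et, y, 0.01)
        model = fit_cpm_sets(et, y, pos, neg)
        object.__setattr__(model, "beta_pos", 1.0)
        object.__setattr__(model, "beta_neg", 0.0)
        sp, _ = brain_scores(et, model.positive_edges, model.negative_edges)
        np.testing.assert_allclose(total_brain_score(model, et), sp)

    def test_invariant_to_extra_edges(self):
        et, y = planted_fixture(n=60, n_roi=6, n_planted=2, rho=0.6, seed=13)
        model = fit_cpm(et, y, 0.01)
        total = total_brain_score(model, et)
        wider = EdgeTable(
            pd.concat([et.data,
                       pd.Series(np.ones(60), index=et.data.index, name="xx")],
                      axis=1),
            et.pairs + [("x", "x2")])
        np.testing.assert_allclose(total_brain_score(model, wider), total)

    def test_training_correlation_equals_multiple_r(self):
        # oracle: OLS fitted values; dropping the intercept leaves the
        # correlation with y unchanged
        et, y = planted_fixture(n=100, n_roi=8, n_planted=4, rho=0.5, seed=14)
        model = fit_cpm(et, y, 0.01)
        total = total_brain_score(model, et)
        sp, sn = brain_scores(et, model.positive_edges, model.negative_edges)
        design = np.column_stack([sp, sn, np.ones(100)])
        fitted = design @ np.linalg.pinv(design) @ y.to_numpy()
        expected = np.corrcoef(fitted, y)[0, 1]
        assert np.corrcoef(total, y)[0, 1] == pytest.approx(expected, abs=1e-8)
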