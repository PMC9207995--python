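import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from netbridge.connectome import (ConnectomeSet, EdgeTable,
                                  build_confound_design, connectome_partial,
                                  connectome_pearson, connectome_tangent,
                                  devectorize, edge_labels, filter_rois,
                                  geometric_mean_spd, regress_confounds,
                                  restrict_edges, vectorize_edges)
from netbridge.synthetic_data import make_confounds, make_timeseries


def random_corr_mats(n_sub, r, seed):
    rng = np.random.default_rng(seed)
    mats = []
    for _ in range(n_sub):
        a = rng.standard_normal((r + 10, r))
        mats.append(np.corrcoef(a, rowvar=False))
    return np.array(mats)


class TestPearson:
    def test_duplicated_column_unit_edge(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        ts = np.column_stack([x, x, rng.standard_normal(100)])
        c = connectome_pearson(ts)
        assert c[0, 1] == pytest.approx(1.0)

    def test_generator_covariance_recovered(self):
        cov = np.array([[1.0, 0.7], [0.7, 1.0]])
        ts = make_timeseries(1, 100_000, cov, seed=3)[0]
        assert connectome_pearson(ts)[0, 1] == pytest.approx(0.7, abs=0.01)

    def test_independent_columns_near_zero(self):
        ts = make_timeseries(1, 50_000, np.eye(5), seed=4)[0]
        c = connectome_pearson(ts)
        assert np.abs(c[~np.eye(5, dtype=bool)]).max() < 0.03

    def test_constant_column_rejected(self):
        ts = np.column_stack([np.ones(50), np.random.default_rng(0).standard_normal(50)])
        with pytest.raises(ValueError, match="constant ROI columns: \\[0\\]"):
            connectome_pearson(ts)

    def test_symmetry_and_range(self):
        ts = make_timeseries(1, 200, np.eye(6), seed=5)[0]
        c = connectome_pearson(ts)
        assert np.abs(c - c.T).max() < 1e-12
        assert np.all(c >= -1) and np.all(c <= 1)
        np.testing.assert_allclose(np.diag(c), 1.0)


class TestPartial:
    def test_chain_conditioned_edge_vanishes(self):
        # X - Y - Z chain: corr(X,Z) = corr(X,Y) corr(Y,Z) => partial(X,Z) = 0
        cov = np.array([[1.0, 0.6, 0.36], [0.6, 1.0, 0.6], [0.36, 0.6, 1.0]])
        ts = make_timeseries(1, 200_000, cov, seed=6)[0]
        rho = connectome_partial(ts, shrinkage=None)
        assert abs(rho[0, 2]) < 0.02

    def test_two_rois_partial_equals_pearson(self):
        ts = make_timeseries(1, 500, np.array([[1.0, 0.4], [0.4, 1.0]]), seed=7)[0]
        assert connectome_partial(ts, shrinkage=None)[0, 1] == pytest.approx(
            connectome_pearson(ts)[0, 1], abs=1e-10)

    def test_identity_cov_near_zero(self):
        ts = make_timeseries(1, 50_000, np.eye(4), seed=8)[0]
        rho = connectome_partial(ts, shrinkage=None)
        assert np.abs(rho[~np.eye(4, dtype=bool)]).max() < 0.03

    def test_short_series_needs_shrinkage(self):
        ts = make_timeseries(1, 11, np.eye(10), seed=9)[0]
        with pytest.raises(ValueError, match="shrinkage"):
            connectome_partial(ts, shrinkage=None)
        rho = connectome_partial(ts, shrinkage="ledoit_wolf")
        assert np.isfinite(rho).all()


class TestTangent:
    def test_reference_maps_to_zero(self):
        mats = np.array([np.eye(3) * 2.0] * 5)
        cset = ConnectomeSet([f"s{i}" for i in range(5)], mats,
                             ["a", "b", "c"], metric="covariance")
        out = connectome_tangent(cset)
        assert np.abs(out.matrices).max() < 1e-8

    def test_round_trip(self):
        mats = random_corr_mats(6, 4, seed=10) + 0.5 * np.eye(4)
        cset = ConnectomeSet([f"s{i}" for i in range(6)], mats,
                             list("abcd"), metric="covariance")
        out = connectome_tangent(cset)
        ref = out.reference
        w, v = np.linalg.eigh(ref)
        ref_sqrt = (v * np.sqrt(w)) @ v.T
        for orig, tang in zip(mats, out.matrices):
            back = ref_sqrt @ expm(tang) @ ref_sqrt
            assert np.abs(back - orig).max() < 1e-6

    def test_non_pd_rejected_with_subject(self):
        mats = random_corr_mats(3, 3, seed=11)
        mats[1] = np.ones((3, 3))  # singular
        cset = ConnectomeSet(["s0", "s1", "s2"], mats, list("abc"),
                             metric="covariance")
        with pytest.raises(ValueError, match="s1"):
            connectome_tangent(cset)

    def test_geometric_mean_of_identical(self):
        m = random_corr_mats(1, 4, seed=12)[0] + 0.3 * np.eye(4)
        g = geometric_mean_spd(np.array([m] * 4))
        assert np.abs(g - m).max() < 1e-8


class TestVectorize:
    def test_three_by_three_order(self):
        mats = random_corr_mats(2, 3, seed=13)
        cset = ConnectomeSet(["s0", "s1"], mats, list("abc"))
        et = vectorize_edges(cset)
        assert list(et.data.columns) == ["0_1", "0_2", "1_2"]
        assert et.pairs == [("a", "b"), ("a", "c"), ("b", "c")]

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 1000), r=st.integers(2, 8))
    def test_round_trip_identity(self, seed, r):
        mats = random_corr_mats(3, r, seed=seed)
        cset = ConnectomeSet(["s0", "s1", "s2"], mats,
                             [f"n{i}" for i in range(r)], metric="pearson")
        back = devectorize(vectorize_edges(cset))
        np.testing.assert_allclose(back.matrices, mats, atol=1e-12)

    def test_300_rois_edge_count(self):
        assert len(edge_labels(300)) == 44_850

    def test_bad_edge_count_rejected(self):
        df = pd.DataFrame(np.zeros((2, 4)), index=["a", "b"],
                          columns=["0_1", "0_2", "1_2", "x"])
        et = EdgeTable(df, [("a", "b")] * 4)
        with pytest.raises(ValueError, match="integer R"):
            devectorize(et)


class TestConfoundRegression:
    def _edges(self, mat, subjects):
        r = int(round((1 + np.sqrt(1 + 8 * mat.shape[1])) / 2))
        labels = edge_labels(r)
        names = [f"n{i}" for i in range(r)]
        iu = np.triu_indices(r, k=1)
        pairs = [(names[i], names[j]) for i, j in zip(*iu)]
        return EdgeTable(pd.DataFrame(mat, index=subjects, columns=labels), pairs)

    def test_age_effect_removed(self):
        rng = np.random.default_rng(0)
        conf = make_confounds(200, 2, seed=0)
        edges = 2.0 * conf["age"].to_numpy()[:, None] + rng.standard_normal((200, 3))
        et = self._edges(edges, conf.index)
        out = regress_confounds(et, conf)
        for k in range(3):
            assert abs(np.corrcoef(out.data.iloc[:, k], conf["age"])[0, 1]) < 1e-8

    def test_residuals_orthogonal_to_all_confounds(self):
        rng = np.random.default_rng(1)
        conf = make_confounds(150, 3, seed=1)
        et = self._edges(rng.standard_normal((150, 6)), conf.index)
        out = regress_confounds(et, conf)
        X, names = build_confound_design(conf)
        for k in range(6):
            for c in range(1, X.shape[1]):  # skip intercept
                assert abs(np.corrcoef(out.data.iloc[:, k], X[:, c])[0, 1]) < 1e-8

    def test_zero_variance_confounds_center_only(self):
        rng = np.random.default_rng(2)
        subjects = [f"s{i}" for i in range(50)]
        conf = pd.DataFrame({"c": np.zeros(50)}, index=subjects)
        mat = rng.standard_normal((50, 3)) + 5.0
        et = self._edges(mat, subjects)
        out = regress_confounds(et, conf)
        np.testing.assert_allclose(out.values(), mat - mat.mean(axis=0), atol=1e-10)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        conf = make_confounds(100, 2, seed=3)
        et = self._edges(rng.standard_normal((100, 3)), conf.index)
        once = regress_confounds(et, conf)
        twice = regress_confounds(once, conf)
        np.testing.assert_allclose(twice.values(), once.values(), atol=1e-10)

    def test_planted_trait_effect_survives(self):
        # confounds independent of the trait: pre/post trait-edge correlation
        # changes by < 0.05 at n=500
        rng = np.random.default_rng(4)
        n = 500
        conf = make_confounds(n, 2, seed=4)
        trait = rng.standard_normal(n)
        edge = 0.6 * trait + 0.8 * rng.standard_normal(n)
        et = self._edges(np.column_stack([edge, rng.standard_normal(n),
                                          rng.standard_normal(n)]), conf.index)
        before = np.corrcoef(et.data.iloc[:, 0], trait)[0, 1]
        out = regress_confounds(et, conf)
        after = np.corrcoef(out.data.iloc[:, 0], trait)[0, 1]
        assert abs(after - before) < 0.05

    def test_singleton_site_warns(self):
        rng = np.random.default_rng(5)
        subjects = [f"s{i}" for i in range(20)]
        conf = pd.DataFrame({"site": ["a"] * 19 + ["b"],
                             "age": rng.uniform(10, 20, 20)}, index=subjects)
        et = self._edges(rng.standard_normal((20, 3)), subjects)
        with pytest.warns(RuntimeWarning, match="single-subject"):
            regress_confounds(et, conf)

    def test_collinear_confounds_rejected(self):
        rng = np.random.default_rng(6)
        subjects = [f"s{i}" for i in range(30)]
        v = rng.standard_normal(30)
        conf = pd.DataFrame({"u": v, "w": 2 * v}, index=subjects)
        et = self._edges(rng.standard_normal((30, 3)), subjects)
        with pytest.raises(ValueError, match="collinear"):
            regress_confounds(et, conf)

    def test_misaligned_subjects_rejected(self):
        rng = np.random.default_rng(7)
        et = self._edges(rng.standard_normal((10, 3)),
                         [f"s{i}" for i in range(10)])
        conf = make_confounds(5, 1, seed=7)
        with pytest.raises(ValueError, match="missing"):
            regress_confounds(et, conf)


class TestFilterRois:
    def test_boundary(self):
        kept, excluded = filter_rois({"a": 0.49, "b": 0.50, "c": 1.0})
        assert excluded == ["a"]
        assert kept == ["b", "c"]

    def test_full_coverage_keeps_all(self):
        kept, excluded = filter_rois({"a": 1.0, "b": 1.0})
        assert not excluded

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            filter_rois({"a": 1.2})

    def test_restrict_edges(self):
        mats = random_corr_mats(2, 4, seed=20)
        cset = ConnectomeSet(["s0", "s1"], mats, list("abcd"))
        et = vectorize_edges(cset)
        out = restrict_edges(et, ["a", "b", "d"])
        assert out.n_edges == 3
        assert all("c" not in p for p in out.pairs)
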