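import numpy as np
import pytest

from syncflow import dynamic as D
from syncflow import synthetic as S
from syncflow.errors import InvalidArgumentError
from syncflow.types import CRQAParams, DynamicISC, GLMResult

from conftest import make_bold, make_series
from _oracles import sliding_isc_bruteforce


class TestSlidingIsc:
    @pytest.mark.parametrize(
        "T, w, s, want",
        [(680, 10, 1, 671), (12, 10, 1, 3), (12, 10, 2, 2), (10, 10, 1, 1), (30, 5, 5, 6)],
    )
    def test_window_count_formula(self, rng, T, w, s, want):
        subs = [
            make_bold(rng.standard_normal((2, T)), subject_id=f"s{i}") for i in range(2)
        ]
        out = D.sliding_isc(subs, w, s)
        assert out.n_windows == want
        assert out.values.shape == (2, want)

    def test_matches_slicewise_bruteforce(self, rng):
        datas = [rng.standard_normal((4, 12)) for _ in range(3)]
        subs = [make_bold(d, subject_id=f"s{i}") for i, d in enumerate(datas)]
        out = D.sliding_isc(subs, 10, 1)
        np.testing.assert_allclose(out.values, sliding_isc_bruteforce(datas, 10, 1))

    def test_window_times_are_centres(self, rng):
        subs = [
            make_bold(rng.standard_normal((2, 14)), tr=3.0, subject_id=f"s{i}")
            for i in range(2)
        ]
        out = D.sliding_isc(subs, 10, 2)
        # centre of window k: (k*step + (w-1)/2) * tr
        np.testing.assert_allclose(out.window_times, [13.5, 19.5, 25.5])

    def test_identical_subjects_all_one(self, rng):
        data = rng.standard_normal((3, 20))
        subs = [make_bold(data, subject_id=f"s{i}") for i in range(3)]
        out = D.sliding_isc(subs, 5, 1)
        np.testing.assert_allclose(out.values, 1.0)

    def test_window_too_long_rejected(self, rng):
        subs = [make_bold(rng.standard_normal((2, 8)), subject_id=f"s{i}") for i in range(2)]
        with pytest.raises(InvalidArgumentError):
            D.sliding_isc(subs, 10, 1)
        with pytest.raises(InvalidArgumentError):
            D.sliding_isc(subs, 2, 1)


class TestPrepareRegressor:
    def grid(self, n=40, dt=3.0, t0=0.0):
        return t0 + dt * np.arange(n)

    def test_constant_series_becomes_half(self):
        times = self.grid()
        s = make_series(np.full(40, 9.0), dt=3.0)
        with pytest.warns(UserWarning):
            col = D.prepare_regressor(s, times)
        np.testing.assert_allclose(col, 0.5)

    def test_output_on_window_grid(self):
        times = self.grid(30)
        s = make_series(np.random.default_rng(0).random(900), dt=0.1)
        col = D.prepare_regressor(s, times)
        assert col.shape == (30,)

    def test_lag_shifts_peak_later(self):
        # impulse at window 10: with a 5 s lag on a 3 s grid the filtered
        # peak moves to window 10 + round(5/3) = 12.
        times = self.grid(40)
        values = np.zeros(40)
        values[10] = 1.0
        s = make_series(values, dt=3.0)
        col = D.prepare_regressor(s, times, sigma=2.8, lag=5.0)
        assert int(np.argmax(col)) == 12

    def test_zero_lag_zero_sigma_limit_is_minmax(self):
        times = self.grid(20)
        vals = np.random.default_rng(1).random(20) * 10 + 3
        s = make_series(vals, dt=3.0)
        col = D.prepare_regressor(s, times, sigma=1e-6, lag=0.0)
        want = (vals - vals.min()) / (vals.max() - vals.min())
        np.testing.assert_allclose(col, want, atol=1e-6)

    def test_single_window_rejected(self):
        with pytest.raises(InvalidArgumentError):
            D.prepare_regressor(make_series([1.0, 2.0]), np.array([0.0]))


class TestOrthogonalize:
    def test_columns_mutually_orthogonal(self, rng):
        cols = {f"c{i}": rng.standard_normal(50) for i in range(4)}
        dm = D.orthogonalize(cols, ["c0", "c1", "c2", "c3"])
        gram = dm.columns.T @ dm.columns
        off = gram - np.diag(np.diag(gram))
        np.testing.assert_allclose(off, 0.0, atol=1e-8)

    def test_columns_mean_centred(self, rng):
        cols = {"a": rng.standard_normal(30) + 5, "b": rng.standard_normal(30)}
        dm = D.orthogonalize(cols, ["a", "b"])
        np.testing.assert_allclose(dm.columns.mean(axis=0), 0.0, atol=1e-10)

    def test_first_column_unchanged_up_to_centering(self, rng):
        a = rng.standard_normal(30)
        dm = D.orthogonalize({"a": a, "b": rng.standard_normal(30)}, ["a", "b"])
        np.testing.assert_allclose(dm.columns[:, 0], a - a.mean())

    def test_order_changes_later_columns(self, rng):
        shared = rng.standard_normal(40)
        cols = {
            "a": shared + 0.3 * rng.standard_normal(40),
            "b": shared + 0.3 * rng.standard_normal(40),
        }
        ab = D.orthogonalize(cols, ["a", "b"])
        ba = D.orthogonalize(cols, ["b", "a"])
        # second column differs depending on which came first
        assert not np.allclose(ab.columns[:, 1], ba.columns[:, 0])

    def test_collinear_pair_named_in_error(self, rng):
        a = rng.standard_normal(20)
        with pytest.raises(InvalidArgumentError, match="'dup'"):
            D.orthogonalize({"a": a, "dup": 2.0 * a}, ["a", "dup"])

    def test_empty_order_rejected(self):
        with pytest.raises(InvalidArgumentError):
            D.orthogonalize({}, [])


def make_dyn(values, tr=3.0, window_len=10, step=1):
    values = np.asarray(values, float)
    n_windows = values.shape[1]
    times = (np.arange(n_windows) * step + (window_len - 1) / 2.0) * tr
    return DynamicISC(
        values=values, window_len=window_len, step=step, tr=tr, window_times=times
    )


class TestGlmFit:
    def test_perfect_fit_recovers_beta_and_caps_z(self, rng):
        x = rng.standard_normal(60)
        dm = D.orthogonalize({"x": x}, ["x"])
        dyn = make_dyn(np.stack([2.0 * dm.columns[:, 0], -dm.columns[:, 0]]))
        res = D.glm_fit(dyn, dm, highpass=None)
        np.testing.assert_allclose(res.betas[:, 0], [2.0, -1.0], atol=1e-10)
        # floating-point residuals keep z just below the hard cap
        assert 30.0 < res.z_stats[0, 0] <= D.Z_CAP
        assert -D.Z_CAP <= res.z_stats[1, 0] < -30.0

    def test_null_betas_near_zero(self, rng):
        x = rng.standard_normal(200)
        dm = D.orthogonalize({"x": x}, ["x"])
        dyn = make_dyn(rng.standard_normal((5, 200)))
        res = D.glm_fit(dyn, dm, highpass=None)
        assert np.all(np.abs(res.z_stats) < 4.0)

    def test_z_matches_scipy_on_small_case(self, rng):
        from scipy import stats

        x = rng.standard_normal(30)
        dm = D.orthogonalize({"x": x}, ["x"])
        y = 0.5 * dm.columns[:, 0] + rng.standard_normal(30)
        res = D.glm_fit(make_dyn(y[None, :]), dm, highpass=None)
        lr = stats.linregress(dm.columns[:, 0], y)
        t = lr.slope / lr.stderr
        z_want = np.sign(t) * stats.norm.isf(stats.t.sf(abs(t), 28))
        assert res.z_stats[0, 0] == pytest.approx(z_want)

    def test_row_mismatch_rejected(self, rng):
        dm = D.orthogonalize({"x": rng.standard_normal(20)}, ["x"])
        with pytest.raises(InvalidArgumentError):
            D.glm_fit(make_dyn(rng.standard_normal((2, 25))), dm, highpass=None)

    def test_highpass_removes_drift_confound(self, rng):
        # a regressor uncorrelated with y except through a shared slow
        # drift should lose its spurious effect after filtering
        n = 200
        drift = np.linspace(0, 1, n)
        x = drift + 0.05 * rng.standard_normal(n)
        y = 5 * drift + 0.05 * rng.standard_normal(n)
        dm = D.orthogonalize({"x": x}, ["x"])
        dyn = make_dyn(y[None, :], tr=3.0, window_len=10)
        unfiltered = D.glm_fit(dyn, dm, highpass=None)
        filtered = D.glm_fit(dyn, dm, highpass=100.0)
        assert abs(filtered.z_stats[0, 0]) < abs(unfiltered.z_stats[0, 0])


class TestClusterThreshold:
    def test_no_suprathreshold_voxels(self):
        assert D.cluster_threshold(np.zeros((4, 4, 4)), 3.1) == []

    def test_full_block_single_cluster(self):
        vol = np.zeros((5, 5, 5))
        vol[1:4, 1:4, 1:4] = 5.0
        (cl,) = D.cluster_threshold(vol, 3.1)
        assert cl.extent == 27
        assert cl.peak_z == 5.0

    def test_corner_touch_connectivity(self):
        vol = np.zeros((4, 4, 4))
        vol[0, 0, 0] = 5.0
        vol[1, 1, 1] = 5.0  # touches only diagonally
        assert len(D.cluster_threshold(vol, 3.1, connectivity=26)) == 1
        assert len(D.cluster_threshold(vol, 3.1, connectivity=6)) == 2

    def test_min_extent_filter_and_sorting(self):
        vol = np.zeros((6, 6, 6))
        vol[0, 0, 0:2] = 4.0  # extent 2
        vol[3:6, 3:6, 3:6] = 4.0  # extent 27
        cls = D.cluster_threshold(vol, 3.1, min_extent=3)
        assert len(cls) == 1 and cls[0].extent == 27
        cls = D.cluster_threshold(vol, 3.1)
        assert [c.extent for c in cls] == [27, 2]

    def test_invalid_args_rejected(self):
        with pytest.raises(InvalidArgumentError):
            D.cluster_threshold(np.zeros((2, 2, 2)), -1.0)
        with pytest.raises(InvalidArgumentError):
            D.cluster_threshold(np.zeros((2, 2, 2)), 3.1, connectivity=18)


class TestClusterPermutation:
    def test_true_effect_survives_null_does_not(self, rng):
        n = 80
        x = rng.standard_normal(n)
        dm = D.orthogonalize({"x": x}, ["x"])
        mask = np.ones((3, 3, 3), dtype=bool)
        values = 0.3 * rng.standard_normal((27, n))
        # strong effect in a 2x2x2 corner block (voxels of the flat index)
        block = np.zeros((3, 3, 3), dtype=bool)
        block[:2, :2, :2] = True
        values[block.ravel()] += 2.0 * dm.columns[:, 0]
        res = D.cluster_permutation(
            make_dyn(values), dm, mask, z_thresh=3.1, n_perm=100, seed=0,
            highpass=None,
        )
        assert len(res.clusters) >= 1
        assert res.clusters[0].extent >= 8
        assert res.clusters[0].p_value <= 0.05

    def test_pure_noise_yields_no_clusters(self, rng):
        n = 60
        dm = D.orthogonalize({"x": rng.standard_normal(n)}, ["x"])
        mask = np.ones((2, 2, 2), dtype=bool)
        res = D.cluster_permutation(
            make_dyn(rng.standard_normal((8, n))), dm, mask,
            z_thresh=3.1, n_perm=50, seed=1, highpass=None,
        )
        assert res.clusters == []


class TestRoiSummary:
    def make_result(self, betas, names=("a",)):
        return GLMResult(
            names=list(names), betas=np.asarray(betas, float),
            z_stats=np.zeros_like(np.asarray(betas, float)),
        )

    def test_blockwise_means(self):
        mask = np.ones((4, 1, 1), dtype=bool)
        labels = np.array([1, 1, 2, 2]).reshape(4, 1, 1)
        res = self.make_result([[1.0], [3.0], [10.0], [20.0]])
        table = D.roi_summary(res, labels, mask)
        assert table.loc[1, "a"] == pytest.approx(2.0)
        assert table.loc[2, "a"] == pytest.approx(15.0)

    def test_background_and_empty_roi(self):
        mask = np.zeros((4, 1, 1), dtype=bool)
        mask[:2] = True
        labels = np.array([1, 1, 0, 2]).reshape(4, 1, 1)
        res = self.make_result([[5.0], [7.0]])
        table = D.roi_summary(res, labels, mask)
        assert table.loc[1, "a"] == pytest.approx(6.0)
        assert np.isnan(table.loc[2, "a"])  # ROI 2 has no in-mask voxels
        assert 0 not in table.index

    def test_multiple_regressors(self):
        mask = np.ones((2, 1, 1), dtype=bool)
        labels = np.array([1, 1]).reshape(2, 1, 1)
        res = self.make_result([[1.0, 10.0], [3.0, 30.0]], names=("a", "b"))
        table = D.roi_summary(res, labels, mask)
        assert list(table.columns) == ["a", "b"]
        assert table.loc[1, "b"] == pytest.approx(20.0)

    def test_shape_mismatch_rejected(self):
        mask = np.ones((2, 1, 1), dtype=bool)
        res = self.make_result([[1.0], [2.0]])
        with pytest.raises(InvalidArgumentError):
            D.roi_summary(res, np.ones((3, 1, 1)), mask)


class TestRatingSimilarityRegressor:
    params = CRQAParams(radius=0.5, lag_window=2.0, normalize=True)

    def test_identical_raters_fully_similar(self, rng):
        base = rng.random(30)
        ratings = {f"s{i}": make_series(base, name=f"s{i}") for i in range(3)}
        labels = {k: "g" for k in ratings}
        out = D.rating_similarity_regressor(
            ratings, labels, CRQAParams(radius=1.5, lag_window=2.0), window=5.0
        )
        np.testing.assert_allclose(out["g"].values, 1.0)

    def test_one_series_per_group(self):
        coupled = S.gen_ratings(3, 60.0, 24.0, 0.9, seed=1)
        uncoupled = S.gen_ratings(3, 60.0, 24.0, 0.0, seed=2)
        ratings = {s.name + "c": s for s in coupled}
        ratings.update({s.name + "u": s for s in uncoupled})
        labels = {k: ("c" if k.endswith("c") else "u") for k in ratings}
        out = D.rating_similarity_regressor(ratings, labels, self.params, window=3.0)
        assert set(out) == {"c", "u"}
        assert out["c"].n == out["u"].n
        assert out["c"].values.mean() > out["u"].values.mean()

    def test_undersized_group_rejected(self, rng):
        ratings = {"s0": make_series(rng.random(20))}
        with pytest.raises(InvalidArgumentError):
            D.rating_similarity_regressor(ratings, {"s0": "g"}, self.params)
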