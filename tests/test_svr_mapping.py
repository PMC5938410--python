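import numpy as np
import pytest

from conftest import make_tensor
from mlsmap.design_matrix import (MultiLesionDesign, build_multilesion_design,
                                  build_single_design)
from mlsmap.svr_mapping import (default_c_grid, default_gamma_grid, extract_beta,
                                fit_svr, loocv_train, train_and_fit)


def random_design(m=40, v=20, seed=0, prevalence=0.4, lesion_type="AIL"):
    rng = np.random.default_rng(seed)
    data = (rng.random((m, v)) < prevalence).astype(np.uint8)
    t = make_tensor(data, lesion_type, grid_shape=(4, 4, 4), voxel_index=np.arange(v))
    return build_single_design(t, k=1, volume_mode="none")


class TestGrids:
    def test_linear_grid_is_published_range(self):
        grid = default_c_grid("linear")
        assert grid[0] == 2.0 ** -20
        assert grid[-1] == 2.0 ** 20
        assert len(grid) == 41
        np.testing.assert_allclose(np.diff(np.log2(grid)), 1.0)

    def test_rbf_grids(self):
        c = default_c_grid("rbf")
        assert c[0] == 2.0 ** -20 and c[-1] == 2.0 ** 6 and len(c) == 27
        g = default_gamma_grid()
        np.testing.assert_array_equal(g, np.arange(1, 17))

    def test_unknown_kernel(self):
        with pytest.raises(ValueError):
            default_c_grid("poly")


class TestFitSvr:
    def test_single_feature_rank_correlated(self):
        rng = np.random.default_rng(1)
        x = rng.random((30, 1))
        y = 3.0 * x[:, 0] + 0.01 * rng.normal(size=30)
        model = fit_svr(x, y, "linear", C=1e3)
        pred = model.predict(x)
        assert np.corrcoef(pred, y)[0, 1] >= 0.99

    def test_constant_deficit(self):
        x = np.random.default_rng(2).random((20, 3))
        model = fit_svr(x, np.full(20, 4.0), "linear", C=1.0, epsilon=0.1)
        beta = model.dual_coef @ model.support_vectors if model.support_vectors.size \
            else np.zeros(3)
        np.testing.assert_allclose(beta, 0.0, atol=1e-9)
        assert abs(model.intercept - 4.0) <= 0.1 + 1e-9

    def test_deterministic_refit(self):
        d = random_design()
        y = np.random.default_rng(3).normal(size=d.n_subjects)
        a = fit_svr(d, y, "linear", C=2.0)
        b = fit_svr(d, y, "linear", C=2.0)
        np.testing.assert_array_equal(a.dual_coef, b.dual_coef)
        assert a.intercept == b.intercept

    def test_dual_coef_bounded_by_c(self):
        d = random_design()
        y = np.random.default_rng(4).normal(size=d.n_subjects)
        for C in (0.01, 1.0, 100.0):
            model = fit_svr(d, y, "linear", C=C)
            assert (np.abs(model.dual_coef) <= C + 1e-10).all()

    def test_invalid_params(self):
        d = random_design()
        y = np.zeros(d.n_subjects)
        with pytest.raises(ValueError):
            fit_svr(d, y, "linear", C=-1.0)
        with pytest.raises(ValueError):
            fit_svr(d, y, "rbf", C=1.0, gamma=None)


class TestExtractBeta:
    def test_primal_dual_consistency(self):
        d = random_design()
        y = np.random.default_rng(5).normal(size=d.n_subjects)
        model = fit_svr(d, y, "linear", C=10.0)
        betas = extract_beta(model, d)
        beta = betas.concatenated()
        pred = d.matrix @ beta + model.intercept
        assert np.abs(pred - model.predict(d.matrix)).max() < 1e-6

    def test_zero_column_zero_beta(self):
        rng = np.random.default_rng(6)
        data = (rng.random((20, 5)) < 0.5).astype(np.uint8)
        data[:, 2] = 0
        data[0, 2] = 0  # keep column all-zero
        t = make_tensor(data, grid_shape=(4, 4, 4))
        # bypass filtering: build design manually so the zero column stays
        d = MultiLesionDesign(
            columns=[("AIL", int(v)) for v in range(5)], matrix=data.astype(float),
            volume_mode="none", grid=t.grid, subject_ids=t.subject_ids,
            block_slices={"AIL": slice(0, 5)})
        y = rng.normal(size=20)
        model = fit_svr(d, y, "linear", C=5.0)
        betas = extract_beta(model, d)
        assert betas.blocks["AIL"][2] == 0.0

    def test_planted_voxel_has_peak_beta(self):
        rng = np.random.default_rng(7)
        data = (rng.random((50, 15)) < 0.4).astype(np.uint8)
        y = 5.0 * data[:, 4]  # noise-free signal at voxel 4
        t = make_tensor(data, grid_shape=(4, 4, 4))
        d = build_single_design(t, k=1)
        model = fit_svr(d, (y - y.mean()) / y.std(), "linear", C=100.0)
        beta = extract_beta(model, d).blocks["AIL"]
        assert np.argmax(np.abs(beta)) == 4
        assert beta[4] > 0  # larger deficit => positive weight

    def test_block_split(self):
        rng = np.random.default_rng(8)
        ail = (rng.random((30, 8)) < 0.4).astype(np.uint8)
        wmh = (rng.random((30, 8)) < 0.4).astype(np.uint8) & (1 - ail)
        ta = make_tensor(ail, "AIL", grid_shape=(2, 2, 2))
        tw = make_tensor(wmh, "WMH", grid_shape=(2, 2, 2))
        d = build_multilesion_design(ta, tw, k=1)
        y = rng.normal(size=30)
        model = fit_svr(d, y, "linear", C=1.0)
        betas = extract_beta(model, d)
        assert len(betas.blocks["AIL"]) == d.block_slices["AIL"].stop
        total = len(betas.blocks["AIL"]) + len(betas.blocks["WMH"])
        assert total == d.n_columns

    def test_wrong_design_rejected(self):
        d1, d2 = random_design(v=10), random_design(v=12, seed=9)
        y = np.random.default_rng(10).normal(size=d1.n_subjects)
        model = fit_svr(d1, y, "linear", C=1.0)
        with pytest.raises(ValueError, match="not fitted on this design"):
            extract_beta(model, d2)


class TestLoocvTrain:
    def test_noiseless_linear_signal_high_accuracy(self):
        rng = np.random.default_rng(11)
        d = random_design(m=40, v=20, seed=11)
        w = np.zeros(20)
        w[[2, 7]] = [2.0, 1.0]
        y = d.matrix @ w
        rep = loocv_train(d, y, "linear", c_grid=2.0 ** np.arange(-2, 13, 2))
        assert rep.best_accuracy >= 0.99

    def test_constant_deficit_errors(self):
        d = random_design()
        with pytest.raises(ValueError, match="constant"):
            loocv_train(d, np.ones(d.n_subjects), "linear", c_grid=[1.0])

    def test_tie_break_toward_smaller_c(self):
        # a deficit SVR cannot fit at all yields identical (zero-ish) accuracy;
        # argmax picks the first, i.e. smallest, C
        d = random_design(m=12, v=3, seed=12)
        rng = np.random.default_rng(12)
        y = rng.normal(size=12)
        rep = loocv_train(d, y, "linear", c_grid=[0.5, 1.0, 2.0])
        ties = np.flatnonzero(np.isclose(rep.accuracy, rep.best_accuracy))
        assert rep.best_C == [0.5, 1.0, 2.0][ties[0]]

    def test_small_m_warns(self):
        d = random_design(m=6, v=4, seed=13)
        y = np.random.default_rng(13).normal(size=6)
        with pytest.warns(UserWarning, match="small"):
            loocv_train(d, y, "linear", c_grid=[1.0])

    def test_rbf_grid_search_shapes(self):
        d = random_design(m=15, v=6, seed=14)
        y = np.random.default_rng(14).normal(size=15)
        rep = loocv_train(d, y, "rbf", c_grid=[0.5, 1.0], gamma_grid=[1.0, 2.0, 4.0])
        assert rep.accuracy.shape == (2, 3)
        assert rep.best_C in (0.5, 1.0)
        assert rep.best_gamma in (1.0, 2.0, 4.0)

    def test_accuracy_invariant_to_deficit_sign_flip(self):
        d = random_design(m=25, v=10, seed=15)
        rng = np.random.default_rng(15)
        y = d.matrix @ rng.normal(size=10) + 0.2 * rng.normal(size=25)
        grid = [0.25, 4.0]
        a = loocv_train(d, y, "linear", c_grid=grid)
        b = loocv_train(d, -y, "linear", c_grid=grid)
        # standardization maps -y to -(z-scored y); the SVR problem is
        # symmetric under joint sign flip, so accuracies coincide up to the
        # libsvm solver tolerance
        np.testing.assert_allclose(a.accuracy, b.accuracy, atol=5e-3)


class TestTrainAndFit:
    def test_mlsm_reduction_to_lsm(self):
        rng = np.random.default_rng(16)
        ail = (rng.random((30, 12)) < 0.4).astype(np.uint8)
        ta = make_tensor(ail, "AIL", grid_shape=(4, 4, 4), voxel_index=np.arange(12))
        empty = make_tensor(np.zeros((30, 12), dtype=np.uint8), "WMH",
                            grid_shape=(4, 4, 4), voxel_index=np.arange(12))
        y = ail @ rng.normal(size=12) + 0.3 * rng.normal(size=30)
        grid = [0.5, 8.0]
        d_multi = build_multilesion_design(ta, empty, k=2)
        d_single = build_single_design(ta, k=2)
        _, _, b_multi = train_and_fit(d_multi, y, c_grid=grid)
        _, _, b_single = train_and_fit(d_single, y, c_grid=grid)
        np.testing.assert_allclose(b_multi.blocks["AIL"], b_single.blocks["AIL"],
                                   atol=1e-8)
        assert b_multi.blocks["WMH"].size == 0

    def test_rbf_rejected_for_multilesion(self):
        rng = np.random.default_rng(17)
        ail = (rng.random((20, 6)) < 0.5).astype(np.uint8)
        wmh = (rng.random((20, 6)) < 0.5).astype(np.uint8) & (1 - ail)
        d = build_multilesion_design(
            make_tensor(ail, "AIL", grid_shape=(2, 2, 2)),
            make_tensor(wmh, "WMH", grid_shape=(2, 2, 2)), k=1)
        with pytest.raises(ValueError, match="linear kernel only"):
            train_and_fit(d, rng.normal(size=20), kernel="rbf", c_grid=[1.0])

    def test_scaling_covariance(self):
        # X -> cX with C -> C/c^2 leaves the decision function unchanged
        d = random_design(m=25, v=8, seed=18)
        rng = np.random.default_rng(18)
        y = rng.normal(size=25)
        c = 3.0
        m1 = fit_svr(d.matrix, y, "linear", C=4.0, tol=1e-8)
        m2 = fit_svr(c * d.matrix, y, "linear", C=4.0 / c ** 2, tol=1e-8)
        np.testing.assert_allclose(m1.predict(d.matrix), m2.predict(c * d.matrix),
                                   atol=1e-6)
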