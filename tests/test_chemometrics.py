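"""PCA, network initialisation, SCG training and prediction."""
import numpy as np
import pytest

from serscal import (
    ANNModel,
    ANNTopology,
    DegenerateInputError,
    TrainConfig,
    ann_init,
    ann_predict,
    calibrate_ann,
    pca_fit,
)
from serscal.chemometrics import scg_minimize, scg_train
from serscal.spectra import concentration_matrix


class TestPCA:
    def test_dominant_direction_separates_clusters(self):
        rng = np.random.default_rng(0)
        X = 0.01 * rng.standard_normal((40, 30))
        X[:20, 3] += 5.0
        res = pca_fit(X, 2)
        assert res.explained_variance_fraction[0] > res.explained_variance_fraction[1]
        s = res.scores[:, 0]
        assert (s[:20].mean() - s[20:].mean()) ** 2 > 9 * (s.var() / 10)

    def test_full_reconstruction_is_exact(self):
        X = np.random.default_rng(1).standard_normal((15, 8))
        res = pca_fit(X, 8)
        assert np.allclose(res.reconstruct(), X, atol=1e-8)
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(8), atol=1e-8)

    def test_rank_one_matrix_explained_by_first_component(self):
        u = np.random.default_rng(2).standard_normal(20)
        v = np.random.default_rng(3).standard_normal(9)
        res = pca_fit(np.outer(u, v), 2)
        assert res.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-10)

    def test_explained_fractions_non_increasing_and_bounded(self):
        X = np.random.default_rng(4).standard_normal((30, 12))
        res = pca_fit(X, 6)
        evf = res.explained_variance_fraction
        assert np.all(np.diff(evf) <= 1e-12) and evf.sum() <= 1 + 1e-12

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            pca_fit(np.zeros((5, 10)), 5)


class TestAnnInit:
    def test_same_seed_identical_weights(self):
        t = ANNTopology(50, 20, 3)
        a, b = ann_init(t, 7), ann_init(t, 7)
        assert np.array_equal(a.w1, b.w1) and np.array_equal(a.b2, b.b2)

    def test_different_seeds_differ(self):
        t = ANNTopology(50, 20, 1)
        assert not np.array_equal(ann_init(t, 1).w1, ann_init(t, 2).w1)

    def test_paper_topology_shapes(self):
        m = ann_init(ANNTopology(1024, 20, 3), 0)
        assert m.w1.shape == (1024, 20) and m.w2.shape == (20, 3)
        assert m.b1.shape == (20,) and m.b2.shape == (3,)

    def test_topology_parse_roundtrip(self):
        t = ANNTopology.parse("1024-20-3")
        assert t == ANNTopology(1024, 20, 3) and str(t) == "1024-20-3"


class TestSCGMinimize:
    def test_matches_normal_equations_on_linear_least_squares(self):
        """Oracle equivalence: SCG on the convex quadratic MSE of a linear
        model must reach the normal-equations solution."""
        rng = np.random.default_rng(0)
        X = rng.standard_normal((120, 30))
        y = X @ rng.standard_normal(30) + 0.1 * rng.standard_normal(120)

        def fg(w):
            r = X @ w - y
            return float(np.mean(r**2)), (2.0 / y.size) * (X.T @ r)

        w, _ = scg_minimize(fg, np.zeros(30), max_iter=3000, gtol=1e-12)
        w_ref = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.linalg.norm(w - w_ref) / np.linalg.norm(w_ref) < 1e-6

    def test_non_finite_objective_aborts_with_diagnostic(self):
        def fg(w):
            return float(np.sum(np.exp(w * 100))), 100 * np.exp(w * 100)

        with pytest.raises(FloatingPointError):
            scg_minimize(fg, np.full(3, 50.0), max_iter=50)


@pytest.fixture(scope="module")
def linear_fit(noisefree_small_preprocessed, noisefree_small_dataset):
    """Network trained to convergence on exact noise-free mixing data."""
    X = noisefree_small_preprocessed.intensities
    Y = concentration_matrix(noisefree_small_dataset.concentrations)[:, 1:2]
    cfg = TrainConfig(max_epochs=500, patience=100, seed=0)
    model = calibrate_ann(X, Y, X, Y, ANNTopology(X.shape[1], 20, 1), cfg)
    return model, X, Y


class TestSCGTrain:
    def test_fits_noise_free_linear_mixing(self, linear_fit):
        """A linear problem an MLP must solve: the least-squares oracle has
        (numerically) zero residual on these data, and SCG training drives
        the network MSE below 1e-4 of the target variance."""
        model, X, Y = linear_fit
        ls_resid = np.linalg.lstsq(
            np.column_stack([X, np.ones(len(X))]), Y, rcond=None
        )[1]
        assert ls_resid.size == 0 or ls_resid[0] < 1e-12 * Y.var() * len(Y)
        pred = ann_predict(model, X)
        assert np.mean((pred - Y) ** 2) < 1e-4 * Y.var()

    def test_single_epoch_bookkeeping(self, noisefree_small_preprocessed,
                                      noisefree_small_dataset):
        X = noisefree_small_preprocessed.intensities
        Y = concentration_matrix(noisefree_small_dataset.concentrations)[:, :1]
        m = calibrate_ann(X, Y, X, Y, ANNTopology(X.shape[1], 20, 1),
                          TrainConfig(max_epochs=1, seed=0))
        assert len(m.history["train"]) == 1 and len(m.history["val"]) == 1
        assert m.best_epoch == 1

    def test_best_epoch_is_validation_argmin(self, linear_fit):
        model, _, _ = linear_fit
        val = np.array(model.history["val"])
        assert model.best_epoch == int(np.argmin(val)) + 1
        assert val[model.best_epoch - 1] <= val.min() + 1e-15

    def test_training_error_non_increasing(self, linear_fit):
        """SCG never accepts a step that worsens the objective, so the
        recorded training curve is monotone non-increasing."""
        model, _, _ = linear_fit
        tr = np.array(model.history["train"])
        assert np.all(np.diff(tr) <= 1e-15)

    def test_training_is_deterministic(self, noisefree_small_preprocessed,
                                       noisefree_small_dataset):
        X = noisefree_small_preprocessed.intensities
        Y = concentration_matrix(noisefree_small_dataset.concentrations)[:, :1]
        cfg = TrainConfig(max_epochs=40, seed=9)
        t = ANNTopology(X.shape[1], 20, 1)
        m1 = calibrate_ann(X[:30], Y[:30], X[30:], Y[30:], t, cfg)
        m2 = calibrate_ann(X[:30], Y[:30], X[30:], Y[30:], t, cfg)
        assert m1.history["train"] == m2.history["train"]
        assert np.array_equal(m1.w1, m2.w1)

    def test_constant_targets_rejected(self):
        X = np.random.default_rng(0).standard_normal((20, 5))
        Y = np.ones((20, 1))
        m = ann_init(ANNTopology(5, 4, 1), 0)
        with pytest.raises(DegenerateInputError):
            scg_train(m, X, Y, X, Y, TrainConfig(max_epochs=5))


class TestAnnPredict:
    def test_converged_fit_predicts_training_targets(self, linear_fit):
        model, X, Y = linear_fit
        pred = ann_predict(model, X)
        span = Y.max() - Y.min()
        assert np.max(np.abs(pred - Y)) < 0.01 * span

    def test_zero_weights_predict_constant(self):
        t = ANNTopology(8, 4, 2)
        m = ann_init(t, 0)
        m.w1[:], m.b1[:], m.w2[:] = 0, 0, 0
        m.b2[:] = [0.5, 0.1]
        out = ann_predict(m, np.random.default_rng(0).standard_normal((6, 8)))
        assert np.allclose(out, np.tile([0.5, 0.1], (6, 1)))

    def test_batch_equals_rowwise(self, linear_fit):
        model, X, _ = linear_fit
        batch = ann_predict(model, X[:5])
        rows = np.vstack([ann_predict(model, X[i]) for i in range(5)])
        assert np.allclose(batch, rows, atol=1e-14)

    def test_channel_mismatch_rejected(self, linear_fit):
        model, _, _ = linear_fit
        with pytest.raises(ValueError):
            ann_predict(model, np.zeros((3, 7)))


class TestSerialization:
    def test_json_roundtrip_preserves_predictions(self, linear_fit):
        model, X, _ = linear_fit
        clone = ANNModel.from_json(model.to_json())
        assert np.allclose(ann_predict(clone, X), ann_predict(model, X), atol=1e-15)
        assert clone.best_epoch == model.best_epoch
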