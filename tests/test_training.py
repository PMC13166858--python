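import math

import numpy as np
import pytest

from depmci.autodiff import Tensor
from depmci.model import ModelConfig, forward_predict, init_params
from depmci.pipeline import WindowSample
from depmci.training import (
    AdamW,
    MetricsReport,
    OptimizerState,
    TrainConfig,
    adamw_step,
    bce_loss,
    compute_gradients,
    compute_metrics,
    export_attention_heatmap,
    predict,
    run_baselines,
    samples_to_arrays,
    train,
    tune_grid,
)


class TestBceLoss:
    def test_perfect_prediction_vanishes(self):
        assert bce_loss([1.0], [1 - 1e-9]) == pytest.approx(0.0, abs=1e-6)

    def test_single_half_is_log_two(self):
        assert bce_loss([1.0], [0.5]) == pytest.approx(math.log(2), abs=1e-12)

    def test_two_sample_hand_value(self):
        got = bce_loss([1.0, 0.0], [0.8, 0.3])
        assert got == pytest.approx(-(math.log(0.8) + math.log(0.7)), abs=1e-12)
        assert got == pytest.approx(0.5798, abs=1e-4)

    def test_mean_reduction_divides_by_n(self):
        s = bce_loss([1.0, 0.0], [0.8, 0.3], reduction="sum")
        m = bce_loss([1.0, 0.0], [0.8, 0.3], reduction="mean")
        assert m == pytest.approx(s / 2)

    def test_probabilities_at_bounds_are_clamped_finite(self):
        assert np.isfinite(bce_loss([1.0, 0.0], [0.0, 1.0]))

    def test_tensor_path_matches_numpy_path(self):
        y = np.array([1.0, 0.0, 1.0])
        p = np.array([0.9, 0.2, 0.6])
        t = bce_loss(y, Tensor(p, requires_grad=True))
        assert float(t.data) == pytest.approx(bce_loss(y, p), abs=1e-12)


def _oracle_adamw(theta, grads, lr=3e-4, b1=0.9, b2=0.999, lam=0.01, eps=1e-8):
    """Straight-line re-implementation of the update recurrences."""
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    out = [theta.copy()]
    for t, g in enumerate(grads, start=1):
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        m_hat = m / (1 - b1**t)
        v_hat = v / (1 - b2**t)
        theta = theta - lr * m_hat / (np.sqrt(v_hat) + eps) - lam * theta
        out.append(theta.copy())
    return out


class TestAdamW:
    def test_first_step_hand_value(self):
        state = OptimizerState.zeros_like(np.array(1.0))
        theta = adamw_step(np.array(1.0), np.array(1.0), state)
        # 1 - 3e-4 * 1/(1 + eps) - 0.01 * 1
        assert float(theta) == pytest.approx(0.9897, abs=1e-6)
        assert state.t == 1

    def test_zero_gradient_is_pure_decay(self):
        state = OptimizerState.zeros_like(np.array(2.0))
        theta = adamw_step(np.array(2.0), np.array(0.0), state)
        assert float(theta) == pytest.approx(2.0 - 0.01 * 2.0, abs=1e-15)

    def test_three_steps_on_scalar_quadratic_match_oracle(self):
        theta = np.array(1.5)
        state = OptimizerState.zeros_like(theta)
        thetas = [theta.copy()]
        grads = []
        for _ in range(3):
            g = 2.0 * theta  # gradient of theta^2
            grads.append(np.array(g))
            theta = adamw_step(theta, np.array(g), state)
            thetas.append(theta.copy())
        want = _oracle_adamw(np.array(1.5), grads)
        for a, b in zip(thetas, want):
            assert float(a) == pytest.approx(float(b), abs=1e-12)

    def test_hundred_random_steps_match_oracle(self):
        rng = np.random.default_rng(0)
        theta = rng.normal(size=(3, 4))
        grads = [rng.normal(size=(3, 4)) for _ in range(100)]
        state = OptimizerState.zeros_like(theta)
        got = theta.copy()
        for g in grads:
            got = adamw_step(got, g, state)
        want = _oracle_adamw(theta, grads)[-1]
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        state = OptimizerState.zeros_like(np.zeros(3))
        with pytest.raises(ValueError, match="shape"):
            adamw_step(np.zeros(3), np.zeros(4), state)

    def test_decay_applies_to_every_parameter(self):
        cfg = ModelConfig(n_features=2, d_model=4, n_heads=2, d_ffn=8,
                          dropout=0.0, max_seq_len=2)
        params = init_params(cfg, seed=0)
        params["enc0.norm1.gamma"].data[:] = 1.0
        opt = AdamW(params)
        opt.step({k: np.zeros_like(p.data) for k, p in params.items()})
        np.testing.assert_allclose(params["enc0.norm1.gamma"].data, 0.99)


def _tiny_dataset(n=40, n_features=4, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2, n_features))
    # separable-ish labels from the feature change between waves
    y = (X[:, 1, 0] - X[:, 0, 0] + 0.3 * rng.normal(size=n) > 0).astype(float)
    return X, y


def _tiny_splits(seed=0):
    X, y = _tiny_dataset(seed=seed)
    samples = [WindowSample(f"p{i}", 1, X[i], int(y[i])) for i in range(len(y))]
    return samples[:24], samples[24:32], samples[32:]


class TestGradientAccumulation:
    @pytest.mark.parametrize("k", [1, 2, 4])
    def test_mean_of_equal_batches_equals_union_gradient(self, k):
        cfg = ModelConfig(n_features=4, d_model=8, n_heads=2, d_ffn=16,
                          dropout=0.0, max_seq_len=2)
        params = init_params(cfg, seed=1)
        params["head.W"].data = np.random.default_rng(2).normal(
            0, 0.3, params["head.W"].shape)
        X, y = _tiny_dataset(n=8 * k, seed=3)
        union_grads, _ = compute_gradients(params, cfg, X, y)
        parts = []
        for i in range(k):
            g, _ = compute_gradients(params, cfg, X[8 * i:8 * (i + 1)],
                                     y[8 * i:8 * (i + 1)])
            parts.append(g)
        for name in union_grads:
            mean = np.mean([p[name] for p in parts], axis=0)
            np.testing.assert_allclose(mean, union_grads[name], atol=1e-6)


class TestTrainLoop:
    def _config(self, **kw):
        return ModelConfig(n_features=4, d_model=8, n_heads=2, d_ffn=16,
                           dropout=0.1, max_seq_len=2)

    def test_same_seed_identical_final_weights(self):
        splits = _tiny_splits()
        tc = TrainConfig(batch_size=8, max_epochs=3, patience=3, seed=5)
        a = train(self._config(), splits, tc)
        b = train(self._config(), splits, tc)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k].data, b.params[k].data)

    def test_zero_patience_stops_at_first_non_improvement(self):
        splits = _tiny_splits()
        tc = TrainConfig(batch_size=8, max_epochs=30, patience=0, seed=6)
        res = train(self._config(), splits, tc)
        scores = [h["val_auc"] for h in res.history]
        # every epoch before the last strictly improved on the running best
        best = -np.inf
        for s in scores[:-1]:
            assert s > best
            best = max(best, s)
        if len(scores) < 30:
            assert scores[-1] <= best

    def test_validation_missing_a_class_rejected(self):
        tr, va, te = _tiny_splits()
        va = [s for s in va if s.label == 0] or va[:1]
        with pytest.raises(ValueError, match="class"):
            train(self._config(), (tr, va, te),
                  TrainConfig(batch_size=8, max_epochs=2, seed=0))


class TestMetrics:
    def _scores_for_counts(self, tp, fn, tn, fp):
        y = [1] * tp + [1] * fn + [0] * tn + [0] * fp
        p = [0.9] * tp + [0.1] * fn + [0.2] * tn + [0.8] * fp
        return np.array(y), np.array(p)

    def test_hand_confusion_example(self):
        y, p = self._scores_for_counts(tp=3, fn=2, tn=4, fp=1)
        rep = compute_metrics(y, p)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (3, 2, 4, 1)
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.sensitivity == pytest.approx(0.6)
        assert rep.precision == pytest.approx(0.75)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.f1 == pytest.approx(2 / 3, abs=1e-4)

    def test_perfect_separation_scores_one_everywhere(self):
        y = np.array([1, 1, 0, 0])
        p = np.array([0.9, 0.8, 0.2, 0.1])
        rep = compute_metrics(y, p)
        for v in (rep.accuracy, rep.sensitivity, rep.precision,
                  rep.specificity, rep.f1, rep.auc):
            assert v == pytest.approx(1.0)

    def test_identities_on_random_confusion_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            tp, fn, tn, fp = rng.integers(0, 8, size=4)
            if tp + fn == 0 or tn + fp == 0:
                continue  # AUC needs both classes
            y, p = self._scores_for_counts(tp, fn, tn, fp)
            rep = compute_metrics(y, p)
            n = tp + fn + tn + fp
            assert rep.accuracy == pytest.approx((tp + tn) / n)
            assert rep.sensitivity == pytest.approx(tp / (tp + fn))
            if tp + fp == 0:
                assert rep.precision is None and "precision" in rep.notes
            else:
                assert rep.precision == pytest.approx(tp / (tp + fp))
            assert rep.specificity == pytest.approx(tn / (tn + fp))
            if rep.precision not in (None, 0) or rep.sensitivity != 0:
                if rep.precision is not None and (rep.precision + rep.sensitivity) > 0:
                    assert rep.f1 == pytest.approx(
                        2 * rep.precision * rep.sensitivity
                        / (rep.precision + rep.sensitivity))

    def test_auc_equals_pairwise_concordance(self):
        """Trapezoidal ROC integration equals the Mann-Whitney statistic
        (ties counted half), checked on 100 random score sets including
        heavily tied ones, and cross-checked against scikit-learn."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        for i in range(100):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            p = np.round(rng.random(n), 1 if i % 2 else 3)  # force ties
            rep = compute_metrics(y, p)
            pos, neg = p[y == 1], p[y == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            concordance = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert rep.auc == pytest.approx(concordance, abs=1e-12)
            assert rep.auc == pytest.approx(roc_auc_score(y, p), abs=1e-12)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            compute_metrics([1, 1, 1], [0.2, 0.5, 0.9])


class TestTuning:
    def test_single_cell_grid_returns_it(self):
        splits = _tiny_splits()
        mc = ModelConfig(n_features=4, d_model=8, n_heads=2, d_ffn=16,
                         dropout=0.0, max_seq_len=2)
        base = TrainConfig(batch_size=8, max_epochs=2, patience=1, seed=0)
        best, records = tune_grid({"lr": [1e-3]}, mc, splits, base)
        assert best["lr"] == 1e-3
        assert len(records) == 1

    def test_duplicates_deduplicated_and_argmax_consistent(self):
        splits = _tiny_splits()
        mc = ModelConfig(n_features=4, d_model=8, n_heads=2, d_ffn=16,
                         dropout=0.0, max_seq_len=2)
        base = TrainConfig(batch_size=8, max_epochs=2, patience=1, seed=0)
        best, records = tune_grid({"lr": [1e-3, 1e-3, 3e-3]}, mc, splits, base)
        assert len(records) == 2
        winner = max(records, key=lambda r: (r["val_auc"], r["val_f1"], -r["lr"]))
        assert best["lr"] == winner["lr"]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tune_grid({"lr": []}, None, _tiny_splits())


class TestBaselines:
    def _splits_from(self, X, y):
        samples = [WindowSample(f"p{i}", 1, X[i], int(y[i]))
                   for i in range(len(y))]
        return samples[:60], samples[60:80], samples[80:]

    def test_constant_features_are_chance_level(self):
        rng = np.random.default_rng(9)
        X = np.ones((120, 2, 3))
        y = rng.integers(0, 2, size=120)
        reports = run_baselines(self._splits_from(X, y), seed=0)
        for name in ("xgboost", "svm"):
            assert 0.35 <= reports[name]["test"].auc <= 0.65

    def test_same_seed_identical_reports(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(120, 2, 3))
        y = (X[:, 1, 0] > 0).astype(int)
        splits = self._splits_from(X, y)
        a = run_baselines(splits, seed=4)
        b = run_baselines(splits, seed=4)
        for name in a:
            assert a[name]["test"].to_dict() == b[name]["test"].to_dict()

    def test_planted_signal_beats_chance_with_bootstrap_margin(self):
        """On synthetic windows with a planted signal, both baseline learners
        beat AUC 0.5 at the 99% bootstrap level."""
        rng = np.random.default_rng(11)
        X = rng.normal(size=(300, 2, 4))
        y = ((X[:, 1, 0] - X[:, 0, 0]) + 0.5 * rng.normal(size=300) > 0).astype(int)
        samples = [WindowSample(f"p{i}", 1, X[i], int(y[i])) for i in range(300)]
        splits = samples[:200], samples[200:240], samples[240:]
        reports = run_baselines(splits, seed=1)
        X_te, y_te = samples_to_arrays(splits[2])
        for name in ("xgboost", "svm"):
            assert reports[name]["test"].auc > 0.5
        # bootstrap the test AUC of each learner over test indices
        from sklearn.svm import SVC
        from xgboost import XGBClassifier

        X_tr, y_tr = samples_to_arrays(splits[0])
        flat_tr, flat_te = X_tr.reshape(len(X_tr), -1), X_te.reshape(len(X_te), -1)
        for clf in (XGBClassifier(n_estimators=200, max_depth=3,
                                  random_state=1, n_jobs=1,
                                  eval_metric="logloss"),
                    SVC(kernel="rbf", random_state=1)):
            clf.fit(flat_tr, y_tr)
            s = (clf.predict_proba(flat_te)[:, 1]
                 if hasattr(clf, "predict_proba") else clf.decision_function(flat_te))
            boot = []
            brng = np.random.default_rng(2)
            for _ in range(400):
                idx = brng.integers(0, len(y_te), len(y_te))
                if y_te[idx].min() == y_te[idx].max():
                    continue
                boot.append(compute_metrics(y_te[idx], s[idx]).auc)
            assert np.quantile(boot, 0.01) > 0.5


class TestHeatmap:
    def _setup(self):
        cfg = ModelConfig(n_features=3, d_model=8, n_heads=2, d_ffn=16,
                          dropout=0.0, max_seq_len=2)
        params = init_params(cfg, seed=12)
        X = np.random.default_rng(13).normal(size=(5, 2, 3))
        return cfg, params, X

    def test_zero_projection_gives_zero_matrix(self):
        cfg, params, X = self._setup()
        params["input_proj.W"].data[:] = 0.0
        df = export_attention_heatmap(params, cfg, X, ["a", "b", "c"])
        assert (df.to_numpy() == 0).all()

    def test_shape_and_row_order_follow_manifest(self, tmp_path):
        cfg, params, X = self._setup()
        names = ["cesd_1", "cesd_2", "age"]
        out_csv = tmp_path / "heat.csv"
        out_png = tmp_path / "heat.png"
        df = export_attention_heatmap(params, cfg, X, names,
                                      out_csv=out_csv, out_png=out_png)
        assert df.shape == (3, cfg.d_model)
        assert list(df.index) == names
        assert out_csv.exists() and out_png.exists()

    def test_untrained_checkpoint_warns(self):
        cfg, params, X = self._setup()
        with pytest.warns(UserWarning, match="untrained"):
            export_attention_heatmap(params, cfg, X, ["a", "b", "c"],
                                     trained=False)
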