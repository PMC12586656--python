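"""Hybrid model: layers, training loop contracts, gradients, persistence."""

import copy

import numpy as np
import pytest

from aquaqnet.backbones import BackboneError, ToyConvBackbone, get_profile
from aquaqnet.model import (
    HybridFitResults,
    HybridQuantumClassifier,
    ModelSpec,
    TrainConfig,
    TrainingError,
    _forward,
    _loss_and_grads,
    classify,
    extract_features,
    fuse,
    init_params,
    init_state,
    project,
    split_fused,
)


class TestBackbones:
    def test_toy_backbone_deterministic_on_constant_input(self):
        bb = ToyConvBackbone(feature_dim=16, seed=1)
        zero = np.zeros((1, 32, 32, 3))
        a = bb.extract_features(zero)
        b = bb.extract_features(zero)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (1, 16)

    @pytest.mark.parametrize(
        "name,d",
        [
            ("resnet50", 2048),
            ("mobilenetv2", 1280),
            ("inceptionresnetv2", 1536),
            ("densenet201", 1920),
        ],
    )
    def test_profile_feature_widths(self, name, d):
        assert get_profile(name).feature_dim == d

    def test_metadata_profile_cannot_extract(self):
        class Fake:
            backbone_id = "resnet50"
            functional = False

        with pytest.raises(TrainingError):
            extract_features(np.zeros((1, 224, 224, 3)), Fake())

    def test_wrong_image_shape_rejected(self):
        bb = ToyConvBackbone(feature_dim=16, seed=0)
        with pytest.raises(BackboneError, match="expects"):
            bb.extract_features(np.zeros((1, 16, 16, 3)))

    def test_gap_of_channelwise_constant_map(self):
        # global average pooling of a per-channel constant returns the constant
        fmap = np.tile(np.arange(6.0), (1, 5, 5, 1))
        np.testing.assert_allclose(fmap.mean(axis=(1, 2))[0], np.arange(6.0))


class TestProjectFuse:
    def test_zero_weights_give_zero_projection(self):
        z = np.random.default_rng(0).normal(size=16)
        np.testing.assert_array_equal(
            project(z, np.zeros((4, 16)), np.zeros(4)), np.zeros(4)
        )

    def test_tanh_bound_strict(self):
        rng = np.random.default_rng(1)
        c = project(rng.normal(size=16) * 4, rng.normal(size=(4, 16)), rng.normal(size=4))
        assert np.all(np.abs(c) < 1.0)

    def test_matches_scalar_arithmetic_oracle(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=6)
        w = rng.normal(size=(4, 6))
        b = rng.normal(size=4)
        want = [np.tanh(sum(w[i, j] * z[j] for j in range(6)) + b[i]) for i in range(4)]
        np.testing.assert_allclose(project(z, w, b), want, atol=1e-12)

    def test_projection_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            project(np.zeros(5), np.zeros((4, 6)), np.zeros(4))

    def test_fuse_order_and_roundtrip(self):
        c = np.array([0.1, 0.2, 0.3, 0.4])
        q = np.array([-1.0, 0.0, 0.5, 1.0])
        u = fuse(c, q)
        np.testing.assert_array_equal(u, [0.1, 0.2, 0.3, 0.4, -1.0, 0.0, 0.5, 1.0])
        c2, q2 = split_fused(u)
        np.testing.assert_array_equal(c2, c)
        np.testing.assert_array_equal(q2, q)
        assert u.size == 8

    def test_fuse_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse(np.zeros(4), np.zeros(3))


class TestClassify:
    def _spec(self):
        return ModelSpec(backbone_id="toy", feature_dim=16, backbone_nontrainable=0)

    def test_all_zero_parameters_give_uniform(self):
        spec = self._spec()
        params = init_params(spec, np.random.default_rng(0))
        params = {k: np.zeros_like(v) for k, v in params.items()}
        probs = classify(np.zeros(8), params, spec, mode="infer")
        np.testing.assert_allclose(probs, np.full(5, 0.2), atol=1e-12)

    def test_softmax_shift_invariance(self):
        spec = self._spec()
        params = init_params(spec, np.random.default_rng(1))
        u = np.random.default_rng(2).uniform(-1, 1, 8)
        base = classify(u, params, spec)
        shifted = dict(params)
        shifted["out_b"] = params["out_b"] + 7.3
        np.testing.assert_allclose(
            classify(u, shifted, spec), base, atol=1e-12
        )

    def test_infer_mode_deterministic_and_normalized(self):
        spec = self._spec()
        params = init_params(spec, np.random.default_rng(3))
        u = np.random.default_rng(4).uniform(-1, 1, (5, 8))
        a = classify(u, params, spec)
        b = classify(u, params, spec)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(a >= 0)

    def test_invalid_mode_rejected(self):
        spec = self._spec()
        params = init_params(spec, np.random.default_rng(5))
        with pytest.raises(ValueError, match="mode"):
            classify(np.zeros(8), params, spec, mode="test")


class TestTraining:
    def test_separable_two_class_problem_learned(self):
        # two linearly separable clusters, 200 samples, toy-scale d=16
        rng = np.random.default_rng(6)
        z = np.concatenate(
            [rng.normal(-2, 0.5, size=(100, 16)), rng.normal(2, 0.5, size=(100, 16))]
        )
        y = np.repeat([0, 1], 100)
        perm = rng.permutation(200)
        spec = ModelSpec(
            backbone_id="toy", feature_dim=16, backbone_nontrainable=0, n_classes=2
        )
        model = HybridQuantumClassifier(
            z[perm][:160], y[perm][:160], z[perm][160:], y[perm][160:], spec=spec
        )
        res = model.fit(TrainConfig(seed=0, max_epochs=30))
        assert max(res.trace.train_acc) >= 0.95

    def test_early_stopping_halts_at_patience_plus_one(self, cluster_features):
        z_tr, y_tr, z_va, y_va = cluster_features
        spec = ModelSpec(backbone_id="toy", feature_dim=16, backbone_nontrainable=0)
        model = HybridQuantumClassifier(z_tr, y_tr, z_va, y_va, spec=spec)
        res = model.fit(
            TrainConfig(seed=0, max_epochs=50, early_stop_patience=5),
            _val_evaluator=lambda params, state: (1.0, 0.2),  # frozen val loss
        )
        assert res.trace.stopped_epoch == 6  # 1 best + 5 patience
        assert res.trace.best_epoch == 1

    def test_same_seed_gives_bit_identical_traces(self, cluster_features):
        z_tr, y_tr, z_va, y_va = cluster_features
        spec = ModelSpec(backbone_id="toy", feature_dim=16, backbone_nontrainable=0)

        def run():
            model = HybridQuantumClassifier(z_tr, y_tr, z_va, y_va, spec=spec)
            return model.fit(TrainConfig(seed=7, max_epochs=4))

        a, b = run(), run()
        assert a.trace.train_loss == b.trace.train_loss
        assert a.trace.val_loss == b.trace.val_loss
        assert a.trace.val_acc == b.trace.val_acc
        for key in a.params:
            np.testing.assert_array_equal(a.params[key], b.params[key])

    def test_trace_val_accuracy_matches_metrics_recomputation(self, cluster_features):
        z_tr, y_tr, z_va, y_va = cluster_features
        spec = ModelSpec(backbone_id="toy", feature_dim=16, backbone_nontrainable=0)
        model = HybridQuantumClassifier(z_tr, y_tr, z_va, y_va, spec=spec)
        res = model.fit(TrainConfig(seed=1, max_epochs=3))
        # restored best-epoch parameters must reproduce the logged accuracy
        report = res.evaluate(z_va, y_va)
        assert report.accuracy == pytest.approx(
            res.trace.val_acc[res.trace.best_epoch - 1]
        )

    def test_quantum_diagnostics_recorded(self, cluster_features):
        z_tr, y_tr, z_va, y_va = cluster_features
        spec = ModelSpec(backbone_id="toy", feature_dim=16, backbone_nontrainable=0)
        model = HybridQuantumClassifier(z_tr, y_tr, z_va, y_va, spec=spec)
        res = model.fit(
            TrainConfig(
                seed=2, max_epochs=2, record_quantum_diagnostics=True, probe_every=3
            )
        )
        assert len(res.trace.costs) > 0
        assert all(len(z) == 4 for z in res.trace.probe_z)
        assert all(len(t) == 24 for t in res.trace.theta_path)
        assert all(abs(v) <= 1 + 1e-9 for z in res.trace.probe_z for v in z)

    def test_empty_split_rejected(self):
        with pytest.raises(TrainingError):
            HybridQuantumClassifier(
                np.zeros((0, 16)), np.zeros(0, dtype=int),
                np.zeros((2, 16)), np.zeros(2, dtype=int),
            )

    def test_single_class_training_set_rejected(self):
        z = np.random.default_rng(0).normal(size=(10, 16))
        with pytest.raises(TrainingError):
            HybridQuantumClassifier(z, np.zeros(10, dtype=int), z, np.zeros(10, dtype=int))

    def test_unknown_optimizer_rejected(self, cluster_features):
        z_tr, y_tr, z_va, y_va = cluster_features
        spec = ModelSpec(backbone_id="toy", feature_dim=16, backbone_nontrainable=0)
        model = HybridQuantumClassifier(z_tr, y_tr, z_va, y_va, spec=spec)
        with pytest.raises(TrainingError, match="optimizer"):
            model.fit(TrainConfig(optimizer="adabob"))


class TestEndToEndGradient:
    def test_backprop_matches_finite_differences(self):
        # 3-sample micro-batch, dropout off so the loss is deterministic
        rng = np.random.default_rng(8)
        spec = ModelSpec(
            backbone_id="toy", feature_dim=6, backbone_nontrainable=0,
            n_classes=3, dropout_rate=0.0, head_widths=(8, 6),
        )
        z = rng.normal(size=(3, 6))
        y = np.array([0, 1, 2])
        params = init_params(spec, rng)

        def loss_at(p):
            state = init_state(spec)
            cache: dict = {}
            probs = _forward(z, p, state, spec, "train", rng, False, cache)
            return float(-np.mean(np.log(probs[np.arange(3), y] + 1e-12)))

        _, _, grads = _loss_and_grads(
            z, y, params, init_state(spec), spec, rng, update_state=False
        )
        h = 1e-6
        check_rng = np.random.default_rng(9)
        for key, p in params.items():
            flat_idx = check_rng.choice(
                p.size, size=min(10, p.size), replace=False
            )
            for idx in flat_idx:
                pp = {k: v.copy() for k, v in params.items()}
                pm = {k: v.copy() for k, v in params.items()}
                pp[key].flat[idx] += h
                pm[key].flat[idx] -= h
                fd = (loss_at(pp) - loss_at(pm)) / (2 * h)
                got = grads[key].flat[idx]
                if abs(fd) < 1e-8 and abs(got) < 1e-8:
                    continue  # below finite-difference noise floor
                denom = max(abs(fd), abs(got))
                assert abs(got - fd) / denom < 1e-4, (key, idx, got, fd)


class TestFrozenBackboneAndPersistence:
    def test_backbone_bytes_unchanged_by_training(self, small_corpus):
        images, labels, _ = small_corpus
        from aquaqnet.datasets import preprocess, stratified_split

        bb = ToyConvBackbone(feature_dim=16, seed=0)
        before = bb.parameter_bytes()
        tr, va, _ = stratified_split(labels, seed=0)
        x_tr = np.stack([preprocess(images[i], (32, 32), "scale01") for i in tr])
        x_va = np.stack([preprocess(images[i], (32, 32), "scale01") for i in va])
        model = HybridQuantumClassifier.from_images(
            x_tr, labels[tr], x_va, labels[va], bb
        )
        model.fit(TrainConfig(seed=0, max_epochs=2))
        assert bb.parameter_bytes() == before

    def test_checkpoint_roundtrip_preserves_predictions(
        self, cluster_features, tmp_path
    ):
        z_tr, y_tr, z_va, y_va = cluster_features
        spec = ModelSpec(backbone_id="toy", feature_dim=16, backbone_nontrainable=0)
        model = HybridQuantumClassifier(z_tr, y_tr, z_va, y_va, spec=spec)
        res = model.fit(TrainConfig(seed=3, max_epochs=3))
        path = tmp_path / "ckpt.json"
        res.save(path)
        loaded = HybridFitResults.load(path)
        np.testing.assert_allclose(
            loaded.predict_proba(z_va), res.predict_proba(z_va), atol=1e-12
        )
        assert loaded.spec == res.spec
        assert loaded.trace.best_epoch == res.trace.best_epoch

    def test_summary_mentions_key_quantities(self, cluster_features):
        z_tr, y_tr, z_va, y_va = cluster_features
        spec = ModelSpec(backbone_id="toy", feature_dim=16, backbone_nontrainable=0)
        res = HybridQuantumClassifier(z_tr, y_tr, z_va, y_va, spec=spec).fit(
            TrainConfig(seed=4, max_epochs=2)
        )
        text = res.summary()
        assert "4 qubits" in text
        assert f"{res.ledger.trainable_total:,}" in text
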