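"""Architecture contracts, auto-encoder, training strategy, prediction."""

import numpy as np
import pytest

from cape import nn
from cape.network import (
    Autoencoder,
    ConvKernel,
    EnhancerNetwork,
    NetworkConfig,
    WindowDataset,
    aggregate_origin,
    average_predictions,
    build_model,
    conv_activate,
    cross_cell_line_predict,
    softmax_probability,
    train_two_stage,
)
from cape.sampling import Sample
from cape.core_io import GenomicInterval


class TestConvActivate:
    kernel = ConvKernel(np.array([[1.0, -2.0], [3.0, 0.5]]))

    def test_positive_activation(self):
        x = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert conv_activate(x, self.kernel, 0) == pytest.approx(1.5)

    def test_relu_clamps_negative(self):
        x = np.array([[0.0, 1.0], [0.0, 0.0]])
        assert conv_activate(x, self.kernel, 0) == 0.0

    def test_out_of_range_position(self):
        with pytest.raises(ValueError):
            conv_activate(np.zeros((2, 2)), self.kernel, 1)

    def test_matches_double_loop_oracle(self):
        import math

        rng = np.random.default_rng(0)
        for _ in range(200):
            m, n, L = rng.integers(1, 6), rng.integers(1, 5), rng.integers(6, 15)
            kernel = ConvKernel(rng.standard_normal((m, n)))
            x = rng.standard_normal((L, n))
            i = int(rng.integers(0, L - m + 1))
            # fsum in transposed (channel-major) order: exactly-rounded
            # results must agree bit for bit regardless of order
            manual = math.fsum(
                kernel.weights[a, b] * x[i + a, b]
                for b in range(n) for a in range(m)
            )
            assert conv_activate(x, kernel, i) == max(manual, 0.0)


class TestSoftmaxProbability:
    def test_symmetry(self):
        np.testing.assert_allclose(softmax_probability((0.0, 0.0)), [0.5, 0.5])

    def test_analytic_pair(self):
        np.testing.assert_allclose(
            softmax_probability((0.0, np.log(3))), [0.25, 0.75], atol=1e-12
        )

    def test_large_logits_stable(self):
        p = softmax_probability((1000.0, 0.0))
        assert np.isfinite(p).all()
        assert p[0] == pytest.approx(1.0)

    def test_sums_to_one_for_huge_logits(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            z = rng.uniform(-1e4, 1e4, size=2)
            assert abs(softmax_probability(z).sum() - 1.0) < 1e-12


class TestArchitecture:
    def test_default_config_layer_shapes(self):
        model = build_model(NetworkConfig(), seed=0)
        shapes = model.layer_output_shapes("dna")
        assert shapes[0] == (300, 128)  # first conv, same padding
        assert shapes[4] == (150, 128)  # after first max-pool
        assert shapes[-1] == (75, 64)  # after second max-pool
        # DNase module identical geometry, 1 input channel
        assert model.layer_output_shapes("dnase") == shapes

    def test_forward_probabilities_sum_to_one(self):
        cfg = NetworkConfig.reduced(latent_len=40)
        model = build_model(cfg, seed=1)
        rng = np.random.default_rng(0)
        logits = model.forward(
            rng.random((3, 40, 4)).astype(np.float32),
            rng.random((3, 40, 1)).astype(np.float32),
        )
        probs = nn.softmax(logits)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_first_layer_kernels_shape(self):
        model = build_model(NetworkConfig.reduced(), seed=0)
        kernels = model.first_layer_kernels("dna")
        assert len(kernels) == 16
        assert kernels[0].weights.shape == (8, 4)

    def test_at_least_one_module_required(self):
        with pytest.raises(ValueError):
            build_model(NetworkConfig(use_dna=False, use_dnase=False))

    def test_save_load_round_trip(self, tmp_path):
        cfg = NetworkConfig.reduced(latent_len=24)
        model = build_model(cfg, seed=5)
        rng = np.random.default_rng(2)
        x_dna = rng.random((2, 24, 4)).astype(np.float32)
        x_enc = rng.random((2, 24, 1)).astype(np.float32)
        before = model.predict_proba(x_dna, x_enc)
        model.save(tmp_path / "m.npz")
        loaded = EnhancerNetwork.load(tmp_path / "m.npz")
        np.testing.assert_allclose(loaded.predict_proba(x_dna, x_enc), before)

    def test_deterministic_inference_and_batching(self):
        cfg = NetworkConfig.reduced(latent_len=24)
        model = build_model(cfg, seed=3)
        rng = np.random.default_rng(4)
        x_dna = rng.random((7, 24, 4)).astype(np.float32)
        x_enc = rng.random((7, 24, 1)).astype(np.float32)
        batch = model.predict_proba(x_dna, x_enc)
        np.testing.assert_allclose(model.predict_proba(x_dna, x_enc), batch)
        single = np.array([
            model.predict_proba(x_dna[i:i + 1], x_enc[i:i + 1])[0] for i in range(7)
        ])
        np.testing.assert_allclose(single, batch, atol=1e-6)


class TestAutoencoder:
    def test_encoder_output_shape_independent_of_k(self):
        rng = np.random.default_rng(0)
        for k in (3, 5):
            ae = Autoencoder(k, latent_len=50, seed=1)
            x = rng.random((4, 50, k)).astype(np.float32)
            assert ae.encode(x).shape == (4, 50, 1)

    def test_training_reduces_reconstruction_loss(self):
        rng = np.random.default_rng(1)
        x = rng.random((64, 30, 2)).astype(np.float32)
        ae = Autoencoder(2, latent_len=30, seed=2)
        before = ae.reconstruction_loss(x)
        ae.fit(x, epochs=20, batch_size=8, seed=3)
        assert ae.reconstruction_loss(x) < before

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            Autoencoder(0)


def _toy_dataset(n_origins=30, latent=40, k=2, seed=0, separable=True):
    """Tiny separable dataset: positives carry a distinctive block in both
    channels."""
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n_origins):
        label = i % 2
        seq_idx = rng.integers(0, 4, size=latent)
        acc = rng.random((k, latent)).astype(np.float32)
        if label and separable:
            seq_idx[10:18] = [3, 2, 0, 1, 2, 3, 0, 1]
            acc[:, 10:18] += 3.0
        seq = "".join("ACGT"[j] for j in seq_idx)
        samples.append(
            Sample(
                origin_id=f"o{i}",
                window=GenomicInterval("c", 0, latent),
                label=int(label),
                fold=i % 5,
                sequence=seq,
                accessibility=acc,
            )
        )
    return WindowDataset.from_samples(samples)


class TestTwoStageTraining:
    def test_feature_modules_frozen_in_stage2(self):
        dataset = _toy_dataset(40, seed=1)
        cfg = NetworkConfig.reduced(latent_len=40, epochs_stage1=2, epochs_stage2=3)
        model = build_model(cfg, seed=0)
        model, log, ae = train_two_stage(model, dataset, fold_id=0, seed=0)
        stage2 = [r for r in log if r.stage == 2]
        assert len(stage2) >= 1
        digests = {r.feature_module_checksum for r in stage2}
        assert len(digests) == 1
        # and the frozen digest equals the end-of-stage-1 digest
        stage1 = [r for r in log if r.stage == 1]
        assert stage1[-1].feature_module_checksum == stage2[0].feature_module_checksum

    def test_stage1_uses_balanced_classes(self, monkeypatch):
        from cape import network as net

        captured = []
        orig = net._train_stage

        def spy(model, x_dna, x_enc, y, stage, epochs, cfg, seed, log, **kw):
            captured.append((stage, np.bincount(y, minlength=2)))
            return orig(model, x_dna, x_enc, y, stage, epochs, cfg, seed, log, **kw)

        monkeypatch.setattr(net, "_train_stage", spy)
        dataset = _toy_dataset(40, seed=2)
        cfg = NetworkConfig.reduced(latent_len=40, epochs_stage1=1, epochs_stage2=1)
        model = build_model(cfg, seed=0)
        net.train_two_stage(model, dataset, fold_id=0, seed=0)
        stage1_counts = [c for s, c in captured if s == 1][0]
        assert stage1_counts[0] == stage1_counts[1]

    def test_single_class_training_rejected(self):
        dataset = _toy_dataset(20, seed=3)
        dataset.y[:] = 1
        cfg = NetworkConfig.reduced(latent_len=40)
        with pytest.raises(ValueError):
            train_two_stage(build_model(cfg, seed=0), dataset, fold_id=0, seed=0)

    def test_training_improves_loss_on_separable_data(self):
        dataset = _toy_dataset(60, seed=4)
        cfg = NetworkConfig.reduced(latent_len=40, epochs_stage1=8, epochs_stage2=2)
        model = build_model(cfg, seed=1)
        train = dataset.subset(dataset.fold != 0)
        ae = Autoencoder(2, latent_len=40, seed=0)
        ae.fit(train.x_acc, epochs=3, seed=0)
        x_enc = ae.encode(train.x_acc)
        loss0, _ = nn.softmax_cross_entropy(
            model.forward(train.x_dna, x_enc), train.y
        )
        model, log, ae2 = train_two_stage(model, dataset, fold_id=0, seed=1,
                                          autoencoder=ae)
        x_enc = ae.encode(train.x_acc)
        loss1, _ = nn.softmax_cross_entropy(
            model.forward(train.x_dna, x_enc), train.y
        )
        assert loss1 < loss0


class TestAggregation:
    def test_mean(self):
        assert aggregate_origin([0.2, 0.4, 0.9], "mean") == pytest.approx(0.5)

    def test_max(self):
        assert aggregate_origin([0.2, 0.4, 0.9], "max") == pytest.approx(0.9)

    def test_single_window_identity(self):
        assert aggregate_origin([0.7], "mean") == pytest.approx(0.7)
        assert aggregate_origin([0.7], "max") == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_origin([], "mean")

    def test_unknown_aggregator(self):
        with pytest.raises(ValueError):
            aggregate_origin([0.5], "median")


class TestCollectiveScoring:
    def test_unweighted_mean(self):
        per_model = [{"a": 0.2}, {"a": 0.4}, {"a": 0.6}]
        assert average_predictions(per_model)["a"] == pytest.approx(0.4)

    def test_identical_models_equal_single(self):
        preds = {"a": 0.3, "b": 0.8}
        assert average_predictions([preds] * 5) == pytest.approx(preds)

    def test_eight_models(self):
        rng = np.random.default_rng(0)
        per_model = [{"a": float(rng.random())} for _ in range(8)]
        expected = np.mean([p["a"] for p in per_model])
        assert average_predictions(per_model)["a"] == pytest.approx(expected)

    def test_mismatched_origins_rejected(self):
        with pytest.raises(ValueError):
            average_predictions([{"a": 0.1}, {"b": 0.2}])

    def test_cross_cell_line_identical_models_match_single(self):
        dataset = _toy_dataset(20, latent=40, seed=5)
        cfg = NetworkConfig.reduced(latent_len=40, ae_epochs=2)
        model = build_model(cfg, seed=2)
        single = cross_cell_line_predict([model], dataset, ae_seed=7, ae_epochs=2)
        triple = cross_cell_line_predict([model] * 3, dataset, ae_seed=7,
                                         ae_epochs=2)
        for a, b in zip(single, triple):
            assert a.origin_id == b.origin_id
            assert a.aggregate == pytest.approx(b.aggregate, abs=1e-9)
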