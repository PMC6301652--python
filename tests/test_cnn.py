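import numpy as np
import pytest

from penyek import pipeline
from penyek.cnn import (
    AugmentConfig,
    CNNStructure,
    FineTuneConfig,
    TABLE_PRESETS,
    TrainConfig,
    augment,
    bootstrap_hard_negatives,
    build_network,
    build_structure,
    build_vgg16,
    convolve_reference,
    load_result,
    numerical_gradient_check,
    predict,
    rotate_patch,
    save_result,
    spatial_sizes,
    train,
    translate_patch,
)
from penyek.cnn.network import Conv2D
from penyek.preproc import Patch


class TestConvolveReference:
    def test_identity_kernel(self):
        assert list(convolve_reference([1, 2, 3], [1])) == [1, 2, 3]

    def test_box_kernel_expansion(self):
        # y_0=x_0 h_0, y_1=x_0 h_1 + x_1 h_0, ... expanded by hand
        assert list(convolve_reference([1, 1, 1], [1, 1])) == [1, 2, 2, 1]

    def test_zero_kernel_annihilates(self, rng):
        x = rng.normal(size=7)
        assert np.allclose(convolve_reference(x, [0, 0, 0]), 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            convolve_reference([], [1])

    def test_linearity(self, rng):
        x1, x2 = rng.normal(size=(2, 6))
        h = rng.normal(size=3)
        lhs = convolve_reference(2 * x1 + x2, h)
        rhs = 2 * convolve_reference(x1, h) + convolve_reference(x2, h)
        assert np.allclose(lhs, rhs)


class TestConvLayerOracle:
    def test_matches_reference_on_rows(self, rng):
        """A conv layer on a 1xN raster with the kernel concentrated in its
        middle row equals the flipped-kernel full convolution, cropped to
        the central N samples ('same' boundary convention)."""
        for _ in range(10):
            n = int(rng.integers(5, 16))
            k = int(rng.choice([3, 5]))
            x = rng.normal(size=n)
            h = rng.normal(size=k)
            layer = Conv2D(1, 1, k, rng, dtype=np.float64)
            kernel = np.zeros((1, k, k))
            kernel[0, k // 2, :] = h
            layer.w.value = kernel.reshape(-1, 1)
            layer.b.value[:] = 0.0
            out = layer.forward(x.reshape(1, 1, 1, n))[0, 0, 0]
            full = convolve_reference(x, h[::-1])
            crop = full[k // 2 : k // 2 + n]
            assert np.allclose(out, crop, atol=1e-12)


class TestBuildStructure:
    def test_preset_1(self):
        s = build_structure(1, input_size=21, head_classes=3)
        assert s.conv_kernel_sizes == (3, 3)
        assert s.feature_maps == (16, 16)
        assert s.pool_kernel_sizes == (3, 3)
        assert s.fc_outputs == (128, 3)

    def test_preset_7(self):
        s = build_structure(7, input_size=224, head_classes=3)
        assert s.conv_kernel_sizes == (11, 5, 3, 3, 3)
        assert s.feature_maps == (96, 256, 384, 384, 256)
        assert s.fc_outputs == (4096, 4096, 3)

    def test_unknown_id(self):
        with pytest.raises(ValueError, match="1..7"):
            build_structure(8)

    def test_head_override_defaults_to_two(self):
        assert build_structure(4).fc_outputs[-1] == 2

    def test_forward_emits_probabilities(self, rng):
        s = build_structure(1, input_size=21, input_channels=1)
        net = build_network(s, seed=0)
        probs = net.predict_proba(rng.normal(size=(4, 1, 21, 21)).astype(np.float32))
        assert probs.shape == (4, 2)
        assert np.all(np.isfinite(probs))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_input_too_small_rejected(self):
        s = build_structure(7, input_size=8)
        with pytest.raises(ValueError, match="too small"):
            build_network(s)


class TestBuildVgg16:
    def test_thirteen_conv_layers_freeze_through_block_3(self):
        s = build_vgg16(FineTuneConfig(head_classes=2, freeze_through_block=3),
                        input_size=64)
        net = build_network(s, seed=0)
        convs = [l for l in net.layers if isinstance(l, Conv2D)]
        assert len(convs) == 13
        frozen = [not l.trainable for l in convs]
        assert frozen == [True] * 7 + [False] * 6  # blocks 1-3 hold 2+2+3 convs

    def test_224_input_reaches_7x7_before_fc(self):
        s = build_vgg16(FineTuneConfig(), input_size=224)
        assert spatial_sizes(s)[-1] == 7

    def test_head_probabilities(self, rng):
        s = build_vgg16(FineTuneConfig(head_classes=2), input_channels=1, input_size=32)
        net = build_network(s, seed=1)
        probs = net.predict_proba(rng.normal(size=(2, 1, 32, 32)).astype(np.float32))
        assert probs.shape == (2, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_unreadable_pretrained_source_errors(self, tmp_path):
        missing = tmp_path / "nope.npz"
        ft = FineTuneConfig(pretrained_source=str(missing))
        s = build_vgg16(ft, input_channels=1, input_size=32)
        with pytest.raises(ValueError, match="could not be read"):
            build_network(s)

    def test_finetune_validation(self):
        with pytest.raises(ValueError):
            FineTuneConfig(head_classes=1)
        with pytest.raises(ValueError):
            FineTuneConfig(freeze_through_block=6)


def _patches(n, side=10, rgb=False, label="benign", seed=0):
    rng = np.random.default_rng(seed)
    shape = (side, side, 3) if rgb else (side, side)
    return [
        Patch(pixels=rng.integers(0, 256, size=shape, dtype=np.uint8).astype(np.uint8),
              label=label, source=("img", i))
        for i in range(n)
    ]


class TestAugment:
    def test_mode_none_is_identity(self):
        ps = _patches(5)
        assert augment(ps, AugmentConfig(mode="none")) == ps

    def test_rotation_only_counts(self):
        ps = _patches(10)
        out = augment(ps, AugmentConfig(mode="rotation_only"))
        assert len(out) == 40  # original + 3 rotations each

    def test_rot90_four_times_is_identity(self, rng):
        px = rng.integers(0, 256, size=(9, 9, 3), dtype=np.uint8)
        out = px
        for _ in range(4):
            out = rotate_patch(out, 90.0)
        assert np.array_equal(out, px)

    def test_translation_fills_by_edge_replication(self):
        px = np.arange(16, dtype=np.uint8).reshape(4, 4)
        out = translate_patch(px, 1, 0)
        assert np.array_equal(out[0], px[0])  # replicated edge row
        assert np.array_equal(out[1:], px[:3])

    def test_seeded_determinism(self):
        ps = _patches(4)
        cfg = AugmentConfig(mode="both", seed=5)
        a = augment(ps, cfg)
        b = augment(ps, cfg)
        assert len(a) == len(b)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))

    def test_labels_preserved(self, small_patch_dataset):
        out = augment(small_patch_dataset[:6], AugmentConfig(mode="both", seed=1))
        originals = {p.label for p in small_patch_dataset[:6]}
        assert {p.label for p in out} == originals

    def test_invalid_translation(self):
        with pytest.raises(ValueError):
            AugmentConfig(max_translation=0.6)


def _tiny_structure(side=10):
    return CNNStructure(
        structure_id="tiny", conv_kernel_sizes=(3,), feature_maps=(4,),
        pool_kernel_sizes=(2,), fc_outputs=(8, 2), input_size=side,
        input_channels=1,
    )


class TestTrain:
    def test_epochs_zero_leaves_init_untouched(self, small_patch_dataset):
        s = _tiny_structure(21)
        tc = TrainConfig(epochs=0, seed=3)
        res = train(small_patch_dataset, [], s, tc)
        assert res.loss_history == []
        fresh = build_network(s, seed=3)
        for a, b in zip(res.network.get_weights(), fresh.get_weights()):
            assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        ps = _patches(8, side=10)
        with pytest.raises(ValueError, match="both classes"):
            train(ps, [], _tiny_structure(), TrainConfig(epochs=1))

    def test_shape_mismatch_names_expected_size(self, small_patch_dataset):
        with pytest.raises(ValueError, match="input size 10"):
            train(small_patch_dataset, [], _tiny_structure(10), TrainConfig(epochs=1))

    def test_seeded_determinism(self, small_patch_dataset):
        s = _tiny_structure(21)
        tc = TrainConfig(epochs=2, seed=4, batch_size=8)
        a = train(small_patch_dataset, [], s, tc)
        b = train(small_patch_dataset, [], s, tc)
        assert a.loss_history == b.loss_history

    def test_zero_lr_keeps_weights(self, small_patch_dataset):
        s = _tiny_structure(21)
        tc = TrainConfig(epochs=2, initial_lr=0.0, seed=1)
        res = train(small_patch_dataset, [], s, tc)
        fresh = build_network(s, seed=1)
        for a, b in zip(res.network.get_weights(), fresh.get_weights()):
            assert np.array_equal(a, b)

    def test_loss_finite_every_epoch(self, small_patch_dataset):
        tc = TrainConfig(epochs=3, seed=0, batch_size=8)
        res = train(small_patch_dataset, small_patch_dataset[:6], _tiny_structure(21), tc)
        assert len(res.loss_history) == 3
        assert len(res.val_loss_history) == 3
        assert np.all(np.isfinite(res.loss_history))

    def test_separable_patches_reach_high_training_accuracy(self, small_patch_dataset):
        edm = pipeline.transform_patches(small_patch_dataset, "F")
        s = build_structure(1, input_size=21, input_channels=1)
        tc = TrainConfig(epochs=20, optimizer="adam", initial_lr=1e-3, seed=0)
        res = train(edm, [], s, tc)
        probs = predict(res, edm)
        pred = probs[:, 1] >= 0.5
        truth = np.array([p.label == "BPH" for p in edm])
        assert (pred == truth).mean() >= 0.95


@pytest.fixture(scope="module")
def trained(small_patch_dataset):
    edm = pipeline.transform_patches(small_patch_dataset, "F")
    s = build_structure(1, input_size=21, input_channels=1)
    tc = TrainConfig(epochs=5, optimizer="adam", initial_lr=1e-3, seed=0)
    return edm, train(edm, [], s, tc)


class TestPredict:

    def test_rows_sum_to_one(self, trained):
        edm, res = trained
        probs = predict(res, edm)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_duplicated_patch_identical_rows(self, trained):
        edm, res = trained
        probs = predict(res, [edm[0], edm[0]])
        assert np.array_equal(probs[0], probs[1])

    def test_save_load_roundtrip(self, trained, tmp_path):
        edm, res = trained
        save_result(res, tmp_path / "model")
        loaded = load_result(tmp_path / "model")
        assert np.allclose(predict(loaded, edm[:8]), predict(res, edm[:8]), atol=1e-7)

    def test_batch_permutation_equivariance(self, trained, rng):
        edm, res = trained
        perm = rng.permutation(len(edm))
        probs = predict(res, edm)
        probs_perm = predict(res, [edm[i] for i in perm])
        assert np.allclose(probs[perm], probs_perm, atol=1e-7)


class TestGradientCheck:
    def test_two_layer_structure_matches_numerics(self, rng):
        s = CNNStructure(
            structure_id="check", conv_kernel_sizes=(3, 3), feature_maps=(3, 3),
            pool_kernel_sizes=(2,), fc_outputs=(6, 2), input_size=8,
            input_channels=1,
        )
        net = build_network(s, seed=0, dtype=np.float64)
        x = rng.normal(size=(3, 1, 8, 8))
        y = np.array([0, 1, 1])
        assert numerical_gradient_check(net, x, y) < 1e-4


@pytest.fixture(scope="module")
def setup(small_patch_dataset):
    edm = pipeline.transform_patches(small_patch_dataset, "F")
    s = build_structure(1, input_size=21, input_channels=1)
    tc = TrainConfig(epochs=4, optimizer="adam", initial_lr=1e-3, seed=0)
    res = train(edm[:20], [], s, tc)
    candidates = [p for p in edm[20:] if p.label == "benign"]
    return edm[:20], res, candidates


class TestBootstrapHardNegatives:

    def test_unattainable_threshold_is_noop(self, setup):
        train_set, res, candidates = setup
        out, _, counts = bootstrap_hard_negatives(
            res, train_set, [], candidates, threshold=1.01, rounds=2
        )
        assert out == list(train_set)
        assert counts == [0]

    def test_zero_rounds_is_identity(self, setup):
        train_set, res, candidates = setup
        out, final, counts = bootstrap_hard_negatives(
            res, train_set, [], candidates, threshold=0.5, rounds=0
        )
        assert out == list(train_set)
        assert final is res
        assert counts == []

    def test_non_benign_candidates_rejected(self, setup, small_patch_dataset):
        train_set, res, _ = setup
        bph = [p for p in small_patch_dataset if p.label == "BPH"][:2]
        with pytest.raises(ValueError, match="benign"):
            bootstrap_hard_negatives(res, train_set, [], bph, rounds=1)

    def test_hard_negative_count_drops_after_retraining(self, setup):
        train_set, res, candidates = setup
        before = (predict(res, candidates)[:, 1] >= 0.3).sum()
        _, final, _ = bootstrap_hard_negatives(
            res, train_set, [], candidates, threshold=0.3, rounds=1
        )
        after = (predict(final, candidates)[:, 1] >= 0.3).sum()
        assert after <= before


class TestTablePresets:
    def test_all_seven_presets_instantiate(self):
        for sid in TABLE_PRESETS:
            s = build_structure(sid, input_size=64, input_channels=1)
            assert len(s.conv_kernel_sizes) == len(s.feature_maps)
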