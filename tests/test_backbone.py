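import numpy as np
import pytest

import octsaliency as oc
from octsaliency.backbone import (
    BackboneSpec,
    BlockAddress,
    CaptureSpec,
    build_model,
    forward_with_capture,
    load_checkpoint,
    save_checkpoint,
)
from octsaliency.training import (
    AdamW,
    ReduceLROnPlateau,
    TrainConfig,
    focal_ls_loss,
    train,
)
from .oracles import focal_ls_loop


class TestModelContract:
    def test_forward_yields_six_logits(self, tiny_model, synth_input):
        logits = tiny_model.predict_logits(synth_input[None])
        assert logits.shape == (1, 6)
        assert np.all(np.isfinite(logits))

    def test_same_seed_identical_parameters(self):
        a = build_model(BackboneSpec(), seed=5)
        b = build_model(BackboneSpec(), seed=5)
        for k in a.params:
            assert np.array_equal(a.params[k].data, b.params[k].data)

    def test_incompatible_window_rejected(self):
        with pytest.raises(ValueError):
            BackboneSpec(window_size=3)

    def test_block_addressing_global_flattening(self):
        spec = BackboneSpec()
        addr = BlockAddress.from_global(spec, 3)
        assert (addr.stage_index, addr.block_index_in_stage) == (1, 1)
        with pytest.raises(ValueError):
            BlockAddress.from_global(spec, 4)

    def test_checkpoint_roundtrip(self, tiny_model, synth_input, tmp_path):
        save_checkpoint(tiny_model, tmp_path / "m.npz")
        again = load_checkpoint(tmp_path / "m.npz")
        assert np.allclose(again.predict_logits(synth_input[None]),
                           tiny_model.predict_logits(synth_input[None]))


class TestCapture:
    def test_capture_is_non_invasive(self, tiny_model, synth_input):
        plain = tiny_model.predict_logits(synth_input[None])[0]
        spec = CaptureSpec(attention_at=(0, 1, 2, 3), norm_tokens_at=(0, 1, 2, 3),
                           final_norm=True, target_activation=True)
        bundle = forward_with_capture(tiny_model, synth_input, spec)
        assert np.allclose(bundle.logits, plain, atol=1e-6)

    def test_attention_rows_sum_to_one(self, tiny_model, synth_input):
        spec = CaptureSpec(attention_at=(0, 1, 2, 3))
        bundle = forward_with_capture(tiny_model, synth_input, spec)
        for g, cap in bundle.attention.items():
            assert np.allclose(cap.probs.sum(axis=-1), 1.0, atol=1e-5)
            assert cap.grad.shape == cap.probs.shape
            assert cap.shift_size == (0 if g % 2 == 0 else 2)

    def test_predicted_target_is_argmax(self, tiny_model, synth_input):
        bundle = forward_with_capture(tiny_model, synth_input,
                                      CaptureSpec(final_norm=True))
        assert bundle.target_class == int(np.argmax(bundle.logits))

    def test_norm2_preferred_over_norm1(self, tiny_model, synth_input):
        spec = CaptureSpec(norm_tokens_at=(0, 3))
        bundle = forward_with_capture(tiny_model, synth_input, spec)
        assert all(cap.source == "norm2" for cap in bundle.tokens.values())
        assert bundle.tokens[0].grid == (8, 8)
        assert bundle.tokens[3].grid == (4, 4)

    def test_invalid_address_rejected(self, tiny_model, synth_input):
        with pytest.raises(ValueError, match="capture point"):
            forward_with_capture(tiny_model, synth_input,
                                 CaptureSpec(attention_at=(7,)))

    def test_gradients_match_finite_differences(self, tiny_model, synth_input):
        spec = CaptureSpec(attention_at=(1,), final_norm=True, want_gradients=True)
        bundle = forward_with_capture(tiny_model, synth_input, spec)
        tgt = bundle.target_class
        rng = np.random.default_rng(0)
        checks = []
        fn = bundle.final_norm
        H, W = fn.grid
        C = fn.tokens.shape[1]
        for key, shape, grad in [
            (("final_norm", None), (1, H, W, C), fn.grad.reshape(1, H, W, C)),
            (("attn", 1), bundle.attention[1].probs.shape, bundle.attention[1].grad),
        ]:
            for _ in range(5):
                idx = tuple(rng.integers(0, s) for s in shape)
                eps = 1e-5
                d = np.zeros(shape); d[idx] = eps
                up = tiny_model.forward(synth_input[None], perturb={key: d})[0].data[0, tgt]
                d[idx] = -eps
                dn = tiny_model.forward(synth_input[None], perturb={key: d})[0].data[0, tgt]
                num = (up - dn) / (2 * eps)
                checks.append(abs(num - grad[idx]) <= 1e-3 * max(abs(num), 1e-6))
        assert all(checks)


class TestFocalLsLoss:
    def test_reduces_to_cross_entropy(self):
        assert focal_ls_loss(np.zeros(2), 0, gamma=0, label_smoothing=0) == pytest.approx(
            np.log(2), abs=1e-12
        )
        rng = np.random.default_rng(1)
        z = rng.standard_normal((8, 6))
        y = rng.integers(0, 6, 8)
        logp = z - np.log(np.exp(z - z.max(1, keepdims=True)).sum(1, keepdims=True)) - z.max(1, keepdims=True)
        ce = -logp[np.arange(8), y].mean()
        assert focal_ls_loss(z, y, gamma=0, label_smoothing=0) == pytest.approx(ce, abs=1e-7)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            z = rng.standard_normal(6) * 3
            y = int(rng.integers(0, 6))
            expect = focal_ls_loop(z, y, 2.0, 0.05)
            assert focal_ls_loss(z, y) == pytest.approx(expect, rel=1e-9)

    def test_two_class_hand_value(self):
        # logits (1,0), label 0, gamma 2, eps 0.05
        got = focal_ls_loss(np.array([1.0, 0.0]), 0, gamma=2, label_smoothing=0.05)
        assert got == pytest.approx(focal_ls_loop([1.0, 0.0], 0, 2.0, 0.05), rel=1e-12)
        assert got == pytest.approx(0.0244, abs=2e-4)

    def test_confident_correct_prediction_drives_loss_to_zero(self):
        losses = [focal_ls_loss(np.array([m, 0.0]), 0, gamma=2, label_smoothing=0)
                  for m in (1, 3, 6, 10)]
        assert all(a > b for a, b in zip(losses, losses[1:]))
        assert losses[-1] < 1e-3

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal((4, 6))
        y = np.array([0, 2, 4, 5])
        perm = rng.permutation(6)
        inv = np.argsort(perm)
        assert focal_ls_loss(z, y) == pytest.approx(
            focal_ls_loss(z[:, inv], perm[y]), rel=1e-12
        )

    def test_nonfinite_logits_rejected(self):
        with pytest.raises(ValueError):
            focal_ls_loss(np.array([np.inf, 0.0]), 0)


class TestSchedulerAndTraining:
    def test_plateau_trace_on_flat_metric(self):
        params = {"p": oc.build_model(BackboneSpec(), seed=0).params["head.fc2.bias"]}
        opt = AdamW([{"params": params, "lr": 1.0}])
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=3)
        lrs = []
        for _ in range(6):
            sched.step(0.5)  # flat validation accuracy
            lrs.append(opt.groups[0]["lr"])
        # best at epoch 1; reduction lands at epoch 5 (after 3 bad epochs + 1)
        assert lrs == [1.0, 1.0, 1.0, 1.0, 0.5, 0.5]

    def test_plateau_resets_on_improvement(self):
        params = {"p": oc.build_model(BackboneSpec(), seed=0).params["head.fc2.bias"]}
        opt = AdamW([{"params": params, "lr": 1.0}])
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=2)
        for acc in [0.5, 0.4, 0.6, 0.55, 0.5]:
            sched.step(acc)
        assert opt.groups[0]["lr"] == 1.0  # never more than patience bad epochs

    def test_freeze_policy_updates_only_head_and_final_norm(self):
        model = oc.tiny_backbone(seed=1)
        x, y = oc.make_dataset(4, side=32, seed=2)
        before = model.state_dict()
        cfg = TrainConfig(max_epochs=2, min_epochs=1, early_stop_patience=5,
                          freeze_backbone=True, unfreeze_last_n_blocks=0,
                          lr_backbone=1e-3, lr_head=1e-3, batch_size=8, seed=0)
        train(model, x, y, cfg)
        allowed = model.trainable_names(True, 0)
        for name, arr in model.state_dict().items():
            changed = not np.array_equal(arr, before[name])
            if name in allowed:
                continue  # may or may not move
            assert not changed, f"frozen parameter {name} changed"
        assert any(not np.array_equal(model.state_dict()[n], before[n])
                   for n in model.head_param_names())

    def test_unfreeze_capped_at_total_blocks(self, tiny_model):
        names_all = tiny_model.trainable_names(True, 20)  # caps at 4 blocks
        assert any(n.startswith("stage0.block0.") for n in names_all)

    def test_short_training_reduces_loss(self):
        model = oc.tiny_backbone(seed=3)
        x, y = oc.make_dataset(20, side=32, seed=4)  # 120 images
        cfg = oc.fixture_train_config(max_epochs=15, min_epochs=15,
                                      early_stop_patience=99, seed=0)
        hist = train(model, x, y, cfg)
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert len(hist.val_acc) == 15

    def test_empty_or_single_class_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            train(tiny_model, np.empty((0, 3, 32, 32)), np.empty(0, int), TrainConfig())
        x, _ = oc.make_dataset(2, side=32, seed=5)
        with pytest.raises(ValueError):
            train(tiny_model, x, np.zeros(len(x), int), TrainConfig())

    def test_class_balanced_sampler_oversamples_minority(self):
        from octsaliency.training import _class_balanced_indices

        labels = np.array([0] * 90 + [1] * 10)
        idx = _class_balanced_indices(labels, 20000, np.random.default_rng(0))
        frac1 = (labels[idx] == 1).mean()
        assert 0.45 < frac1 < 0.55
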