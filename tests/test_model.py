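"""Decoder architecture, training loop, determinism and checkpointing."""

import numpy as np
import pytest

from spike2image.autodiff import Tensor
from spike2image.model import (
    DecoderConfig,
    build_model,
    compare_methods,
    evaluate_on_pairs,
    learning_rate,
    load_checkpoint,
    reconstruct,
    save_checkpoint,
    train,
)
from spike2image.synthdata import SimConfig, make_benchmark

TINY = dict(
    n_neurons=10,
    n_time_bins=5,
    image_shape=(16, 16),
    fc_hidden=16,
    encoder_channels=(4, 4, 4, 4),
    decoder_channels=(4, 4, 4, 1),
    epochs=3,
    batch_size=8,
    lr0=2e-3,
    gabor_orientation_step_deg=90.0,
    gabor_ksizes=(7,),
)

TINY_SIM = SimConfig(
    n_neurons=10, image_shape=(16, 16), window_ms=50.0, bin_width_ms=10.0, seed=5
)


@pytest.fixture(scope="module")
def tiny_pairs():
    ds = make_benchmark(TINY_SIM, n_stimuli=40)
    pairs = ds.pairs()
    return pairs[:32], pairs[32:]


def tiny_cfg(**overrides):
    kw = dict(TINY)
    kw.update(overrides)
    return DecoderConfig(**kw)


class TestArchitecture:
    def test_forward_shape_contract(self):
        model = build_model(tiny_cfg(seed=0))
        x = Tensor(np.random.default_rng(0).standard_normal((3, 50)).astype(np.float32))
        out = model(x)
        assert out.data.shape == (3, 1, 16, 16)
        assert (out.data >= 0).all() and (out.data <= 1).all()

    def test_stride_arithmetic_on_80px_images(self):
        cfg = tiny_cfg(image_shape=(80, 80), seed=0)
        model = build_model(cfg)
        model.train_mode(False)
        x = Tensor(np.zeros((1, 50), dtype=np.float32))
        # walk the encoder and track spatial sizes: 80 -> 40 -> 20 -> 10 -> 5
        h = model.act(model.fc1(x))
        h = model.act(model.fc2(h))
        h = h.reshape(1, 1, 80, 80)
        h = model.act(model.first_conv(h))
        sizes = []
        for conv in model.encoder:
            h = model.act(conv(h))
            sizes.append(h.data.shape[-1])
        assert sizes == [40, 20, 10, 5]
        out = model(Tensor(np.zeros((1, 50), dtype=np.float32)))
        assert out.data.shape == (1, 1, 80, 80)

    def test_indivisible_image_shape_rejected(self):
        with pytest.raises(ValueError, match="conv_stride"):
            tiny_cfg(image_shape=(30, 30))

    def test_same_seed_builds_identical_models(self):
        a = build_model(tiny_cfg(seed=7))
        b = build_model(tiny_cfg(seed=7))
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)
        c = build_model(tiny_cfg(seed=8))
        assert any(
            not np.array_equal(pa.data, pc.data)
            for pa, pc in zip(a.parameters(), c.parameters())
        )

    def test_parameter_count_matches_closed_form(self):
        cfg = tiny_cfg(seed=0)
        model = build_model(cfg)
        k, s = cfg.conv_ksize, 16 * 16
        n_in = cfg.n_neurons * cfg.n_time_bins
        bank = cfg.bank()
        expected = (
            (n_in * 16 + 16)                  # fc1
            + (16 * s + s)                    # fc2
            + sum(                             # 4 encoder convs
                o * i * k * k + o
                for i, o in zip((len(bank), 4, 4, 4), (4, 4, 4, 4))
            )
            + sum(                             # 4 decoder deconvs
                i * o * k * k + o
                for i, o in zip((4, 4, 4, 4), (4, 4, 4, 1))
            )
        )
        # fixed Gabor kernels are not trainable parameters
        assert model.n_parameters() == expected


class TestSchedule:
    def test_published_decay_anchors(self):
        cfg = DecoderConfig(seed=0)
        assert learning_rate(cfg, 0) == pytest.approx(0.02)
        assert learning_rate(cfg, 99) == pytest.approx(0.02)
        assert learning_rate(cfg, 100) == pytest.approx(0.018)
        assert learning_rate(cfg, 200) == pytest.approx(0.0162)

    def test_history_lr_column_follows_schedule(self, tiny_pairs):
        tr, te = tiny_pairs
        cfg = tiny_cfg(seed=1, epochs=4, lr_decay_every=2, lr_decay=0.5, lr0=1e-3)
        _, hist = train(build_model(cfg), tr, te, cfg, metrics_every=0)
        assert hist.lr == [1e-3, 1e-3, 5e-4, 5e-4]


class TestTraining:
    def test_loss_decreases_on_small_set(self, tiny_pairs):
        tr, te = tiny_pairs
        cfg = tiny_cfg(seed=2, epochs=8)
        _, hist = train(build_model(cfg), tr, te, cfg, metrics_every=0)
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert len(hist.train_loss) == 8

    def test_overfits_single_repeated_sample(self, tiny_pairs):
        tr, _ = tiny_pairs
        one = [tr[0]] * 8
        cfg = tiny_cfg(
            seed=3, epochs=20, mu_mix=0.0, dropout_p=0.0, lr0=2e-2,
            fc_hidden=32, encoder_channels=(8, 8, 8, 8), decoder_channels=(8, 8, 8, 1),
        )
        _, hist = train(build_model(cfg), one, one, cfg, metrics_every=0)
        assert hist.train_loss[-1] < 0.1 * hist.train_loss[0]

    def test_training_is_seed_reproducible(self, tiny_pairs):
        tr, te = tiny_pairs
        cfg = tiny_cfg(seed=4, epochs=3)
        _, h1 = train(build_model(cfg), tr, te, cfg, metrics_every=0)
        _, h2 = train(build_model(cfg), tr, te, cfg, metrics_every=0)
        assert h1.train_loss == h2.train_loss
        assert h1.test_loss == h2.test_loss

    def test_empty_split_rejected(self, tiny_pairs):
        tr, te = tiny_pairs
        cfg = tiny_cfg(seed=0)
        with pytest.raises(ValueError, match="nonempty"):
            train(build_model(cfg), [], te, cfg)


class TestReconstruct:
    def test_inference_is_deterministic_and_in_range(self, tiny_pairs):
        tr, te = tiny_pairs
        cfg = tiny_cfg(seed=5, epochs=2)
        model, _ = train(build_model(cfg), tr, te, cfg, metrics_every=0)
        counts = np.stack([p[0].counts for p in te])
        a = reconstruct(model, counts)
        b = reconstruct(model, counts)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (len(te), 16, 16)
        assert (a >= 0).all() and (a <= 1).all()

    def test_all_zero_spikes_give_valid_image(self, tiny_pairs):
        tr, te = tiny_pairs
        cfg = tiny_cfg(seed=5, epochs=1)
        model, _ = train(build_model(cfg), tr, te, cfg, metrics_every=0)
        out = reconstruct(model, np.zeros((1, 10, 5), dtype=int))
        assert np.isfinite(out).all()
        assert (out >= 0).all() and (out <= 1).all()

    def test_training_improves_heldout_ssim(self, tiny_pairs):
        tr, te = tiny_pairs
        cfg = tiny_cfg(seed=6, epochs=15)
        untrained = build_model(cfg)
        untrained.fit_normalizer(np.stack([p[0].counts for p in tr]))
        before = evaluate_on_pairs(untrained, te)["ssim"]
        model, _ = train(build_model(cfg), tr, te, cfg, metrics_every=0)
        after = evaluate_on_pairs(model, te)["ssim"]
        assert after > before


class TestCheckpoint:
    def test_round_trip_preserves_metrics(self, tiny_pairs, tmp_path):
        tr, te = tiny_pairs
        cfg = tiny_cfg(seed=7, epochs=2)
        model, _ = train(build_model(cfg), tr, te, cfg, metrics_every=0)
        before = evaluate_on_pairs(model, te)
        save_checkpoint(model, tmp_path / "ck.npz")
        loaded, wm = load_checkpoint(tmp_path / "ck.npz")
        assert wm is None
        after = evaluate_on_pairs(loaded, te)
        assert after == before


class TestCompare:
    def test_report_schema_and_ablation_equivalence(self, tiny_pairs):
        tr, te = tiny_pairs
        cfg = tiny_cfg(seed=8, epochs=2)
        report = compare_methods(tr, te, cfg)
        assert set(report["methods"]) == {"method1", "method2", "proposed"}
        for row in report["methods"].values():
            assert {"mse", "psnr", "ssim", "vifp"} <= set(row)

    def test_proposed_with_ablations_off_equals_method1(self, tiny_pairs):
        tr, te = tiny_pairs
        base = tiny_cfg(seed=9, epochs=4)
        m1_cfg = tiny_cfg(seed=9, epochs=4, mu_mix=0.0, gabor_enabled=False)
        ablated = tiny_cfg(seed=9, epochs=4, mu_mix=0.0, gabor_enabled=False)
        _, h1 = train(build_model(m1_cfg), tr, te, m1_cfg, metrics_every=0)
        _, h2 = train(
            build_model(ablated), tr, te, ablated, weight_matrix=None, metrics_every=0
        )
        assert h1.train_loss == h2.train_loss
        assert h1.test_loss == h2.test_loss
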