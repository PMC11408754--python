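"""Architecture accounting, autodiff correctness, and training behavior."""

import warnings

import numpy as np
import pytest

from fluordepth import network
from fluordepth.datasets import generate_training_set
from fluordepth.network import (
    ModelConfig,
    TrainConfig,
    _composite_loss,
    build_model,
    predict,
    train,
)

TINY = ModelConfig(
    prop_channels=(3, 4), fluor_entry=3, fluor_channels=(4, 4),
    trunk_channels=4, head_channels=(3, 2),
)


def tiny_model(seed=1):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_model(TINY, seed=seed)


class TestArchitecture:
    def test_committed_schedule_parameter_count(self):
        assert ModelConfig().parameter_count() == 920_514

    def test_built_model_matches_analytic_count(self):
        for cfg in (TINY, ModelConfig.scaled(0.1)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = build_model(cfg)
            assert m.parameter_count() == cfg.parameter_count()

    def test_off_schedule_config_warns_not_fails(self):
        with pytest.warns(UserWarning, match="920,514"):
            build_model(ModelConfig.scaled(0.5))
        with pytest.raises(ValueError):
            build_model(ModelConfig.scaled(0.5), strict=True)

    def test_doubling_a_layer_changes_count_by_analytic_delta(self):
        base = ModelConfig()
        import dataclasses

        wider = dataclasses.replace(base, fluor_entry=64)
        # entry: 54f + f; next conv: 9*f*96 + 96 -> delta = 55*32 + 9*32*96
        delta = 55 * 32 + 9 * 32 * 96
        assert wider.parameter_count() - base.parameter_count() == delta

    def test_forward_preserves_lateral_dims_and_finiteness(self):
        m = tiny_model()
        out = m.forward(np.zeros((2, 2, 33, 41), np.float32), np.zeros((2, 6, 33, 41), np.float32))
        assert out.shape == (2, 2, 33, 41)
        assert np.all(np.isfinite(out))

    def test_layerwise_dims_probe(self):
        m = tiny_model()
        x = np.random.default_rng(0).normal(size=(1, 9, 9, 2)).astype(np.float32)
        for layer in m.prop_arm.layers:
            x = layer.forward(x)
            assert x.shape[1:3] == (9, 9)


class TestAutodiff:
    def test_gradients_match_finite_differences(self):
        """Central finite differences on a tiny net (float32; ReLU kinks can
        trip individual probes, so assert on the overwhelming majority)."""
        m = tiny_model()
        rng = np.random.default_rng(0)
        xp = rng.normal(size=(2, 2, 9, 9)).astype(np.float32)
        xf = rng.normal(size=(2, 6, 9, 9)).astype(np.float32)
        y = rng.uniform(0, 1, size=(2, 2, 9, 9)).astype(np.float32)
        pred = m.forward(xp, xf)
        _, g = _composite_loss(pred, y, (1.0, 1.0))
        m.zero_grad()
        m.backward(g)
        bad = total = 0
        crng = np.random.default_rng(7)
        for p in m.params:
            if p.value.size < 4:
                continue
            for _ in range(3):
                idx = tuple(crng.integers(0, s) for s in p.value.shape)
                eps, orig = 2e-3, float(p.value[idx])
                p.value[idx] = orig + eps
                lp = _composite_loss(m.forward(xp, xf), y, (1.0, 1.0))[0]
                p.value[idx] = orig - eps
                lm = _composite_loss(m.forward(xp, xf), y, (1.0, 1.0))[0]
                p.value[idx] = orig
                num, ana = (lp - lm) / (2 * eps), float(p.grad[idx])
                total += 1
                if abs(num - ana) / (abs(num) + abs(ana) + 1e-6) > 0.05:
                    bad += 1
        assert bad <= 0.1 * total

    def test_forward_is_pure(self):
        m = tiny_model()
        rng = np.random.default_rng(0)
        xp = rng.normal(size=(1, 2, 11, 11)).astype(np.float32)
        xf = rng.normal(size=(1, 6, 11, 11)).astype(np.float32)
        a = m.forward(xp, xf)
        b = m.forward(xp, xf)
        np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def overfit_manifest(lut):
    return generate_training_set("cylinder", 10, seed=3, lut=lut, val_fraction=0.2)


class TestTraining:
    def test_overfit_ten_samples_drives_loss_down(self, overfit_manifest):
        """Capacity sanity: the architecture can overfit a tiny set."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = build_model(ModelConfig.scaled(0.08), seed=0)
        cfg = TrainConfig(learning_rate=1e-3, lr_decay=1.0, max_epochs=50,
                          patience=50, batch_size=2, seed=0)
        history = train(m, overfit_manifest, cfg)
        assert min(history["train_loss"]) < history["train_loss"][0] / 10.0

    def test_seeded_training_reproducible(self, overfit_manifest):
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=2, patience=5, batch_size=4, seed=1)
        h1 = train(tiny_model(seed=2), overfit_manifest, cfg)
        h2 = train(tiny_model(seed=2), overfit_manifest, cfg)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_learning_rate_decays(self, overfit_manifest):
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=3, patience=5, batch_size=4, seed=1)
        h = train(tiny_model(seed=2), overfit_manifest, cfg)
        assert np.all(np.diff(h["lr"]) < 0)


class TestPredict:
    def test_predict_units_and_clamping(self, overfit_manifest):
        from fluordepth.datasets import load_sample

        m = tiny_model(seed=0)
        m.normalizer = overfit_manifest.normalizer
        rec = overfit_manifest.records[0]
        (props, fluor), _ = load_sample(rec, m.normalizer)
        pred = predict(m, props, fluor)
        assert pred.depth_mm.shape == (101, 101)
        assert np.all(pred.depth_mm >= 0) and np.all(pred.concentration >= 0)
        again = predict(m, props, fluor)
        np.testing.assert_array_equal(pred.depth_mm, again.depth_mm)

    def test_shape_mismatch_rejected(self):
        m = tiny_model()
        m.normalizer = __import__("fluordepth.datasets", fromlist=["Normalizer"]).Normalizer(1.0)
        with pytest.raises(ValueError):
            predict(m, np.zeros((3, 101, 101), np.float32), np.zeros((6, 101, 101), np.float32))


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path, overfit_manifest):
        m = tiny_model(seed=4)
        m.normalizer = overfit_manifest.normalizer
        m.save(tmp_path / "ckpt.npz")
        back = network.SiameseCNN.load(tmp_path / "ckpt.npz")
        rng = np.random.default_rng(0)
        xp = rng.normal(size=(1, 2, 21, 21)).astype(np.float32)
        xf = rng.normal(size=(1, 6, 21, 21)).astype(np.float32)
        np.testing.assert_array_equal(m.forward(xp, xf), back.forward(xp, xf))
        assert back.normalizer.fluor_p99 == m.normalizer.fluor_p99
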