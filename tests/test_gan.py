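import numpy as np
import pytest

from mebci.gan import (
    DiscriminatorSpec,
    GeneratorSpec,
    MinMaxNorm,
    TrainConfig,
    TrainedConverter,
    build_discriminator,
    build_generator,
    convert,
    slice_trialset,
    train_gan,
)
from mebci.nn import RMSprop, bce_grad, binary_cross_entropy
from mebci.pipeline import TrialSet

CLASSES = ("mRB", "mFB", "mLS", "mRS")


def one_hot(idx, n=4):
    out = np.zeros((len(idx), n))
    out[np.arange(len(idx)), idx] = 1.0
    return out


def make_trials(rng, n=8, length=400, channels=4, value=None):
    if value is None:
        data = rng.standard_normal((n, length, channels))
    else:
        data = np.full((n, length, channels), value) + 0.01 * rng.standard_normal(
            (n, length, channels)
        )
    labels = tuple(CLASSES[i % 4] for i in range(n))
    return TrialSet(data, labels, 1000.0, tuple(1 for _ in range(n)))


class TestSpecs:
    def test_generator_invariants(self):
        spec = GeneratorSpec(timestamps=4000, channels=30)
        assert spec.resolved_filters() == (64, 52, 42, 36, 30)
        spec.validate()

    def test_generator_bad_layer_count(self):
        with pytest.raises(ValueError):
            GeneratorSpec(400, 4, filters=(64, 52), kernels=(64, 32)).validate()

    def test_discriminator_window_too_short(self):
        with pytest.raises(ValueError):
            DiscriminatorSpec(window=40, channels=4).validate()

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(iterations=0)
        with pytest.raises(ValueError):
            TrainConfig(d_learning_rate=0.0)


class TestLabelEmbedding:
    def test_generator_path_shape(self):
        g = build_generator(GeneratorSpec(400, 4), seed=0)
        emb = g.embed_label(one_hot([0, 2]))
        assert emb.shape == (2, 400, 1)

    def test_discriminator_path_shape(self):
        d = build_discriminator(DiscriminatorSpec(100, 4), seed=0)
        emb = d.embed_label(one_hot([1]))
        assert emb.shape == (1, 100, 1)

    def test_non_one_hot_rejected(self):
        g = build_generator(GeneratorSpec(400, 4), seed=0)
        with pytest.raises(ValueError):
            g.embed_label(np.array([[0.5, 0.5, 0.0, 0.0]]))
        with pytest.raises(ValueError):
            g.embed_label(np.array([[1.0, 1.0, 0.0, 0.0]]))

    def test_zero_weights_zero_embedding(self):
        g = build_generator(GeneratorSpec(400, 4), seed=0)
        g.label_dense.params["W"][...] = 0.0
        g.label_dense.params["b"][...] = 0.0
        emb = g.embed_label(one_hot([3]))
        assert np.all(emb == 0)


class TestGenerator:
    def test_shape_conservation(self, rng):
        g = build_generator(GeneratorSpec(400, 4), seed=0)
        x = rng.standard_normal((3, 400, 4))
        y = g.forward(x, one_hot([0, 1, 2]))
        assert y.shape == (3, 400, 4)

    def test_output_bounded_by_tanh(self, rng):
        g = build_generator(GeneratorSpec(256, 6), seed=1)
        y = g.forward(10 * rng.standard_normal((2, 256, 6)), one_hot([0, 1]))
        assert np.all(np.abs(y) <= 1.0)  # float32 tanh saturates to exactly 1
        y_small = g.forward(0.1 * rng.standard_normal((2, 256, 6)),
                            one_hot([0, 1]))
        assert np.all(np.abs(y_small) < 1.0)

    def test_inference_deterministic(self, rng):
        g = build_generator(GeneratorSpec(256, 3), seed=2)
        x = rng.standard_normal((1, 256, 3))
        y1 = g.forward(x, one_hot([0]))
        y2 = g.forward(x, one_hot([0]))
        assert np.array_equal(y1, y2)


class TestDiscriminator:
    def test_score_in_unit_interval(self, rng):
        d = build_discriminator(DiscriminatorSpec(100, 4), seed=0)
        s = d.forward(rng.standard_normal((5, 100, 4)), one_hot([0, 1, 2, 3, 0]))
        assert s.shape == (5, 1)
        assert np.all((s > 0) & (s < 1))

    def test_untrained_calibration_near_half(self, rng):
        x = np.concatenate([np.full((8, 100, 4), 0.5), np.full((8, 100, 4), -0.5)])
        oh = one_hot(np.arange(16) % 4)
        means = []
        for seed in range(10):
            d = build_discriminator(DiscriminatorSpec(100, 4), seed=seed)
            means.append(float(d.forward(x, oh).mean()))
        assert abs(np.mean(means) - 0.5) < 0.2

    def test_dropout_active_in_training_mode(self, rng):
        d = build_discriminator(DiscriminatorSpec(100, 4), seed=0)
        x = rng.standard_normal((4, 100, 4))
        oh = one_hot([0, 1, 2, 3])
        eval1 = d.forward(x, oh, training=False)
        eval2 = d.forward(x, oh, training=False)
        assert np.array_equal(eval1, eval2)
        train1 = d.forward(x, oh, training=True)
        train2 = d.forward(x, oh, training=True)
        assert not np.array_equal(train1, train2)

    def test_separable_oracle_loss_drops(self):
        d = build_discriminator(DiscriminatorSpec(100, 4), seed=0)
        opt = RMSprop(0.0008)
        oh = one_hot(np.arange(16) % 4)
        x = np.concatenate([np.full((8, 100, 4), 0.5), np.full((8, 100, 4), -0.5)])
        t = np.concatenate([np.ones((8, 1)), np.zeros((8, 1))])
        loss = None
        for _ in range(50):
            d.zero_grad()
            pred = d.forward(x, oh, training=True)
            loss = binary_cross_entropy(pred, t)
            d.backward(bce_grad(pred, t))
            opt.step(d.parameters())
        assert loss < 0.1


class TestSlicing:
    def test_window_count_arithmetic(self, rng):
        ts = make_trials(rng, n=2, length=4000, channels=3)
        wb = slice_trialset(ts, 100)
        assert wb.windows.shape == (80, 100, 3)  # 40 windows per trial

    def test_labels_preserved(self, rng):
        ts = make_trials(rng, n=4, length=300, channels=2)
        wb = slice_trialset(ts, 100)
        assert wb.labels[:3] == ("mRB",) * 3
        assert wb.labels[3:6] == ("mFB",) * 3

    def test_partition_exact(self, rng):
        ts = make_trials(rng, n=1, length=400, channels=2)
        wb = slice_trialset(ts, 100)
        rebuilt = wb.windows.reshape(400, 2)
        assert np.array_equal(rebuilt, ts.data[0])

    def test_window_too_long(self, rng):
        ts = make_trials(rng, n=1, length=50, channels=2)
        with pytest.raises(ValueError):
            slice_trialset(ts, 100)


class TestTraining:
    @pytest.fixture(scope="class")
    def trained(self):
        rng = np.random.default_rng(0)
        real = make_trials(rng, n=8, length=400, channels=4, value=0.5)
        sim = make_trials(rng, n=8, length=400, channels=4, value=-0.5)
        cfg = TrainConfig(iterations=30, batch_size=16, gen_batch=4, seed=3)
        return train_gan(sim, real, cfg), sim

    def test_losses_finite_and_recorded(self, trained):
        tr, _ = trained
        assert len(tr.loss_history["d_loss"]) == 30
        assert len(tr.loss_history["g_loss"]) == 30
        assert np.isfinite(tr.loss_history["d_loss"]).all()
        assert np.isfinite(tr.loss_history["g_loss"]).all()

    def test_training_reproducible(self):
        rng1 = np.random.default_rng(5)
        real = make_trials(rng1, n=4, length=300, channels=3, value=0.4)
        sim = make_trials(rng1, n=4, length=300, channels=3, value=-0.4)
        cfg = TrainConfig(iterations=5, batch_size=8, gen_batch=2, seed=9)
        a = train_gan(sim, real, cfg)
        b = train_gan(sim, real, cfg)
        assert a.loss_history == b.loss_history

    def test_channel_mismatch_rejected(self, rng):
        real = make_trials(rng, n=4, channels=4)
        sim = make_trials(rng, n=4, channels=3)
        with pytest.raises(ValueError):
            train_gan(sim, real, TrainConfig(iterations=1))

    def test_convert_roundtrip_shapes(self, trained):
        tr, sim = trained
        out = convert(tr, sim)
        assert out.data.shape == sim.data.shape
        assert out.labels == sim.labels
        out2 = convert(tr, sim)
        assert np.array_equal(out.data, out2.data)

    def test_convert_label_conditioning(self, trained):
        tr, sim = trained
        flipped = TrialSet(
            sim.data, tuple("mFB" if l == "mRB" else "mRB" if l == "mFB" else l
                            for l in sim.labels),
            sim.fs, sim.session_ids,
        )
        a = convert(tr, sim)
        b = convert(tr, flipped)
        assert np.linalg.norm(a.data - b.data) > 0

    def test_convert_unknown_label(self, trained):
        tr, sim = trained
        bad = TrialSet(sim.data, ("mXX",) * sim.n_trials, sim.fs,
                       sim.session_ids)
        with pytest.raises(ValueError):
            convert(tr, bad)

    def test_convert_channel_mismatch(self, trained, rng):
        tr, _ = trained
        other = make_trials(rng, n=2, channels=5)
        with pytest.raises(ValueError):
            convert(tr, other)

    def test_save_load_roundtrip(self, trained, tmp_path):
        tr, sim = trained
        path = tmp_path / "converter.h5"
        tr.save(path)
        back = TrainedConverter.load(path)
        a = convert(tr, sim)
        b = convert(back, sim)
        assert np.allclose(a.data, b.data, atol=1e-6)
        assert back.config.iterations == tr.config.iterations

    def test_loss_history_export(self, trained, tmp_path):
        tr, _ = trained
        path = tmp_path / "loss.tsv"
        tr.export_loss_history(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "iteration\td_loss\tg_loss"
        assert len(lines) == 31


class TestMinMaxNorm:
    def test_roundtrip(self, rng):
        data = rng.standard_normal((4, 50, 3)) * 7 + 2
        norm = MinMaxNorm.fit(data)
        x = norm.transform(data)
        assert x.min() >= -1.0 and x.max() <= 1.0
        assert np.allclose(norm.inverse(x), data)

    def test_constant_channel(self):
        data = np.zeros((2, 10, 1))
        norm = MinMaxNorm.fit(data)
        assert np.all(np.isfinite(norm.transform(data)))
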