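import numpy as np
import pytest

from fedglioma.domain_map import (DomainMapper, MapperConfig, cycle_loss,
                                  gan_losses, init_mapper,
                                  intensity_histogram_distance, map_dataset,
                                  total_objective, train_mapper)
from fedglioma.preprocess import SliceDataset


def toy_dataset(images) -> SliceDataset:
    n = len(images)
    return SliceDataset(images=np.asarray(images, float),
                        labels=np.arange(n) % 2,
                        patient_ids=np.array([f"p{i}" for i in range(n)],
                                             dtype=object),
                        views=np.array(["axial"] * n, dtype=object),
                        slice_indices=np.arange(n))


identity = lambda x: x  # noqa: E731


class TestCycleLoss:
    def test_identity_generators_zero(self):
        rng = np.random.default_rng(0)
        src = rng.random((4, 2, 8, 8))
        tgt = rng.random((3, 2, 8, 8))
        assert cycle_loss(identity, identity, src, tgt) == 0.0

    def test_nonnegative_for_arbitrary_generators(self):
        rng = np.random.default_rng(1)
        src, tgt = rng.random((4, 2, 8, 8)), rng.random((4, 2, 8, 8))
        g = lambda x: 0.5 * x + 0.1  # noqa: E731
        assert cycle_loss(g, g, src, tgt) >= 0.0

    def test_hand_l1_on_one_pixel_images(self):
        """x=0.2 round-trips to 0.3; y=0.8 round-trips to 0.6 -> 0.1+0.2."""
        src = np.array([[[[0.2]]]])
        tgt = np.array([[[[0.8]]]])

        def to_target(x):   # G_P
            return np.where(np.isclose(x, 0.2), 0.5, 0.7)

        def to_source(x):   # G_i
            out = np.where(np.isclose(x, 0.5), 0.3, x)
            return np.where(np.isclose(x, 0.8), 0.7, out)

        def to_target2(x):
            return np.where(np.isclose(x, 0.7), 0.6, to_target(x))

        loss = cycle_loss(to_source, to_target2, src, tgt)
        assert loss == pytest.approx(0.1 + 0.2)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            cycle_loss(identity, identity, np.zeros((0, 2, 4, 4)),
                       np.zeros((1, 2, 4, 4)))


class TestGanLosses:
    def test_perfect_discriminator(self):
        d = lambda x: np.ones(len(x)) if x[0, 0, 0, 0] > 0 \
            else np.zeros(len(x))  # noqa: E731
        real = np.ones((3, 1, 2, 2))
        fake = np.zeros((3, 1, 2, 2))
        l_d, l_g = gan_losses(d, real, fake)
        assert l_d == pytest.approx(0.0)
        assert l_g == pytest.approx(1.0)   # D(fake)=0 -> (0-1)^2

    def test_indifferent_discriminator_hand_value(self):
        d = lambda x: np.full(len(x), 0.5)  # noqa: E731
        l_d, l_g = gan_losses(d, np.zeros((2, 1, 2, 2)),
                              np.zeros((2, 1, 2, 2)))
        assert l_d == pytest.approx(0.5)   # 0.25 + 0.25
        assert l_g == pytest.approx(0.25)

    def test_generator_loss_zero_iff_fake_judged_real(self):
        d = lambda x: np.ones(len(x))  # noqa: E731
        _, l_g = gan_losses(d, np.zeros((2, 1, 2, 2)),
                            np.zeros((2, 1, 2, 2)))
        assert l_g == 0.0


class TestTotalObjective:
    def test_additive_composition_and_lambda_zero(self):
        rng = np.random.default_rng(2)
        src = rng.random((4, 2, 8, 8)).astype(np.float32)
        tgt = rng.random((4, 2, 8, 8)).astype(np.float32)
        pair = init_mapper(cfg=MapperConfig(seed=0), dtype=np.float32)
        from fedglioma.domain_map import discriminator_forward
        d_src = lambda x: discriminator_forward(pair.disc_source, x)[0]  # noqa: E731,E501
        d_tgt = lambda x: discriminator_forward(pair.disc_target, x)[0]  # noqa: E731,E501
        _, g_tgt = gan_losses(d_tgt, tgt, pair.map_to_target(src))
        _, g_src = gan_losses(d_src, src, pair.map_to_source(tgt))
        cyc = cycle_loss(pair.map_to_source, pair.map_to_target, src, tgt)
        lam0 = total_objective(pair, src, tgt, MapperConfig(lambda_cyc=0.0))
        assert lam0 == pytest.approx(g_tgt + g_src, rel=1e-5)
        lam10 = total_objective(pair, src, tgt,
                                MapperConfig(lambda_cyc=10.0))
        assert lam10 == pytest.approx(g_tgt + g_src + 10.0 * cyc, rel=1e-5)
        assert lam10 >= 0.0 and np.isfinite(lam10)


class TestTrainMapper:
    def test_zero_epochs_returns_initialized_pair(self):
        rng = np.random.default_rng(3)
        src = toy_dataset(rng.random((20, 2, 8, 8)))
        tgt = toy_dataset(rng.random((20, 2, 8, 8)))
        cfg = MapperConfig(epochs=0, batch_size=8, seed=4)
        pair = train_mapper(src, tgt, cfg)
        ref = init_mapper(channels=2, cfg=cfg, dtype=np.float32)
        assert pair.to_target.equal(ref.to_target)

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        src = toy_dataset(rng.random((16, 2, 8, 8)))
        tgt = toy_dataset(rng.random((16, 2, 8, 8)))
        cfg = MapperConfig(epochs=2, batch_size=8, seed=5)
        a = train_mapper(src, tgt, cfg)
        b = train_mapper(src, tgt, cfg)
        assert a.to_target.equal(b.to_target)
        assert a.disc_source.equal(b.disc_source)

    def test_too_few_images_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            train_mapper(toy_dataset(rng.random((4, 2, 8, 8))),
                         toy_dataset(rng.random((40, 2, 8, 8))),
                         MapperConfig(batch_size=16))

    def test_gain_shift_reduces_histogram_distance(self):
        """On a pure intensity-gain shift (target = 0.5 x source family)
        the mapped-source histogram moves toward the target, median over
        3 seeds."""
        deltas = []
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            base = rng.random((64, 2, 16, 16))
            src = toy_dataset(base)
            tgt = toy_dataset(0.5 * rng.random((64, 2, 16, 16)))
            cfg = MapperConfig(epochs=25, batch_size=16, seed=seed)
            pair = train_mapper(src, tgt, cfg)
            mapped = map_dataset(pair, src)
            before = intensity_histogram_distance(src.images, tgt.images)
            after = intensity_histogram_distance(mapped.images, tgt.images)
            deltas.append(after - before)
        assert np.median(deltas) < 0.0


class TestMapDataset:
    def test_identity_generator_and_metadata_invariance(self):
        rng = np.random.default_rng(6)
        ds = toy_dataset(rng.random((10, 2, 8, 8)))
        out = map_dataset(identity, ds)
        assert np.allclose(out.images, ds.images)
        assert np.array_equal(out.labels, ds.labels)
        assert list(out.patient_ids) == list(ds.patient_ids)
        assert list(out.views) == list(ds.views)

    def test_output_clipped_to_unit_interval(self):
        rng = np.random.default_rng(7)
        ds = toy_dataset(rng.random((6, 2, 8, 8)))
        wild = lambda x: 3.0 * x - 1.0  # noqa: E731
        out = map_dataset(wild, ds)
        assert out.images.min() >= 0.0 and out.images.max() <= 1.0
        assert np.array_equal(out.labels, ds.labels)


def test_domain_mapper_model_object():
    rng = np.random.default_rng(8)
    src = toy_dataset(rng.random((16, 2, 8, 8)))
    tgt = toy_dataset(rng.random((16, 2, 8, 8)))
    results = DomainMapper(src, tgt,
                           MapperConfig(epochs=1, batch_size=8)).fit()
    mapped = results.transform(src)
    assert mapped.images.shape == src.images.shape
    assert "lambda_cyc" in results.summary()
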