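"""Loss terms, schedule, generator application, and training bookkeeping."""

import math

import numpy as np
import pytest

from uldct.model import (
    LossReport,
    LossWeights,
    ModelBundle,
    TrainSchedule,
    adversarial_loss,
    build_bundle,
    cycle_loss,
    generate,
    identity_loss,
    lr_at_epoch,
    total_loss,
    train,
)
from uldct.phantom import CTImage, ParameterError, small_phantom, render_phantom
from uldct.preprocess import NormalizationSpec


class TestAdversarialLoss:
    def test_uninformative_discriminator_closed_form(self):
        d = np.full((2, 1, 4, 4), 0.5)
        d_loss, g_loss = adversarial_loss(d, d)
        # discriminator objective log(0.5) + log(0.5) = -1.3863
        assert -d_loss == pytest.approx(2 * math.log(0.5), rel=1e-9)
        assert g_loss == pytest.approx(-math.log(0.5), rel=1e-9)

    def test_perfect_discriminator_objective_approaches_zero(self):
        d_loss, _ = adversarial_loss(np.array([1.0 - 1e-9]), np.array([1e-9]))
        assert -d_loss == pytest.approx(0.0, abs=1e-5)

    def test_matches_scalar_bernoulli_oracle_on_grid(self):
        for pr in (0.1, 0.35, 0.6, 0.9):
            for pf in (0.05, 0.5, 0.77):
                d_loss, g_loss = adversarial_loss(np.array([pr]), np.array([pf]))
                assert -d_loss == pytest.approx(
                    math.log(pr) + math.log(1 - pf), rel=1e-9
                )
                assert g_loss == pytest.approx(-math.log(pf), rel=1e-9)

    def test_extreme_probabilities_clamped(self):
        d_loss, g_loss = adversarial_loss(np.array([1.0]), np.array([0.0]))
        assert math.isfinite(d_loss) and math.isfinite(g_loss)


class TestCycleIdentityLoss:
    def test_perfect_reconstruction_zero(self, rng):
        a = rng.normal(size=(2, 1, 8, 8))
        b = rng.normal(size=(2, 1, 8, 8))
        assert cycle_loss(a, a, b, b) == 0.0
        assert identity_loss(a, a, b, b) == 0.0

    def test_constant_offset(self, rng):
        a = rng.normal(size=(4, 4))
        b = rng.normal(size=(4, 4))
        assert cycle_loss(a, a + 0.1, b, b) == pytest.approx(0.1, rel=1e-9)
        assert identity_loss(a, a + 0.3, b, b + 0.2) == pytest.approx(0.5, rel=1e-9)

    def test_matches_elementwise_oracle(self, rng):
        a = rng.normal(size=(3, 5))
        ra = rng.normal(size=(3, 5))
        b = rng.normal(size=(3, 5))
        rb = rng.normal(size=(3, 5))
        oracle = (sum(abs(x - y) for x, y in zip(a.ravel(), ra.ravel())) / a.size
                  + sum(abs(x - y) for x, y in zip(b.ravel(), rb.ravel())) / b.size)
        assert cycle_loss(a, ra, b, rb) == pytest.approx(oracle, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            cycle_loss(np.zeros((2, 2)), np.zeros((3, 3)),
                       np.zeros((2, 2)), np.zeros((2, 2)))

    def test_nonnegative(self, rng):
        for _ in range(5):
            args = [rng.normal(size=(4, 4)) for _ in range(4)]
            assert cycle_loss(*args) >= 0.0
            assert identity_loss(*args) >= 0.0


class TestTotalLoss:
    def test_unit_components_default_weights(self):
        assert total_loss(1.0, 1.0, 1.0, 1.0, LossWeights(20.0, 0.5)) == 22.5

    def test_zero_weights_pure_adversarial(self):
        assert total_loss(0.7, 0.3, 5.0, 5.0, LossWeights(0.0, 0.0)) == 1.0

    def test_linearity_in_each_component(self, rng):
        w = LossWeights(20.0, 0.5)
        for _ in range(10):
            a1, a2, c, i = rng.uniform(0, 2, 4)
            base = total_loss(a1, a2, c, i, w)
            assert total_loss(a1 + 1, a2, c, i, w) == pytest.approx(base + 1)
            assert total_loss(a1, a2, c + 1, i, w) == pytest.approx(base + 20.0)
            assert total_loss(a1, a2, c, i + 1, w) == pytest.approx(base + 0.5)

    def test_report_decomposition_identity(self, rng):
        w = LossWeights()
        r = LossReport.assemble(*rng.uniform(0, 1, 4), w)
        assert r.total == pytest.approx(
            r.adv_A + r.adv_B + w.lambda_cyc * r.cyc + w.lambda_iden * r.iden
        )


class TestSchedule:
    def test_paper_defaults(self):
        s = TrainSchedule()
        assert lr_at_epoch(s, 0) == pytest.approx(2e-4)
        assert lr_at_epoch(s, 149) == pytest.approx(2e-4)
        assert lr_at_epoch(s, 200) == pytest.approx(1e-4)
        assert lr_at_epoch(s, 250) == 0.0

    def test_linear_between_breakpoints(self):
        s = TrainSchedule()
        lrs = [lr_at_epoch(s, e) for e in range(150, 251)]
        diffs = np.diff(lrs)
        assert np.allclose(diffs, diffs[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            lr_at_epoch(TrainSchedule(), 251)
        with pytest.raises(ParameterError):
            lr_at_epoch(TrainSchedule(), -1)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ParameterError):
            TrainSchedule(epochs_total=100, epochs_constant_lr=150)


NORM = NormalizationSpec(hu_floor=-1000.0, hu_ceiling=891.0)


class TestGenerate:
    def test_zero_noise_branch_is_identity(self):
        bundle = build_bundle(NORM, seed=0, base_channels=4, n_res_blocks=1,
                              width_multiplier=1.0)
        # zero every parameter of G_A: residual output = input - 0
        for p in bundle.G_A.params:
            p.data[...] = 0.0
        img = CTImage(np.random.default_rng(0).uniform(-900, 800, (32, 32)))
        out = generate(bundle, img)
        assert np.max(np.abs(out.pixels - img.pixels)) < 1e-3

    def test_output_within_normalizer_window(self):
        bundle = build_bundle(NORM, seed=1, base_channels=4, n_res_blocks=1)
        img = CTImage(np.random.default_rng(1).uniform(-1500, 2000, (32, 32)))
        out = generate(bundle, img)
        assert out.pixels.min() >= NORM.hu_floor - 1e-6
        assert out.pixels.max() <= NORM.hu_ceiling + 1e-6

    def test_shape_and_spacing_preserved_nonmultiple_of_four(self):
        bundle = build_bundle(NORM, seed=2, base_channels=4, n_res_blocks=1)
        img = CTImage(np.zeros((30, 30)), (0.7, 0.7))
        out = generate(bundle, img)
        assert out.shape == (30, 30)
        assert out.spacing_mm == (0.7, 0.7)


@pytest.fixture(scope="module")
def tiny_domains():
    spec = small_phantom()
    clean = render_phantom(spec, 32, 2.0)
    rng = np.random.default_rng(0)
    mk = lambda: [CTImage(clean.pixels + rng.normal(0, 20, clean.shape))
                  for _ in range(2)]
    return mk(), mk()


class TestTrainBookkeeping:
    def test_empty_domain_rejected(self, tiny_domains):
        with pytest.raises(ParameterError):
            train([], tiny_domains[1])

    def test_history_length_equals_epochs(self, tiny_domains):
        a, b = tiny_domains
        sched = TrainSchedule(epochs_total=2, epochs_constant_lr=1, seed=0)
        _, hist = train(a, b, sched, patch_size=16, patches_per_image=1,
                        augmentation=None, width_multiplier=0.125,
                        n_res_blocks=1, base_channels=16)
        assert len(hist) == 2

    def test_zero_generator_updates_leave_generators_unchanged(self, tiny_domains):
        a, b = tiny_domains
        sched = TrainSchedule(epochs_total=1, epochs_constant_lr=1, seed=3)
        bundle, _ = train(a, b, sched, LossWeights(0.0, 0.0),
                          patch_size=16, patches_per_image=1,
                          augmentation=None, width_multiplier=0.125,
                          n_res_blocks=1, base_channels=16, g_updates=0)
        fresh, _ = train(a, b, sched, LossWeights(0.0, 0.0),
                         patch_size=16, patches_per_image=1,
                         augmentation=None, width_multiplier=0.125,
                         n_res_blocks=1, base_channels=16,
                         g_updates=0, d_updates=0)
        for p, q in zip(bundle.G_A.params, fresh.G_A.params):
            np.testing.assert_array_equal(p.data, q.data)

    def test_checkpoint_round_trip(self, tiny_domains, tmp_path):
        a, b = tiny_domains
        sched = TrainSchedule(epochs_total=1, epochs_constant_lr=1, seed=5)
        bundle, _ = train(a, b, sched, patch_size=16, patches_per_image=1,
                          augmentation=None, width_multiplier=0.125,
                          n_res_blocks=1, base_channels=16)
        bundle.save(tmp_path / "ckpt.npz")
        loaded = ModelBundle.load(tmp_path / "ckpt.npz")
        img = CTImage(np.random.default_rng(0).uniform(-500, 500, (32, 32)))
        np.testing.assert_allclose(
            generate(bundle, img).pixels, generate(loaded, img).pixels,
            atol=1e-5,
        )
        assert loaded.normalizer == bundle.normalizer


def test_training_dynamics_cycle_loss_decreases():
    """Over short smoke runs the cycle loss must fall from its initial
    value as the generators approach consistent mappings (majority of
    seeds)."""
    spec = small_phantom()
    from uldct.phantom import make_unpaired_dataset

    wins = 0
    for seed in range(3):
        a, b = make_unpaired_dataset(spec, 2, 24.0, 200.0, seed=seed,
                                     matrix_size=64, spacing_mm=1.0,
                                     method="fast")
        sched = TrainSchedule(epochs_total=4, epochs_constant_lr=4, seed=seed)
        _, hist = train(a, b, sched, patch_size=32, patches_per_image=2,
                        augmentation=None, width_multiplier=0.25,
                        n_res_blocks=1)
        if hist[-1].cyc < hist[0].cyc:
            wins += 1
    assert wins >= 2
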