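"""Loss-suite correctness against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest

from modgan.errors import ConfigError, InvalidParameterError, ShapeError
from modgan.losses import (LossWeights, adversarial_loss, content_loss,
                           gram_matrix, holistic_loss,
                           perceptual_feature_loss, pixel_loss, ssim,
                           ssim_loss, style_loss)
from modgan.nn.autograd import Tensor


class TestAdversarial:
    def test_perfect_discrimination_has_zero_loss(self):
        d, _ = adversarial_loss(np.ones((4, 4)), np.zeros((4, 4)))
        assert d == pytest.approx(0.0, abs=1e-5)

    def test_uninformative_discriminator(self):
        d, g = adversarial_loss(np.full((4, 4), 0.5), np.full((4, 4), 0.5))
        assert d == pytest.approx(2 * math.log(2), rel=1e-9)
        assert g == pytest.approx(math.log(2), rel=1e-9)

    def test_nan_inputs_rejected(self):
        bad = np.full((2, 2), np.nan)
        with pytest.raises(InvalidParameterError):
            adversarial_loss(bad, bad)


class TestPixel:
    def test_identical_is_zero(self, rng):
        x = rng.random((8, 8, 3))
        assert pixel_loss(x, x) == 0.0

    def test_constant_offset(self, rng):
        x = rng.random((8, 8, 3))
        assert pixel_loss(x + 0.5, x) == pytest.approx(0.5)

    def test_symmetry(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert pixel_loss(a, b) == pixel_loss(b, a)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ShapeError):
            pixel_loss(rng.random((4, 4)), rng.random((4, 5)))


class TestPerceptual:
    def test_identical_features_zero(self, rng):
        feats = [rng.random((1, 4, 8, 8)), rng.random((1, 8, 4, 4))]
        assert perceptual_feature_loss(feats, feats) == 0.0

    def test_single_layer_constant_offset(self, rng):
        real = [rng.random((1, 4, 8, 8))]
        fake = [real[0] + 0.3]
        assert perceptual_feature_loss(fake, real) == pytest.approx(0.3 / 2)

    def test_matches_brute_force_double_loop(self, rng):
        fake = [rng.random((1, 3, 6, 6)), rng.random((1, 5, 3, 3))]
        real = [rng.random((1, 3, 6, 6)), rng.random((1, 5, 3, 3))]
        expected = 0.0
        for f, r in zip(fake, real):
            acc = 0.0
            for a, b in zip(f.ravel(), r.ravel()):
                acc += abs(a - b)
            expected += 0.5 * acc / f.size
        assert perceptual_feature_loss(fake, real) == pytest.approx(expected, abs=1e-6)


class TestGram:
    def test_one_channel_equals_squared_frobenius(self, rng):
        f = rng.random((1, 5, 7))
        g = gram_matrix(f)
        assert g.values.shape == (1, 1)
        assert g.values[0, 0] == pytest.approx(np.sum(f**2))
        assert g.depth == 1

    def test_symmetric_and_psd(self, rng):
        g = gram_matrix(rng.normal(size=(6, 4, 4))).values
        assert np.array_equal(g, g.T)
        assert np.linalg.eigvalsh(g).min() >= -1e-8


class TestStyle:
    def test_identical_zero(self, rng):
        feats = [rng.random((2, 4, 4))]
        assert style_loss(feats, feats) == 0.0

    def test_unit_depth_worked_example(self):
        # Gram difference [[2]] at depth 1: (1/5) * (1/4) * 2^2 = 0.2
        hat = [np.ones((1, 1, 2))]   # gram = 2
        ref = [np.zeros((1, 1, 2))]  # gram = 0
        assert style_loss(hat, ref) == pytest.approx(0.2)

    def test_invariant_to_spatial_permutation(self, rng):
        hat = rng.random((3, 4, 4))
        ref = rng.random((3, 4, 4))
        perm = rng.permutation(16)
        hat_p = hat.reshape(3, 16)[:, perm].reshape(3, 4, 4)
        assert style_loss([hat_p], [ref]) == pytest.approx(
            style_loss([hat], [ref]), rel=1e-12
        )

    def test_matches_brute_force(self, rng):
        hats = [rng.random((3, 4, 4)), rng.random((5, 2, 2))]
        refs = [rng.random((3, 4, 4)), rng.random((5, 2, 2))]
        expected = 0.0
        for h, r in zip(hats, refs):
            c = h.shape[0]
            gh = np.zeros((c, c))
            gr = np.zeros((c, c))
            for i in range(c):
                for j in range(c):
                    gh[i, j] = np.sum(h[i] * h[j])
                    gr[i, j] = np.sum(r[i] * r[j])
            expected += (1 / 5) / (4 * c * c) * np.sum((gh - gr) ** 2)
        assert style_loss(hats, refs) == pytest.approx(expected, abs=1e-6)


class TestContent:
    def test_identical_zero(self, rng):
        feats = [rng.random((1, 2, 4, 4))]
        assert content_loss(feats, feats) == 0.0

    def test_constant_offset_squared(self, rng):
        ref = [rng.random((1, 3, 5, 5))]
        hat = [ref[0] + 0.4]
        assert content_loss(hat, ref) == pytest.approx(0.4**2)

    def test_matches_brute_force_and_non_negative(self, rng):
        hats = [rng.normal(size=(1, 2, 3, 3)), rng.normal(size=(1, 4, 2, 2))]
        refs = [rng.normal(size=(1, 2, 3, 3)), rng.normal(size=(1, 4, 2, 2))]
        expected = 0.0
        for h, r in zip(hats, refs):
            expected += np.sum((h - r) ** 2) / h.size
        got = content_loss(hats, refs)
        assert got == pytest.approx(expected, abs=1e-6)
        assert got >= 0.0


def _brute_force_ssim(x, y, data_range):
    """Independent sliding-window SSIM with the 11x11 Gaussian window."""
    ax = np.arange(11) - 5.0
    g = np.exp(-(ax**2) / (2 * 1.5**2))
    w = np.outer(g, g)
    w /= w.sum()
    c1, c2 = (0.01 * data_range) ** 2, (0.03 * data_range) ** 2
    vals = []
    for i in range(x.shape[0] - 10):
        for j in range(x.shape[1] - 10):
            px = x[i : i + 11, j : j + 11]
            py = y[i : i + 11, j : j + 11]
            mx, my = (w * px).sum(), (w * py).sum()
            vx = (w * px * px).sum() - mx * mx
            vy = (w * py * py).sum() - my * my
            vxy = (w * px * py).sum() - mx * my
            vals.append(((2 * mx * my + c1) * (2 * vxy + c2))
                        / ((mx * mx + my * my + c1) * (vx + vy + c2)))
    return float(np.mean(vals))


class TestSsim:
    def test_self_similarity_is_one(self, rng):
        x = rng.random((32, 32))
        assert ssim(x, x, data_range=1.0) == pytest.approx(1.0)

    def test_anticorrelated_is_negative(self):
        # high-frequency zero-mean pattern: local means vanish, so the
        # structure term dominates and anti-correlation drives SSIM < 0
        i, j = np.mgrid[0:32, 0:32]
        x = np.sin(2 * np.pi * i / 4) * np.cos(2 * np.pi * j / 4)
        assert ssim(x, -x, data_range=float(np.ptp(x))) < 0.0

    def test_matches_brute_force_sliding_window(self, rng):
        x, y = rng.random((32, 32)), rng.random((32, 32))
        assert ssim(x, y, data_range=1.0) == pytest.approx(
            _brute_force_ssim(x, y, 1.0), abs=1e-6
        )

    def test_loss_zero_for_identical_and_bounded(self, rng):
        x = rng.random((16, 16))
        assert ssim_loss(x, x, data_range=1.0) == pytest.approx(0.0)
        y = rng.random((16, 16))
        assert 0.0 <= ssim_loss(y, x, data_range=1.0) <= 2.0

    def test_loss_decreases_along_blend_path(self, rng):
        from scipy.ndimage import gaussian_filter

        target = gaussian_filter(rng.random((32, 32)), 2.0)
        start = gaussian_filter(rng.random((32, 32)), 2.0)
        vals = [ssim_loss(start * (1 - a) + target * a, target, data_range=1.0)
                for a in (0.0, 0.5, 1.0)]
        assert vals[0] > vals[1] > vals[2]


class TestHolistic:
    def test_paper_weights_worked_example(self):
        comp = dict(adv=1.0, pix=1.0, perc=1.0, style=1.0, content=1.0, ssim=1.0)
        assert holistic_loss(comp) == pytest.approx(17.0002)

    def test_missing_components_default_to_zero(self):
        assert holistic_loss({"adv": 1.25}) == 1.25

    def test_linear_in_each_component(self, rng):
        base = {k: float(rng.random()) for k in
                ("adv", "pix", "perc", "style", "content", "ssim")}
        w = LossWeights()
        weight_of = {"adv": 1.0, "pix": w.w1, "perc": w.w2, "style": w.w3,
                     "content": w.w4, "ssim": w.w5}
        for key in base:
            bumped = dict(base)
            bumped[key] += 1.0
            delta = holistic_loss(bumped, w) - holistic_loss(base, w)
            assert delta == pytest.approx(weight_of[key], rel=1e-9)

    def test_negative_weight_rejected(self):
        with pytest.raises(ConfigError):
            LossWeights(w1=-1.0)

    def test_non_finite_component_rejected(self):
        with pytest.raises(InvalidParameterError):
            holistic_loss({"adv": float("nan")})

    def test_gradient_flows_through_every_component(self, rng):
        """On a random fixture the holistic loss must send a finite, nonzero
        gradient into the generated image through each term."""
        from modgan.nn import PatchDiscriminator, RandomFeatureExtractor

        fake = Tensor(rng.normal(scale=0.3, size=(1, 3, 32, 32)),
                      requires_grad=True)
        real = Tensor(rng.normal(scale=0.3, size=(1, 3, 32, 32)))
        cond = Tensor(rng.normal(scale=0.3, size=(1, 3, 32, 32)))
        disc = PatchDiscriminator(width=0.0625, rng=rng)
        extractor = RandomFeatureExtractor()
        logits_fake, feats_fake = disc(cond, fake)
        _, feats_real = disc(cond, real)
        f_ext = extractor.features(fake)
        r_ext = extractor.features(real)
        comp = {
            "adv": -(logits_fake.sigmoid().clip(1e-7, 1 - 1e-7).log().mean()),
            "pix": pixel_loss(fake, real),
            "perc": perceptual_feature_loss(feats_fake, feats_real),
            "style": style_loss(f_ext, r_ext),
            "content": content_loss(f_ext, r_ext),
            "ssim": ssim_loss(fake, real, data_range=2.0),
        }
        total = holistic_loss(comp)
        total.backward()
        assert np.isfinite(fake.grad).all()
        assert np.abs(fake.grad).max() > 0.0


class TestLossProperties:
    """Seeded property checks of the loss-suite invariants."""

    from hypothesis import given, settings, strategies as st

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_non_adversarial_losses_vanish_iff_inputs_coincide(self, seed):
        r = np.random.default_rng(seed)
        a = r.normal(size=(12, 12))
        b = a + r.normal(scale=0.1, size=(12, 12))
        assert pixel_loss(a, a) == 0.0
        assert content_loss([a[None, None]], [a[None, None]]) == 0.0
        assert pixel_loss(a, b) > 0.0
        assert content_loss([a[None, None]], [b[None, None]]) > 0.0
        assert style_loss([a[None]], [b[None]]) >= 0.0

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_ssim_symmetric_and_bounded(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.random((16, 16)), r.random((16, 16))
        s = ssim(x, y, data_range=1.0)
        assert -1.0 <= s <= 1.0
        assert s == pytest.approx(ssim(y, x, data_range=1.0), abs=1e-12)
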