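import numpy as np
import pytest
from scipy.signal import correlate

from proj2proj import (
    DiscriminatorSpec,
    IdentityFeatureExtractor,
    RandomConvFeatureExtractor,
    build_discriminator,
    combined_objective,
    feature_matching_loss,
    gan_loss,
)
from proj2proj.autodiff import Tensor
from proj2proj.nn import Conv2d, InstanceNorm2d, LeakyReLU, Sigmoid


# ---------------------------------------------------------------------------
# scipy-based re-implementation of the network forward passes (oracle path)

def conv_scipy(x, weight, bias, stride, pad):
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    outs = []
    for o in range(weight.shape[0]):
        acc = sum(correlate(xp[c], weight[o, c], mode="valid") for c in range(x.shape[0]))
        outs.append(acc[::stride, ::stride] + bias[o])
    return np.stack(outs)


def discriminator_scipy(disc, pair):
    """Forward the patch discriminator with scipy convolutions."""
    x = pair
    for layer in disc.net.layers:
        if isinstance(layer, Conv2d):
            x = conv_scipy(x, layer.weight.data, layer.bias.data, layer.stride, layer.pad)
        elif isinstance(layer, InstanceNorm2d):
            mu = x.mean(axis=(1, 2), keepdims=True)
            sd = np.sqrt(x.var(axis=(1, 2), keepdims=True) + 1e-5)
            x = layer.gamma.data * (x - mu) / sd + layer.beta.data
        elif isinstance(layer, LeakyReLU):
            x = np.where(x > 0, x, layer.alpha * x)
        elif isinstance(layer, Sigmoid):
            x = 1.0 / (1.0 + np.exp(-x))
        else:  # pragma: no cover
            raise AssertionError(f"unexpected layer {layer}")
    return x


def extractor_scipy(extractor, img):
    x = img[None]
    taps = []
    for i, conv in enumerate(extractor.convs):
        x = conv_scipy(x, conv.weight.data, conv.bias.data, 1, conv.pad)
        x = np.where(x > 0, x, 0.2 * x)
        taps.append(x)
        if i < len(extractor.convs) - 1:
            C, H, W = x.shape
            x = x.reshape(C, H // 2, 2, W // 2, 2).mean(axis=(2, 4))
    return taps


RNG = np.random.default_rng(17)
I_IMG = RNG.normal(size=(64, 64))
L_IMG = RNG.normal(size=(64, 64))
G_IMG = RNG.normal(size=(64, 64))
DISC = build_discriminator(DiscriminatorSpec(n_layers=3, base_channels=4), seed=5)
EXT = RandomConvFeatureExtractor(seed=6, n_stages=3, base_channels=4)


class _ConstantDiscriminator:
    def __init__(self, value):
        self.value = value

    def __call__(self, pair):
        return Tensor(np.full((1, 8, 8), self.value))


class TestGanLoss:
    def test_half_confident_discriminator_gives_log2_map(self):
        g_map, _ = gan_loss(L_IMG, G_IMG, I_IMG, _ConstantDiscriminator(0.5))
        np.testing.assert_allclose(g_map.data, -np.log(0.5), atol=1e-12)

    def test_perfect_discriminator_real_term_vanishes(self):
        class Oracle:
            def __call__(self, pair):
                is_real = np.array_equal(pair.data[1], L_IMG)
                return Tensor(np.full((1, 8, 8), 1 - 1e-9 if is_real else 1e-9))

        _, d_map = gan_loss(L_IMG, G_IMG, I_IMG, Oracle())
        # -(log D(I,L) + log(1 - D(I,G))) with both terms near 0
        np.testing.assert_allclose(d_map.data, 0.0, atol=1e-6)

    def test_patch_maps_match_scipy_forward(self):
        """Per-patch maps agree with an independent scipy re-computation of
        the discriminator on fixed random 8x8-patch inputs."""
        g_map, d_map = gan_loss(L_IMG, G_IMG, I_IMG, DISC)
        fake_scores = discriminator_scipy(DISC, np.stack([I_IMG, G_IMG]))
        real_scores = discriminator_scipy(DISC, np.stack([I_IMG, L_IMG]))
        np.testing.assert_allclose(g_map.data, -np.log(fake_scores), atol=1e-9)
        np.testing.assert_allclose(
            d_map.data, -(np.log(real_scores) + np.log(1 - fake_scores)), atol=1e-9)

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError):
            gan_loss(L_IMG, G_IMG[:32, :32], I_IMG, DISC)


class TestFeatureMatchingLoss:
    def test_vanishes_at_equality(self):
        scalar, maps = feature_matching_loss(L_IMG, L_IMG.copy(), EXT)
        assert scalar.item() == 0.0
        assert all(np.all(m.data == 0) for m in maps)

    def test_identity_extractor_constant_offset(self):
        scalar, _ = feature_matching_loss(L_IMG, L_IMG + 0.37, IdentityFeatureExtractor())
        assert scalar.item() == pytest.approx(0.37, abs=1e-12)

    def test_matches_independent_recomputation(self):
        scalar, _ = feature_matching_loss(L_IMG, G_IMG, EXT)
        taps_L = extractor_scipy(EXT, L_IMG)
        taps_G = extractor_scipy(EXT, G_IMG)
        expected = sum(np.mean(np.abs(a - b)) for a, b in zip(taps_L, taps_G))
        assert scalar.item() == pytest.approx(expected, rel=1e-9)

    def test_pseudometric_properties(self):
        """Symmetry, identity, and the triangle inequality on image triples."""
        imgs = [RNG.normal(size=(32, 32)) for _ in range(3)]
        ext = RandomConvFeatureExtractor(seed=2, n_stages=2, base_channels=4)
        d = lambda a, b: feature_matching_loss(a, b, ext)[0].item()
        for a in imgs:
            assert d(a, a) == 0.0
        for a, b in [(0, 1), (0, 2), (1, 2)]:
            assert d(imgs[a], imgs[b]) == pytest.approx(d(imgs[b], imgs[a]), rel=1e-12)
            assert d(imgs[a], imgs[b]) >= 0
        assert d(imgs[0], imgs[2]) <= d(imgs[0], imgs[1]) + d(imgs[1], imgs[2]) + 1e-12


class TestCombinedObjective:
    def test_all_ones_weight_equals_unweighted_sum(self):
        br = combined_objective(L_IMG, G_IMG, I_IMG, DISC, EXT, np.ones((64, 64)))
        assert br.weighted_total == pytest.approx(br.gan_term + br.fm_term, abs=1e-6)

    def test_all_zero_weight_annihilates_loss_and_gradient(self):
        g_t = Tensor(G_IMG[None].copy(), requires_grad=True)
        br = combined_objective(L_IMG, g_t, I_IMG, DISC, EXT, np.zeros((64, 64)))
        assert br.weighted_total == 0.0
        br.generator_loss.backward()
        assert np.all(g_t.grad == 0)

    def test_weight_map_linearity(self):
        rng = np.random.default_rng(23)
        wmap = rng.random((64, 64))
        base = combined_objective(L_IMG, G_IMG, I_IMG, DISC, EXT, wmap).weighted_total
        for alpha in (0.25, 0.5, 1.0):
            scaled = combined_objective(L_IMG, G_IMG, I_IMG, DISC, EXT, alpha * wmap)
            assert scaled.weighted_total == pytest.approx(alpha * base, rel=1e-9)

    def test_left_half_weight_ignores_far_right_perturbation(self):
        """With weights supported on the left half, pixels whose receptive
        influence lies entirely in the right half of every term map do not
        change the loss.  The probe discriminator has a single strided layer
        (no instance normalization, whose global statistics would couple every
        pixel to every patch score)."""
        local_disc = build_discriminator(DiscriminatorSpec(n_layers=1, base_channels=4), seed=9)
        wmap = np.zeros((64, 64))
        wmap[:, :32] = 1.0
        base = combined_objective(L_IMG, G_IMG, I_IMG, local_disc, EXT, wmap).weighted_total
        perturbed = G_IMG.copy()
        perturbed[:, 60:] += 5.0
        after = combined_objective(L_IMG, perturbed, I_IMG, local_disc, EXT, wmap).weighted_total
        assert after == pytest.approx(base, abs=1e-9)

    def test_rejects_weight_shape_mismatch(self):
        with pytest.raises(ValueError):
            combined_objective(L_IMG, G_IMG, I_IMG, DISC, EXT, np.ones((32, 32)))

    def test_gan_fm_coefficients_scale_terms(self):
        ones = np.ones((64, 64))
        br1 = combined_objective(L_IMG, G_IMG, I_IMG, DISC, EXT, ones, gan_weight=0.0,
                                 fm_weight=1.0)
        br2 = combined_objective(L_IMG, G_IMG, I_IMG, DISC, EXT, ones, gan_weight=1.0,
                                 fm_weight=0.0)
        assert br1.weighted_total == pytest.approx(br1.fm_term, abs=1e-6)
        assert br2.weighted_total == pytest.approx(br2.gan_term, abs=1e-6)
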