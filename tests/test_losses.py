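"""Loss-term tests against independent loop-computed oracles."""

import numpy as np
import pytest

from odcseg import losses as L
from odcseg.nn import Tensor


@pytest.fixture
def weights():
    return L.LossWeights(mu1=1.7, mu2=0.3, mu3=2.0, mu4=0.9,
                         delta1=1.1, delta2=0.05, rho1=0.7, rho2=1.3)


class TestReconLosses:
    def test_identity_is_zero_and_constant_offset(self, rng):
        x = rng.normal(0, 1, (2, 3, 8, 8))
        assert float(L.recon_loss_image(x, x)) == 0.0
        assert float(L.recon_loss_image(np.zeros((4, 4)), np.full((4, 4), 0.5))) \
            == pytest.approx(0.5)

    @pytest.mark.parametrize("fn", [L.recon_loss_image, L.recon_loss_content,
                                    L.recon_loss_style])
    def test_matches_loop_oracle_and_symmetry(self, fn, rng):
        a = rng.normal(0, 1, (2, 5, 6))
        b = rng.normal(0, 1, (2, 5, 6))
        ref = np.mean([abs(a.flat[i] - b.flat[i]) for i in range(a.size)])
        assert float(fn(a, b)) == pytest.approx(ref, rel=1e-12)
        assert float(fn(b, a)) == pytest.approx(float(fn(a, b)))
        assert float(fn(a, b)) > 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            L.recon_loss_image(np.zeros((2, 2)), np.zeros((3, 3)))


class TestGanLossTranslation:
    def test_half_scores_single_patch(self):
        # raw objective log(0.5) + log(0.5) = -1.3863; returned negated
        loss = L.gan_loss_translation(np.array([[0.5]]), np.array([[0.5]]))
        assert float(loss) == pytest.approx(-2 * np.log(0.5))

    def test_perfect_discriminator_limit(self):
        loss = L.gan_loss_translation(np.array([[1.0]]), np.array([[0.0]]))
        assert 0 <= float(loss) < 1e-5

    def test_matches_loop_oracle(self, rng):
        real = rng.uniform(0.05, 0.95, (2, 4, 4))
        fake = rng.uniform(0.05, 0.95, (2, 4, 4))
        ref = -(np.mean([np.log(v) for v in real.flat])
                + np.mean([np.log(1 - v) for v in fake.flat]))
        assert float(L.gan_loss_translation(real, fake)) == pytest.approx(ref, rel=1e-12)
        gen_ref = -np.mean([np.log(v) for v in fake.flat])
        assert float(L.gan_loss_translation(None, fake, role="generator")) \
            == pytest.approx(gen_ref, rel=1e-12)

    def test_out_of_range_scores_clamped_finite(self):
        loss = L.gan_loss_translation(np.array([2.0]), np.array([-1.0]))
        assert np.isfinite(float(loss))


class TestSegLosses:
    def test_one_hot_match_is_zero(self):
        y = np.eye(3)[np.random.default_rng(0).integers(0, 3, (4, 4))].transpose(2, 0, 1)
        assert float(L.seg_ce_loss(y, np.clip(y, 1e-9, 1))) < 1e-5

    def test_uniform_probs_analytic(self):
        # 2x2 image, 3 classes, uniform prediction: sum form = 4 log 3
        y = np.zeros((3, 2, 2))
        y[0] = 1.0
        p = np.full((3, 2, 2), 1 / 3)
        assert float(L.seg_ce_loss(y, p)) == pytest.approx(4 * np.log(3), rel=1e-9)
        assert float(L.seg_ce_loss(y, p, reduction="mean")) \
            == pytest.approx(np.log(3), rel=1e-9)

    def test_matches_triple_loop_oracle(self, rng):
        labels = rng.integers(0, 3, (5, 6))
        y = np.eye(3)[labels].transpose(2, 0, 1)
        logits = rng.normal(0, 1, (3, 5, 6))
        e = np.exp(logits)
        p = e / e.sum(0)
        ref = 0.0
        for h in range(5):
            for w in range(6):
                for c in range(3):
                    ref -= y[c, h, w] * np.log(p[c, h, w])
        assert float(L.seg_ce_loss(y, p)) == pytest.approx(ref, rel=1e-9)

    def test_seg_disc_loss_spot_values_and_oracle(self, rng):
        half = np.array([[0.5]])
        assert float(L.seg_disc_loss(half, half)) == pytest.approx(-2 * np.log(0.5))
        half4 = np.full((2, 2), 0.5)
        assert float(L.seg_disc_loss(half4, half4)) == pytest.approx(-8 * np.log(0.5))
        s, t = rng.uniform(0.1, 0.9, (3, 3)), rng.uniform(0.1, 0.9, (3, 3))
        ref = -(sum(np.log(v) for v in s.flat) + sum(np.log(1 - v) for v in t.flat))
        assert float(L.seg_disc_loss(s, t)) == pytest.approx(ref, rel=1e-12)

    def test_seg_adv_loss_spot_values_and_oracle(self, rng):
        assert float(L.seg_adv_loss(np.array([[1.0]]))) == pytest.approx(0.0, abs=1e-5)
        assert float(L.seg_adv_loss(np.array([[0.5]]))) == pytest.approx(-np.log(0.5))
        t = rng.uniform(0.1, 0.9, (4, 4))
        assert float(L.seg_adv_loss(t)) == pytest.approx(
            -sum(np.log(v) for v in t.flat), rel=1e-12)


def _random_batch(rng):
    shp = (1, 2, 3, 3)
    mk = lambda: Tensor(rng.normal(0, 1, shp))
    vec = lambda: Tensor(rng.normal(0, 1, (1, 4)))
    return L.TranslationBatch(xs=mk(), xt=mk(), cs=mk(), ct=mk(), ss=vec(), st=vec(),
                              xs_t=mk(), xt_s=mk(), xs_s=mk(), xt_t=mk(),
                              cs_rec=mk(), ct_rec=mk(), ss_rec=vec(), st_rec=vec())


class TestTotals:
    def test_translation_total_zero_weights(self, rng):
        batch = _random_batch(rng)
        scores = {k: Tensor(rng.uniform(0.2, 0.8, (1, 2, 2)))
                  for k in ("real_target", "fake_target", "real_source", "fake_source")}
        zero = L.LossWeights(mu1=0, mu2=0, mu3=0, mu4=0)
        assert float(L.total_translation_loss(batch, zero, scores)) == 0.0

    def test_translation_total_matches_hand_sum(self, rng, weights):
        batch = _random_batch(rng)
        scores = {k: Tensor(rng.uniform(0.2, 0.8, (1, 2, 2)))
                  for k in ("real_target", "fake_target", "real_source", "fake_source")}
        total = float(L.total_translation_loss(batch, weights, scores, role="generator"))
        hand = (weights.mu1 * (float(L.recon_loss_image(batch.xs, batch.xs_s))
                               + float(L.recon_loss_image(batch.xt, batch.xt_t)))
                + weights.mu2 * (float(L.recon_loss_content(batch.cs, batch.cs_rec))
                                 + float(L.recon_loss_content(batch.ct, batch.ct_rec)))
                + weights.mu3 * (float(L.recon_loss_style(batch.ss, batch.ss_rec))
                                 + float(L.recon_loss_style(batch.st, batch.st_rec)))
                + weights.mu4 * (float(L.gan_loss_translation(None, scores["fake_target"], "generator"))
                                 + float(L.gan_loss_translation(None, scores["fake_source"], "generator"))))
        assert total == pytest.approx(hand, rel=1e-9)

    def test_perfect_recon_only_gan_terms_remain(self, rng, weights):
        batch = _random_batch(rng)
        batch.xs_s, batch.xt_t = batch.xs, batch.xt
        batch.cs_rec, batch.ct_rec = batch.cs, batch.ct
        batch.ss_rec, batch.st_rec = batch.ss, batch.st
        half = Tensor(np.full((1, 2, 2), 0.5))
        scores = {k: half for k in ("real_target", "fake_target",
                                    "real_source", "fake_source")}
        total = float(L.total_translation_loss(batch, weights, scores, role="generator"))
        assert total == pytest.approx(weights.mu4 * 2 * (-np.log(0.5)), rel=1e-6)

    def test_seg_total_and_grand_total(self, weights, rng):
        ce, adv = 1.7, -0.3
        assert float(L.total_seg_loss(ce, adv, weights)) \
            == pytest.approx(weights.delta1 * ce + weights.delta2 * adv)
        zero = L.LossWeights(rho1=0, rho2=0)
        assert float(L.grand_total(2.5, 9.0, 4.0, zero)) == pytest.approx(2.5)
        one = L.LossWeights(rho1=1, rho2=1)
        assert float(L.grand_total(1.0, 1.0, 1.0, one)) == pytest.approx(3.0)
        tr, sg, sh = rng.normal(), rng.normal(), abs(rng.normal())
        assert float(L.grand_total(tr, sg, sh, weights)) \
            == pytest.approx(tr + weights.rho1 * sg + weights.rho2 * sh, rel=1e-12)

    def test_totals_linear_in_weights(self, rng):
        """Finite differences in weight space confirm exact linearity."""
        tr, sg, sh = 1.3, 0.7, 2.1
        f = lambda r1, r2: float(L.grand_total(tr, sg, sh, L.LossWeights(rho1=r1, rho2=r2)))
        for r1, r2 in [(0.4, 1.0), (1.6, 0.2)]:
            d1 = (f(r1 + 0.5, r2) - f(r1, r2)) / 0.5
            d2 = (f(r1, r2 + 0.5) - f(r1, r2)) / 0.5
            assert d1 == pytest.approx(sg, rel=1e-12)
            assert d2 == pytest.approx(sh, rel=1e-12)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            L.LossWeights(mu1=-1)
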