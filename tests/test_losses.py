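"""Value identities and properties of the adversarial/cycle/semantic losses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from domainsalvage import losses as L
from domainsalvage.nn import Tensor
from domainsalvage.nn import autograd as ag


class TestSaturatingAdversarial:
    def test_symmetric_point(self):
        v = L.adv_loss_saturating([0.5, 0.5], [0.5, 0.5]).item()
        assert v == pytest.approx(2 * np.log(0.5), abs=1e-12)

    def test_direct_formula(self):
        v = L.adv_loss_saturating([0.8], [0.3]).item()
        assert v == pytest.approx(np.log(0.8) + np.log(0.7), abs=1e-12)

    def test_perfect_discriminator_limit(self):
        v = L.adv_loss_saturating([1 - 1e-9], [1e-9]).item()
        assert -1e-6 < v < 0

    def test_rejects_probabilities_outside_unit_interval(self):
        with pytest.raises(ValueError, match="0, 1"):
            L.adv_loss_saturating([1.2], [0.5])


class TestWassersteinAdversarial:
    def test_cancelling_scores_with_unit_penalty(self):
        assert L.adv_loss_wgan([0.5], [0.5], gp=1.0, lambda_gp=10.0).item() \
            == pytest.approx(-10.0)

    def test_penalty_off(self):
        assert L.adv_loss_wgan([2.0], [-1.0], gp=0.0).item() == pytest.approx(3.0)

    def test_matches_arithmetic_recomputation(self, seed=5):
        rng = np.random.default_rng(seed)
        r, f = rng.normal(size=20), rng.normal(size=20)
        gp = float(rng.random())
        expect = r.mean() - f.mean() - 10.0 * gp
        assert L.adv_loss_wgan(r, f, gp).item() == pytest.approx(expect, abs=1e-12)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            L.adv_loss_wgan([0.0], [0.0], gp=-0.1)


class TestGradientPenalty:
    """Closed-form critics: D(x) = a * sum(x) has input gradient norm a*sqrt(d)."""

    def test_unit_gradient_critic_zero_penalty(self, rng):
        critic = lambda x: x.sum(axis=1)
        x = rng.random((4, 1))
        assert L.gradient_penalty(critic, x, rng.random((4, 1)), rng) \
            == pytest.approx(0.0, abs=1e-12)

    def test_constant_critic_full_penalty(self, rng):
        critic = lambda x: x.sum(axis=(1, 2, 3)) * 0.0
        x = rng.random((3, 1, 2, 2))
        gp = L.gradient_penalty(critic, x, rng.random((3, 1, 2, 2)), rng)
        assert gp == pytest.approx(1.0, abs=1e-12)
        assert 10.0 * gp == pytest.approx(10.0)

    def test_linear_critic_closed_form(self, rng):
        # D(x) = 2 * sum(x) on 2x2x1 images: norm = 2*sqrt(4) = 4, gp = 9
        critic = lambda x: 2.0 * x.sum(axis=(1, 2, 3))
        x = rng.random((5, 1, 2, 2))
        assert L.gradient_penalty(critic, x, rng.random((5, 1, 2, 2)), rng) \
            == pytest.approx(9.0, abs=1e-10)

    @pytest.mark.parametrize("d", [1, 4, 16])
    def test_minimized_at_inverse_sqrt_dim(self, rng, d):
        # over the family D(x) = a*sum(x), gp(a) = (|a|*sqrt(d) - 1)^2
        shape = (3, 1, d, 1)
        x, xf = rng.random(shape), rng.random(shape)
        best = 1.0 / np.sqrt(d)
        gp_best = L.gradient_penalty(lambda t: best * t.sum(axis=(1, 2, 3)), x, xf, rng)
        assert gp_best == pytest.approx(0.0, abs=1e-10)
        for a in (0.5 * best, 2.0 * best):
            assert L.gradient_penalty(lambda t: a * t.sum(axis=(1, 2, 3)), x, xf, rng) \
                > gp_best + 0.01

    def test_interpolates_lie_on_segment(self, rng):
        x, xf = rng.random((6, 1, 3, 3)), rng.random((6, 1, 3, 3))
        _, x_hat, _, _ = L.gradient_penalty_parts(
            lambda t: t.sum(axis=(1, 2, 3)), x, xf, rng)
        lo = np.minimum(x, xf) - 1e-12
        hi = np.maximum(x, xf) + 1e-12
        assert ((x_hat >= lo) & (x_hat <= hi)).all()


class TestClassificationLosses:
    def test_uniform_logits(self):
        assert L.cls_loss_real(np.zeros((4, 3)), [0, 1, 2, 0]).item() \
            == pytest.approx(np.log(3), abs=1e-12)

    def test_direct_probability(self):
        p = np.array([[0.7, 0.2, 0.1]])
        assert L.cls_loss_real(np.log(p), [0]).item() \
            == pytest.approx(-np.log(0.7), abs=1e-12)

    def test_confident_correct_approaches_zero(self):
        logits = np.array([[30.0, 0.0]])
        assert L.cls_loss_real(logits, [0]).item() < 1e-9

    def test_domain_index_out_of_range(self):
        with pytest.raises(ValueError):
            L.cls_loss_real(np.zeros((2, 3)), [0, 3])

    def test_fake_loss_is_real_loss_of_translated(self, rng):
        # definitional identity for fixed callables
        w = rng.normal(size=(4, 3))
        g = lambda x, c: Tensor(np.tanh(np.asarray(x)))
        d_cls = lambda x: Tensor(x.data @ w if isinstance(x, Tensor) else x @ w)
        x = rng.normal(size=(5, 4))
        c = np.array([0, 1, 2, 0, 1])
        lhs = L.cls_loss_fake(d_cls, g, x, c).item()
        rhs = L.cls_loss_real(d_cls(g(x, c)), c).item()
        assert lhs == pytest.approx(rhs, abs=1e-12)

    def test_task_loss_uniform_and_softmax_arithmetic(self):
        assert L.task_loss(lambda x: Tensor(np.zeros((3, 10))), None, [1, 2, 3]).item() \
            == pytest.approx(np.log(10), abs=1e-12)
        logits = np.array([[2.0, 1.0, 0.0]])
        expect = -np.log(np.exp(2) / (np.exp(2) + np.exp(1) + 1))
        assert L.task_loss(lambda x: Tensor(logits), None, [0]).item() \
            == pytest.approx(expect, abs=1e-12)


class TestCycleLoss:
    def test_identity_generator(self, rng):
        g = lambda x, c: x if isinstance(x, Tensor) else Tensor(np.asarray(x))
        x = rng.normal(size=(3, 1, 4, 4))
        assert L.cycle_loss(g, x, 1, 0).item() == 0.0

    def test_constant_offset(self):
        g = lambda x, c: Tensor(np.full((2, 1, 2, 2), 0.1))
        x = np.zeros((2, 1, 2, 2))
        assert L.cycle_loss(g, x, 1, 0).item() == pytest.approx(0.1, abs=1e-12)

    def test_batch_permutation_invariance(self, rng):
        flip = lambda x, c: Tensor(-_data(x))
        x = rng.normal(size=(6, 1, 3, 3))
        v1 = L.cycle_loss(flip, x, 1, 0).item()
        v2 = L.cycle_loss(flip, x[::-1].copy(), 1, 0).item()
        assert v1 == pytest.approx(v2, abs=1e-12)


def _data(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x)


class TestSemanticLoss:
    def test_identity_generator_perfect_classifiers(self, rng):
        g = lambda x, c: Tensor(_data(x))
        y = np.array([0, 1, 0])
        x = rng.normal(size=(3, 4))

        def one_hot_net(x):
            # confident logits at the true label for this fixed batch
            out = np.full((3, 2), -30.0)
            out[np.arange(3), y] = 30.0
            return Tensor(out)

        v = L.semantic_loss(g, one_hot_net, one_hot_net, x, y, x, 1, 0).item()
        assert v < 1e-9

    def test_uniform_classifiers_give_three_log_n(self, rng):
        n = 7
        g = lambda x, c: Tensor(_data(x))
        uni = lambda x: Tensor(np.zeros((len(_data(x)), n)))
        x = rng.normal(size=(4, 3))
        y = np.array([0, 1, 2, 3])
        v = L.semantic_loss(g, uni, uni, x, y, x, 1, 0).item()
        assert v == pytest.approx(3 * np.log(n), abs=1e-10)

    def test_additive_composition(self, rng):
        rng2 = np.random.default_rng(9)
        w1, w2 = rng2.normal(size=(4, 3)), rng2.normal(size=(4, 3))
        g = lambda x, c: Tensor(np.tanh(_data(x)))
        f_s = lambda x: Tensor(_data(x) @ w1)
        f_t = lambda x: Tensor(_data(x) @ w2)
        x_s, x_t = rng.normal(size=(5, 4)), rng.normal(size=(6, 4))
        y_s = np.array([0, 1, 2, 0, 1])
        total = L.semantic_loss(g, f_s, f_t, x_s, y_s, x_t, 1, 0).item()
        fake = g(x_s, 1)
        pseudo = np.argmax(f_t(x_t).data, axis=1)
        parts = (L.task_loss(f_t, fake, y_s).item()
                 + L.task_loss(f_s, g(fake, 0), y_s).item()
                 + L.task_loss(f_s, g(x_t, 1), pseudo).item())
        assert total == pytest.approx(parts, abs=1e-12)


class TestFinalObjectives:
    def test_unit_components_default_weights(self):
        assert L.discriminator_objective(1.0, 1.0) == pytest.approx(0.0)
        assert L.generator_objective(1.0, 1.0, 1.0, 1.0) == pytest.approx(13.0)

    def test_zero_cycle_weight_removes_term(self):
        w = L.LossWeights(cyc=0.0)
        a = L.generator_objective(0.0, 0.0, 123.0, 0.0, w)
        b = L.generator_objective(0.0, 0.0, 0.0, 0.0, w)
        assert a == b == 0.0

    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_composition_matches_hand_sum(self, vals):
        adv, clsf, cyc, sem = vals
        w = L.LossWeights()
        assert L.generator_objective(adv, clsf, cyc, sem, w) \
            == pytest.approx(adv + w.cls * clsf + w.cyc * cyc + sem, rel=1e-12, abs=1e-12)
        assert L.discriminator_objective(adv, clsf, w) \
            == pytest.approx(-adv + w.cls * clsf, rel=1e-12, abs=1e-12)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            L.LossWeights(cls=-1.0)


class TestFinitenessProperties:
    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_losses_finite_and_nonnegative_where_implied(self, seed):
        rng = np.random.default_rng(seed)
        logits = rng.normal(size=(4, 3)) * 10
        y = rng.integers(0, 3, 4)
        assert np.isfinite(L.cls_loss_real(logits, y).item())
        assert L.cls_loss_real(logits, y).item() >= 0
        g = lambda x, c: Tensor(np.tanh(_data(x)))
        x = rng.normal(size=(3, 1, 2, 2))
        assert L.cycle_loss(g, x, 1, 0).item() >= 0
        r, f = rng.normal(size=5), rng.normal(size=5)
        assert np.isfinite(L.adv_loss_wgan(r, f, rng.random()).item())


class TestGpParameterGradients:
    def test_matches_closed_form_for_scaled_sum_critic(self, rng):
        """For D(x) = a*sum(x): gp(a) = (|a|*sqrt(d)-1)^2, so
        d gp/d a = 2(a*sqrt(d)-1)*sqrt(d) for a > 0."""
        from domainsalvage.nn import Module, Parameter

        class ScaledSum(Module):
            def __init__(self, a):
                super().__init__()
                self.a = Parameter(np.array(a))

            def src_scores(self, x):
                return x.sum(axis=(1, 2, 3)) * self.a

            def forward(self, x):
                return self.src_scores(x)

        d = 9
        a0 = 0.7
        critic = ScaledSum(a0)
        x = rng.random((4, 1, 3, 3))
        xf = rng.random((4, 1, 3, 3))
        gp, x_hat, g, norms = L.gradient_penalty_parts(critic, x, xf, rng)
        assert gp == pytest.approx((a0 * np.sqrt(d) - 1) ** 2, abs=1e-9)
        critic.zero_grad()
        L.gp_parameter_gradients(critic, x_hat, g, norms, coeff=1.0)
        expect = 2 * (a0 * np.sqrt(d) - 1) * np.sqrt(d)
        assert critic.a.grad == pytest.approx(expect, rel=1e-4)


class TestOneStepDescent:
    """One Adam step with the composite objectives on a frozen toy batch
    decreases the stepped player's loss (small learning rate, 3 seeds)."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_critic_and_generator_objectives_decrease(self, seed):
        from domainsalvage.networks import (DiscriminatorSpec, GeneratorSpec,
                                            build_discriminator, build_generator)
        from domainsalvage.nn import Adam
        from domainsalvage.nn import autograd as ag

        rng = np.random.default_rng(seed)
        g = build_generator(GeneratorSpec(image_size=8, base_channels=4, n_down=1,
                                          n_res=1, n_domains=2),
                            np.random.default_rng(seed))
        d = build_discriminator(DiscriminatorSpec(image_size=8, base_channels=4,
                                                  n_domains=2),
                                np.random.default_rng(seed + 10))
        x = rng.uniform(-1, 1, (4, 3, 8, 8)).astype(np.float32)
        dom = np.array([0, 0, 1, 1])
        w = L.LossWeights()
        gp_rng_state = np.random.default_rng(seed + 99)

        def critic_loss(backward=False):
            with ag.no_grad():
                fake = g(x, 1 - dom).data
            smap, cls_logits = d(np.concatenate([x, fake]))
            scores = smap.mean(axis=(1, 2, 3))
            s_real = ag.narrow(scores, 0, 4)
            s_fake = ag.narrow(scores, 4, 8)
            cls_real = L.cls_loss_real(ag.narrow(cls_logits, 0, 4), dom)
            gp, x_hat, grad, norms = L.gradient_penalty_parts(
                d, x, fake, np.random.default_rng(seed + 99))
            adv = L.adv_loss_wgan(s_real, s_fake, gp, w.gp)
            loss = L.discriminator_objective(adv, cls_real, w)
            if backward:
                loss.backward()
                L.gp_parameter_gradients(d, x_hat, grad, norms, w.gp)
            return loss.item()

        opt_d = Adam(d.parameters(), lr=1e-5)
        before = critic_loss(backward=True)
        opt_d.step()
        d.zero_grad()
        assert critic_loss() < before

        def gen_loss(backward=False):
            fake = g(x, 1 - dom)
            smap, cls_logits = d(fake)
            adv = -smap.mean()
            cls_fake = L.cls_loss_real(cls_logits, 1 - dom)
            cyc = (ag.Tensor(x) - g(fake, dom)).abs().mean()
            loss = L.generator_objective(adv, cls_fake, cyc, 0.0, w)
            if backward:
                loss.backward()
            return loss.item()

        opt_g = Adam(g.parameters(), lr=1e-5)
        g.zero_grad()
        before = gen_loss(backward=True)
        opt_g.step()
        g.zero_grad()
        assert gen_loss() < before
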