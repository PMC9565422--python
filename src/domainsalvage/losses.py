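"""Adversarial, domain-classification, cycle, task and semantic losses.

Every loss is a pure function of network outputs (or of the networks as
callables) and labels; each accepts either plain arrays or autograd tensors
and returns a scalar tensor, so the same code path serves both numerical
checks and training.

Conventions: patch score maps are averaged over their spatial extent before
batch averaging; the L1 cycle penalty is a mean over pixels and batch so
its weight is image-size-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autograd as ag
from .nn import Tensor, Module

__all__ = [
    "LossWeights", "adv_loss_saturating", "adv_loss_wgan", "gradient_penalty",
    "gradient_penalty_parts", "gp_parameter_gradients", "cls_loss_real",
    "cls_loss_fake", "cycle_loss", "task_loss", "semantic_loss",
    "discriminator_objective", "generator_objective",
]


@dataclass
class LossWeights:
    """Scalar weights of the composite objectives: all experiments use
    gp=10, cls=1, cyc=10."""

    gp: float = 10.0
    cls: float = 1.0
    cyc: float = 10.0

    def __post_init__(self):
        if min(self.gp, self.cls, self.cyc) < 0:
            raise ValueError("loss weights must be non-negative")


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _scalar(x):
    return x if isinstance(x, Tensor) else float(x)


def adv_loss_saturating(d_real, d_fake) -> Tensor:
    """Original (saturating) GAN objective on probabilities:
    E[log D(x)] + E[log(1 - D(G(x, c)))].  Reference implementation; the
    training default is the Wasserstein form."""
    d_real, d_fake = _t(d_real), _t(d_fake)
    for name, v in (("d_real", d_real), ("d_fake", d_fake)):
        if v.data.min() <= 0.0 or v.data.max() >= 1.0:
            raise ValueError(f"{name} must be probabilities strictly inside (0, 1), "
                             f"got range [{v.data.min():.4g}, {v.data.max():.4g}]")
    return ag.log(d_real).mean() + ag.log(1.0 - d_fake).mean()


def adv_loss_wgan(d_real, d_fake, gp, lambda_gp: float = 10.0) -> Tensor:
    """Wasserstein critic objective with gradient penalty:
    E[D(x)] - E[D(G(x, c))] - lambda_gp * GP."""
    gp_val = gp.item() if isinstance(gp, Tensor) else float(gp)
    if gp_val < 0:
        raise ValueError("gradient penalty must be >= 0")
    return _t(d_real).mean() - _t(d_fake).mean() - lambda_gp * _scalar(gp)


def _per_item_scores(out) -> Tensor:
    """Reduce critic output to one score per item (spatial mean of patch maps)."""
    if isinstance(out, tuple):
        out = out[0]
    out = _t(out)
    if out.data.ndim == 1:
        return out
    return out.mean(axis=tuple(range(1, out.data.ndim)))


def gradient_penalty_parts(d_src, x_real, x_fake, rng: np.random.Generator):
    """Interpolates, per-item input gradients and the penalty value.

    Returns (penalty: float, x_hat, grad, norms).  The interpolation weight
    alpha is uniform per item along the segment between coupled real/fake
    points; the gradient norm is over all pixels of each item.
    """
    xr = x_real.data if isinstance(x_real, Tensor) else np.asarray(x_real)
    xf = x_fake.data if isinstance(x_fake, Tensor) else np.asarray(x_fake)
    if xr.shape != xf.shape:
        raise ValueError("real and fake batches must have the same shape")
    alpha = rng.random(len(xr)).astype(xr.dtype).reshape((-1,) + (1,) * (xr.ndim - 1))
    x_hat = alpha * xr + (1.0 - alpha) * xf

    params = d_src.parameters() if isinstance(d_src, Module) else []
    flags = [p.requires_grad for p in params]
    for p in params:
        p.requires_grad = False
    try:
        xt = Tensor(x_hat, requires_grad=True)
        scores = _per_item_scores(d_src.src_scores(xt) if hasattr(d_src, "src_scores")
                                  else d_src(xt))
        scores.sum().backward()
    finally:
        for p, f in zip(params, flags):
            p.requires_grad = f
    if xt.grad is None:
        raise ValueError("critic is not differentiable with respect to its input")
    g = xt.grad
    norms = np.sqrt((g.reshape(len(g), -1) ** 2).sum(axis=1))
    penalty = float(((norms - 1.0) ** 2).mean())
    return penalty, x_hat, g, norms


def gradient_penalty(d_src, x_real, x_fake, rng: np.random.Generator) -> float:
    """Mean over the batch of (||grad_x_hat D_src(x_hat)||_2 - 1)^2."""
    return gradient_penalty_parts(d_src, x_real, x_fake, rng)[0]


def gp_parameter_gradients(critic: Module, x_hat, g, norms, coeff: float,
                           rel_eps: float = 1e-3) -> None:
    """Accumulate d(coeff * GP)/d(theta) into the critic's parameter grads.

    The penalty's parameter gradient needs the mixed second derivative
    d^2 D / (d x d theta); it is obtained as the parameter gradient of the
    directional derivative of the critic along v = dGP/dg, approximated by a
    central finite difference of the score sum in input space.  The critic is
    piecewise-linear in its input (conv + LeakyReLU, no normalization), so
    within a linear region the difference quotient is exact.
    """
    B = len(x_hat)
    v = (2.0 * (norms - 1.0) / (B * (norms + 1e-12)))
    v = v.reshape((-1,) + (1,) * (x_hat.ndim - 1)) * g
    vmax = float(np.abs(v).max())
    if vmax == 0.0:
        return
    eps = rel_eps / vmax
    both = np.concatenate([x_hat + eps * v, x_hat - eps * v])
    s = _per_item_scores(critic.src_scores(Tensor(both)))
    sign = np.concatenate([np.full(B, 1.0), np.full(B, -1.0)]).astype(s.dtype)
    (s * Tensor(sign * (coeff / (2.0 * eps)))).sum().backward()


def cls_loss_real(d_cls_logits, true_domain) -> Tensor:
    """Eq-3 style domain-classification NLL of the critic on real images."""
    logits = _t(d_cls_logits)
    dom = np.asarray(true_domain)
    k = logits.data.shape[1]
    if dom.max() >= k or dom.min() < 0:
        raise ValueError(f"domain index outside [0, {k})")
    return ag.cross_entropy(logits, dom)


def cls_loss_fake(d_cls, g, x, c) -> Tensor:
    """Domain-classification NLL of translated images at the target code;
    used to optimize the generator only."""
    fake = g(x, c)
    return cls_loss_real(d_cls(fake), c)


def cycle_loss(g, x, c, c_prime) -> Tensor:
    """Mean absolute pixel error of the round trip x -> c -> c_prime."""
    x = _t(x)
    recon = g(g(x, c), c_prime)
    return (x - recon).abs().mean()


def task_loss(f, x, y) -> Tensor:
    """Mean softmax cross-entropy of classifier f on (x, y)."""
    logits = f(x) if callable(f) else f
    return ag.cross_entropy(_t(logits), np.asarray(y))


def semantic_loss(g, f_s, f_t, x_s, y_s, x_t, c, c_prime) -> Tensor:
    """Weak-supervision loss preserving class content through translation:

    task(F_T, G(x_s, c), y_s)
      + task(F_S, G(G(x_s, c), c'), y_s)
      + task(F_S, G(x_t, c), argmax F_T(x_t)).

    The third term pseudo-labels unlabeled target images with the target
    classifier's hard predictions; F_S is the frozen source classifier.
    """
    fake_t = g(x_s, c)
    recon = g(fake_t, c_prime)
    with ag.no_grad():
        pseudo = np.argmax(f_t(x_t).data, axis=1)
    return (task_loss(f_t, fake_t, y_s)
            + task_loss(f_s, recon, y_s)
            + task_loss(f_s, g(x_t, c), pseudo))


def discriminator_objective(adv, cls_real, weights: LossWeights | None = None):
    """L_D = -L_adv + lambda_cls * L_cls^real."""
    w = weights or LossWeights()
    return -_scalar_or_t(adv) + w.cls * _scalar_or_t(cls_real)


def generator_objective(adv, cls_fake, cyc, sem, weights: LossWeights | None = None):
    """L_G = L_adv + lambda_cls * L_cls^fake + lambda_cyc * L_cyc + L_sem."""
    w = weights or LossWeights()
    return (_scalar_or_t(adv) + w.cls * _scalar_or_t(cls_fake)
            + w.cyc * _scalar_or_t(cyc) + _scalar_or_t(sem))


def _scalar_or_t(x):
    return x if isinstance(x, Tensor) else float(x)
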