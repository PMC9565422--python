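"""Training procedures: baseline classifiers, adversarial adaptation, and
translate-then-fine-tune.

The adaptation loop is class-unsupervised by construction: it accepts target
images (and a target domain code) but never target class labels — the
function signature has nowhere to put them.  Determinism: one master seed is
fanned out (data order, weight init, gradient-penalty interpolation,
dropout), so identical config + seed reproduces loss histories bit-for-bit
on CPU.
"""

from __future__ import annotations

import contextlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import losses as L
from .data import LabeledImageSet, BatchPlan, iterate_batches, _balanced_choice
from .evaluation import auc_any
from .networks import (GeneratorSpec, DiscriminatorSpec, TaskNetSpec,
                       build_generator, build_discriminator, build_task_net)
from .nn import Adam, Module, Tensor, cross_entropy
from .nn import autograd as ag

__all__ = [
    "ClassifierConfig", "AdaptationConfig", "ModelBundle", "EarlyStopper",
    "train_classifier", "lr_schedule", "train_adaptation", "translate_set",
    "finetune_on_translated", "predict_logits", "predict_proba", "clone_net",
]


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass
class ClassifierConfig:
    """Baseline/fine-tune protocol: Adam, categorical cross-entropy,
    early stopping on validation AUC."""

    lr: float = 1e-3               # 1e-3 small CNN; 2e-4 dense head
    batch_size: int = 128          # 128 small CNN; 50 dense head
    max_epochs: int = 200
    patience: int = 10             # epochs of no val-AUC improvement
    weight_decay: float = 0.0      # 5e-4 for the dense head
    betas: tuple = (0.9, 0.999)
    augment: bool = False          # random flips/rotations/translations
    balance_by_class: bool = False

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class AdaptationConfig:
    """Adversarial adaptation schedule (per-iteration = one generator step)."""

    total_iters: int = 3000        # paper scale: 200_000
    batch_size: int = 32           # paper scale: 200 (digits) / 20 (radiographs)
    n_critic: int = 5              # critic updates per generator update
    task_update_period: int = 1    # 10 for unstable pairs
    lr: float = 1e-4               # linearly decayed to 0 over the second half
    betas: tuple = (0.5, 0.999)
    weights: L.LossWeights = field(default_factory=L.LossWeights)
    adv_mode: str = "wgan_gp"      # or 'saturating' (reference objective)
    balance_by_class: bool = False
    gen_base: int = 16
    n_res: int = 4
    disc_base: int = 16
    disc_layers: int = 6           # auto-reduced for small images

    def __post_init__(self):
        if min(self.total_iters, self.batch_size, self.n_critic,
               self.task_update_period) < 0 or self.batch_size < 2:
            raise ValueError("counts must be positive (batch_size >= 2)")
        if self.adv_mode not in ("wgan_gp", "saturating"):
            raise ValueError("adv_mode must be 'wgan_gp' or 'saturating'")


@dataclass
class ModelBundle:
    """Parameter sets produced by adaptation."""

    generator: Module
    discriminator: Module
    f_s: Module
    f_t: Module
    n_domains: int
    source_domain: int
    target_domain: int


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

@contextlib.contextmanager
def _frozen(*modules):
    """Temporarily mark parameters non-differentiable (skips their weight
    gradients during backward; forward is unchanged)."""
    saved = []
    for m in modules:
        for p in m.parameters():
            saved.append((p, p.requires_grad))
            p.requires_grad = False
    try:
        yield
    finally:
        for p, f in saved:
            p.requires_grad = f


def _check_finite(value: float, name: str, iteration: int) -> float:
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite {name} at iteration {iteration}")
    return float(value)


def clone_net(net: Module) -> Module:
    """Fresh network with the same spec and a copy of the weights."""
    new = build_task_net(net.spec)
    new.load_state_dict(net.state_dict())
    return new


def predict_logits(net: Module, images: np.ndarray, batch: int = 512) -> np.ndarray:
    """Eval-mode logits for (n, H, W, C) images in [-1, 1]."""
    was_training = net.training
    net.eval()
    nchw = np.ascontiguousarray(np.asarray(images).transpose(0, 3, 1, 2))
    outs = []
    with ag.no_grad():
        for i in range(0, len(nchw), batch):
            outs.append(net(nchw[i:i + batch]).data)
    net.train(was_training)
    return np.concatenate(outs)


def predict_proba(net: Module, images: np.ndarray, batch: int = 512) -> np.ndarray:
    z = predict_logits(net, images, batch)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _augment_batch(x: np.ndarray, rng) -> np.ndarray:
    """Random horizontal flips, small rotations and integer translations."""
    out = x.copy()
    for i in range(len(out)):
        if rng.random() < 0.5:
            out[i] = out[i, :, ::-1]
        ang = rng.uniform(-10, 10)
        out[i] = ndimage.rotate(out[i], ang, axes=(0, 1), reshape=False,
                                order=1, mode="nearest")
        dy, dx = rng.integers(-2, 3, size=2)
        out[i] = np.roll(out[i], (dy, dx), axis=(0, 1))
    return out


class EarlyStopper:
    """Stop after `patience` consecutive updates without improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -np.inf
        self.since = 0
        self.improved = False

    def update(self, metric: float) -> bool:
        """Record a metric; returns True when training should stop."""
        self.improved = metric > self.best
        if self.improved:
            self.best = metric
            self.since = 0
        else:
            self.since += 1
        return self.since >= self.patience


# ---------------------------------------------------------------------------
# Baseline classifier training
# ---------------------------------------------------------------------------

@dataclass
class ClassifierFit:
    net: Module
    history: pd.DataFrame
    best_val_auc: float
    best_epoch: int


def train_classifier(train: LabeledImageSet, val: LabeledImageSet,
                     cfg: ClassifierConfig | None = None, seed: int = 0,
                     net: Module | None = None,
                     spec: TaskNetSpec | None = None) -> ClassifierFit:
    """Train (or continue training) a task network with early stopping.

    Returns the checkpoint with the best validation AUC and a per-epoch
    history of training loss and validation AUC.
    """
    cfg = cfg or ClassifierConfig()
    if len(np.unique(val.class_labels)) < 2:
        raise ValueError("validation AUC undefined: single-class validation set")
    ss = np.random.SeedSequence(seed).spawn(2)
    init_rng, data_rng = (np.random.default_rng(s) for s in ss)
    if net is None:
        n_classes = int(max(train.class_labels.max(), val.class_labels.max())) + 1
        spec = spec or TaskNetSpec(n_classes=n_classes,
                                   image_size=train.images.shape[1],
                                   in_channels=train.images.shape[3])
        net = build_task_net(spec, init_rng)
    opt = Adam(net.parameters(), lr=cfg.lr, betas=cfg.betas,
               weight_decay=cfg.weight_decay)
    x_all = train.to_nchw()
    y_all = train.class_labels
    stopper = EarlyStopper(cfg.patience)
    best_state = net.state_dict()
    best_epoch = -1
    rows = []
    for epoch in range(cfg.max_epochs):
        net.train()
        if cfg.balance_by_class:
            order = np.concatenate([_balanced_choice(data_rng, y_all, cfg.batch_size)
                                    for _ in range(max(1, len(y_all) // cfg.batch_size))])
        else:
            order = data_rng.permutation(len(y_all))
        total, seen = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = x_all[idx]
            if cfg.augment:
                xb = _augment_batch(xb, data_rng)
            loss = cross_entropy(net(xb), y_all[idx])
            net.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item() * len(idx)
            seen += len(idx)
        train_loss = _check_finite(total / seen, "train loss", epoch)
        val_auc = auc_any(predict_proba(net, val.images), val.class_labels)
        rows.append({"epoch": epoch, "train_loss": train_loss, "val_auc": val_auc,
                     "lr": cfg.lr})
        stop = stopper.update(val_auc)
        if stopper.improved:
            best_state = net.state_dict()
            best_epoch = epoch
        if stop:
            break
    net.load_state_dict(best_state)
    net.eval()
    return ClassifierFit(net, pd.DataFrame(rows),
                         float(stopper.best) if best_epoch >= 0 else float("nan"),
                         best_epoch)


# ---------------------------------------------------------------------------
# Adaptation
# ---------------------------------------------------------------------------

def lr_schedule(iteration: int, cfg: AdaptationConfig) -> float:
    """Constant for the first half of training, then linear decay to zero."""
    if not 0 <= iteration <= cfg.total_iters:
        raise ValueError(f"iteration {iteration} outside [0, {cfg.total_iters}]")
    half = cfg.total_iters / 2.0
    if iteration <= half:
        return cfg.lr
    return cfg.lr * (1.0 - (iteration - half) / half)


def train_adaptation(source: LabeledImageSet, target_images: np.ndarray,
                     target_domain: int, f_s: Module,
                     cfg: AdaptationConfig | None = None, seed: int = 0,
                     gen_spec: GeneratorSpec | None = None,
                     disc_spec: DiscriminatorSpec | None = None,
                     checkpoint_fn=None, checkpoint_every: int = 0):
    """Adversarial adaptation between a labeled source set and unlabeled
    target images.

    Per generator step the critic is updated ``n_critic`` times on fresh
    mixed batches (Wasserstein + gradient penalty + domain classification),
    then the generator once (adversarial + domain classification + cycle +
    semantic), and the target task net F_T per ``task_update_period``.
    Returns (ModelBundle, history DataFrame).
    """
    cfg = cfg or AdaptationConfig()
    target_images = np.asarray(target_images, dtype=np.float32)
    src_domain = int(source.domain_labels[0])
    n_domains = max(src_domain, target_domain) + 1
    H = source.images.shape[1]
    gen_spec = gen_spec or GeneratorSpec(image_size=H, base_channels=cfg.gen_base,
                                         n_res=cfg.n_res, n_domains=n_domains)
    disc_spec = disc_spec or DiscriminatorSpec(image_size=H, base_channels=cfg.disc_base,
                                               n_conv=cfg.disc_layers,
                                               n_domains=n_domains)
    ss = np.random.SeedSequence(seed).spawn(4)
    init_rng, data_rng, alpha_rng, _ = (np.random.default_rng(s) for s in ss)

    g = build_generator(gen_spec, init_rng)
    d = build_discriminator(disc_spec, init_rng)
    f_t = clone_net(f_s)
    for p in f_s.parameters():           # frozen weak supervisor
        p.requires_grad = False
    f_s.eval()
    f_t.eval()                           # fine-tuning uses eval-mode statistics

    opt_g = Adam(g.parameters(), lr=cfg.lr, betas=cfg.betas)
    opt_d = Adam(d.parameters(), lr=cfg.lr, betas=cfg.betas)
    opt_t = Adam(f_t.parameters(), lr=cfg.lr, betas=cfg.betas)

    plan = BatchPlan(cfg.batch_size, balance_by_class=cfg.balance_by_class,
                     even_domain_split=True,
                     seed=int(data_rng.integers(0, 2 ** 31)))
    batches = iterate_batches(source, target_images, plan)
    w = cfg.weights
    history: list[dict] = []

    def mixed(batch):
        x = np.concatenate([batch.src_images, batch.tgt_images]).transpose(0, 3, 1, 2)
        dom = np.concatenate([batch.src_domains,
                              np.full(len(batch.tgt_images), target_domain)])
        return np.ascontiguousarray(x), dom.astype(np.int64)

    for it in range(cfg.total_iters):
        lr = lr_schedule(it, cfg)
        opt_g.lr = opt_d.lr = opt_t.lr = lr

        # ---- critic updates (fresh batch each) -----------------------------
        # G is frozen during the critic updates, so all fake batches come
        # from one big generator pass (per-sample ops: results identical)
        crit = [mixed(next(batches)) for _ in range(cfg.n_critic)]
        dom_fakes = [np.where(dr == src_domain, target_domain, src_domain)
                     for _, dr in crit]
        with ag.no_grad():
            fakes_all = g(np.concatenate([xr for xr, _ in crit]),
                          np.concatenate(dom_fakes)).data
        sizes = np.cumsum([len(xr) for xr, _ in crit])[:-1]
        fakes = np.split(fakes_all, sizes)
        for j in range(cfg.n_critic):
            x_real, dom_real = crit[j]
            x_fake = fakes[j]
            B = len(x_real)
            d.zero_grad()
            # one critic pass over [real; fake]
            maps, cls_logits = d(np.concatenate([x_real, x_fake]))
            scores = maps.mean(axis=(1, 2, 3))
            s_real = ag.narrow(scores, 0, B)
            s_fake = ag.narrow(scores, B, 2 * B)
            cls_real = L.cls_loss_real(ag.narrow(cls_logits, 0, B), dom_real)
            if cfg.adv_mode == "wgan_gp":
                gp, x_hat, grad, norms = L.gradient_penalty_parts(
                    d, x_real, x_fake, alpha_rng)
                adv = L.adv_loss_wgan(s_real, s_fake, gp, w.gp)
                loss_d = L.discriminator_objective(adv, cls_real, w)
                loss_d.backward()
                L.gp_parameter_gradients(d, x_hat, grad, norms, w.gp)
                gp_val = gp
            else:
                p_real = ag.sigmoid(s_real)
                p_fake = ag.sigmoid(s_fake)
                adv = L.adv_loss_saturating(p_real, p_fake)
                loss_d = L.discriminator_objective(adv, cls_real, w)
                loss_d.backward()
                gp_val = 0.0
            opt_d.step()
            history.append({
                "iter": it, "phase": "critic", "critic_step": j,
                "adv": _check_finite(adv.item(), "adversarial loss", it),
                "gp": _check_finite(gp_val, "gradient penalty", it),
                "cls_real": _check_finite(cls_real.item(), "domain NLL (real)", it),
                "loss": _check_finite(loss_d.item(), "critic objective", it),
                "lr": lr,
            })

        # ---- generator update ---------------------------------------------
        b = next(batches)
        x_s = np.ascontiguousarray(b.src_images.transpose(0, 3, 1, 2))
        x_t = np.ascontiguousarray(b.tgt_images.transpose(0, 3, 1, 2))
        y_s = b.src_classes
        c_src = np.full(len(x_s), src_domain)
        c_tgt_s = np.full(len(x_s), target_domain)
        c_src_t = np.full(len(x_t), src_domain)
        c_tgt_t = np.full(len(x_t), target_domain)

        ns, nt = len(x_s), len(x_t)
        g.zero_grad()
        with _frozen(d, f_t):
            # one pass translates source->target and target->source
            fake_all = g(Tensor(np.concatenate([x_s, x_t])),
                         np.concatenate([c_tgt_s, c_src_t]))
            fake_t = ag.narrow(fake_all, 0, ns)        # source in target style
            fake_s = ag.narrow(fake_all, ns, ns + nt)  # target in source style
            smap, cls_logits = d(fake_all)
            adv_g = -smap.mean()
            cls_fake = L.cls_loss_real(cls_logits, np.concatenate([c_tgt_s, c_src_t]))
            # one pass for both cycle reconstructions and the Eq-7 third term
            second = g(ag.concat([fake_all, Tensor(x_t)], axis=0),
                       np.concatenate([c_src, c_tgt_t, c_tgt_t]))
            recon_s = ag.narrow(second, 0, ns)
            recon_t = ag.narrow(second, ns, ns + nt)
            trans_t = ag.narrow(second, ns + nt, ns + 2 * nt)
            cyc = 0.5 * ((Tensor(x_s) - recon_s).abs().mean()
                         + (Tensor(x_t) - recon_t).abs().mean())
            with ag.no_grad():
                pseudo = np.argmax(f_t(x_t).data, axis=1)
            sem = (L.task_loss(f_t, fake_t, y_s)
                   + L.task_loss(f_s, recon_s, y_s)
                   + L.task_loss(f_s, trans_t, pseudo))
            loss_g = L.generator_objective(adv_g, cls_fake, cyc, sem, w)
            loss_g.backward()
        opt_g.step()
        history.append({
            "iter": it, "phase": "generator",
            "adv": _check_finite(adv_g.item(), "generator adversarial term", it),
            "cls_fake": _check_finite(cls_fake.item(), "domain NLL (fake)", it),
            "cyc": _check_finite(cyc.item(), "cycle loss", it),
            "sem": _check_finite(sem.item(), "semantic loss", it),
            "loss": _check_finite(loss_g.item(), "generator objective", it),
            "lr": lr,
        })

        # ---- target task-net update ----------------------------------------
        if it % cfg.task_update_period == 0:
            f_t.zero_grad()
            t_loss = cross_entropy(f_t(fake_t.detach()), y_s)
            t_loss.backward()
            opt_t.step()
            history.append({
                "iter": it, "phase": "task",
                "task_loss": _check_finite(t_loss.item(), "task loss", it),
                "lr": lr,
            })

        if checkpoint_fn is not None and checkpoint_every and \
                (it + 1) % checkpoint_every == 0:
            checkpoint_fn(it + 1, ModelBundle(g, d, f_s, f_t, n_domains,
                                              src_domain, target_domain))

    bundle = ModelBundle(g, d, f_s, f_t, n_domains, src_domain, target_domain)
    return bundle, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# Translate-then-fine-tune
# ---------------------------------------------------------------------------

def translate_set(g: Module, dataset: LabeledImageSet, target_c: int,
                  batch: int = 256) -> LabeledImageSet:
    """Replace every image by G(x, target_c); class labels carry over, domain
    labels become ``target_c``."""
    nchw = dataset.to_nchw()
    outs = []
    with ag.no_grad():
        for i in range(0, len(nchw), batch):
            codes = np.full(len(nchw[i:i + batch]), target_c)
            outs.append(g(nchw[i:i + batch], codes).data)
    images = np.clip(np.concatenate(outs).transpose(0, 2, 3, 1), -1.0, 1.0)
    man = dataset.manifest.copy()
    if len(man):
        man["domain"] = target_c
    return LabeledImageSet(images.astype(np.float32), dataset.class_labels.copy(),
                           np.full(len(dataset), target_c), man)


def finetune_on_translated(f_s: Module, translated: LabeledImageSet,
                           val: LabeledImageSet,
                           cfg: ClassifierConfig | None = None,
                           seed: int = 0) -> ClassifierFit:
    """Fine-tune a copy of the source classifier on translated images.

    Starts from F_S's weights; same optimizer and early-stopping protocol as
    baseline training.  With ``max_epochs=0`` the returned network is an
    exact copy of F_S.
    """
    cfg = cfg or ClassifierConfig()
    net = clone_net(f_s)
    if cfg.max_epochs == 0:
        net.eval()
        return ClassifierFit(net, pd.DataFrame(), float("nan"), -1)
    return train_classifier(translated, val, cfg, seed=seed, net=net)
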