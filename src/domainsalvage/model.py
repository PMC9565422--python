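"""Model/Results interface over the training procedures.

Two model classes follow the fit-then-results convention of statistical
modelling packages: :class:`BaselineClassifier` trains a task network on one
domain, and :class:`DomainAdaptation` fits the conditional translation GAN
between a labeled source domain and *unlabeled* target images.  Each
``fit()`` returns a results object carrying the fitted parameters, the
training history, evaluation helpers and a ``summary()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import train as T
from .data import LabeledImageSet
from .evaluation import EvalReport, auc_any, evaluate_scores
from .networks import TaskNetSpec
from .nn import Module

__all__ = ["BaselineClassifier", "ClassifierResults",
           "DomainAdaptation", "AdaptationResults"]


class BaselineClassifier:
    """Supervised task-network model for a single domain.

    Parameters
    ----------
    train, val : LabeledImageSet
        Disjoint training and validation splits.
    config : ClassifierConfig, optional
        Optimization protocol (Adam, cross-entropy, early stopping on
        validation AUC).
    spec : TaskNetSpec, optional
        Architecture; inferred from the data when omitted.
    """

    def __init__(self, train: LabeledImageSet, val: LabeledImageSet,
                 config: T.ClassifierConfig | None = None,
                 spec: TaskNetSpec | None = None):
        self.train_set = train
        self.val_set = val
        self.config = config or T.ClassifierConfig()
        self.spec = spec

    @classmethod
    def from_dataset(cls, dataset: LabeledImageSet, split_spec=None, **kw):
        from .data import split_dataset
        tr, va, te = split_dataset(dataset, split_spec)
        model = cls(tr, va, **kw)
        model.test_set = te
        return model

    def fit(self, seed: int = 0) -> "ClassifierResults":
        fit = T.train_classifier(self.train_set, self.val_set, self.config,
                                 seed=seed, spec=self.spec)
        return ClassifierResults(self, fit, seed)


class ClassifierResults:
    """Fitted classifier: predictions, bootstrap evaluation, summary."""

    def __init__(self, model, fit: T.ClassifierFit, seed: int):
        self.model = model
        self.net: Module = fit.net
        self.history: pd.DataFrame = fit.history
        self.best_val_auc = fit.best_val_auc
        self.best_epoch = fit.best_epoch
        self.seed = seed

    def predict_proba(self, images) -> np.ndarray:
        images = images.images if isinstance(images, LabeledImageSet) else images
        return T.predict_proba(self.net, images)

    def auc(self, test_set: LabeledImageSet) -> float:
        return auc_any(self.predict_proba(test_set), test_set.class_labels)

    def evaluate(self, test_set: LabeledImageSet, n_rep: int = 1000,
                 rep_size: int = 1000, seed: int = 0,
                 baseline_auc: float | None = None,
                 internal_auc: float | None = None,
                 with_calibration: bool = False) -> EvalReport:
        scores = self.predict_proba(test_set)
        if scores.shape[1] == 2:
            scores_for_eval = scores[:, 1]
        else:
            scores_for_eval = scores
        return evaluate_scores(scores_for_eval, test_set.class_labels,
                               n_rep, rep_size, rng=seed,
                               baseline_auc=baseline_auc,
                               internal_auc=internal_auc,
                               with_calibration=with_calibration)

    def summary(self) -> str:
        n_epochs = len(self.history)
        return (f"Task network ({type(self.net).__name__}, "
                f"{self.net.n_parameters():,} parameters)\n"
                f"trained {n_epochs} epochs (best epoch {self.best_epoch}), "
                f"best validation AUC {self.best_val_auc:.4f}\n"
                f"seed {self.seed}")


class DomainAdaptation:
    """Unsupervised adversarial adaptation model.

    Built from a labeled source set, *unlabeled* target images and a fitted
    source classifier.  Target class labels are stripped at construction:
    the model object never holds them, so no code path downstream of
    ``fit()`` can read them.

    Parameters
    ----------
    source : LabeledImageSet
        Labeled source-domain training images.
    target : LabeledImageSet or array
        Target-domain images; any class labels are discarded here.
    source_results : ClassifierResults or Module
        The fitted source task network F_S.
    config : AdaptationConfig, optional
    source_val : LabeledImageSet, optional
        Source validation split; its translation provides the fine-tuning
        validation set (target labels may not be used for that purpose).
    """

    def __init__(self, source: LabeledImageSet, target,
                 source_results, config: T.AdaptationConfig | None = None,
                 source_val: LabeledImageSet | None = None,
                 target_domain: int | None = None):
        self.source = source
        if isinstance(target, LabeledImageSet):
            self.target_images = target.images.copy()
            if target_domain is None:
                target_domain = int(target.domain_labels[0])
        else:
            self.target_images = np.asarray(target, dtype=np.float32)
            if target_domain is None:
                raise ValueError("target_domain required when target is a bare array")
        self.target_domain = target_domain
        self.f_s = source_results.net if isinstance(source_results, ClassifierResults) \
            else source_results
        self.config = config or T.AdaptationConfig()
        self.source_val = source_val

    def fit(self, seed: int = 0) -> "AdaptationResults":
        bundle, history = T.train_adaptation(
            self.source, self.target_images, self.target_domain, self.f_s,
            self.config, seed=seed)
        return AdaptationResults(self, bundle, history, seed)


class AdaptationResults:
    """Fitted adaptation: translation, fine-tuning, diagnostics."""

    def __init__(self, model: DomainAdaptation, bundle: T.ModelBundle,
                 history: pd.DataFrame, seed: int):
        self.model = model
        self.bundle = bundle
        self.history = history
        self.seed = seed

    @property
    def generator(self):
        return self.bundle.generator

    @property
    def target_task_net(self):
        return self.bundle.f_t

    def translate(self, dataset: LabeledImageSet,
                  domain: int | None = None) -> LabeledImageSet:
        domain = self.model.target_domain if domain is None else domain
        return T.translate_set(self.bundle.generator, dataset, domain)

    def finetune(self, cfg: T.ClassifierConfig | None = None,
                 seed: int = 0) -> ClassifierResults:
        """Translate the source train/val splits into the target domain and
        fine-tune a copy of F_S on them."""
        translated = self.translate(self.model.source)
        if self.model.source_val is not None:
            val = self.translate(self.model.source_val)
        else:  # fall back to a held-out slice of the translated train set
            n = len(translated)
            k = max(2, n // 10)
            val, translated = translated.subset(np.arange(k)), \
                translated.subset(np.arange(k, n))
        fit = T.finetune_on_translated(self.bundle.f_s, translated, val,
                                       cfg, seed=seed)
        stub = BaselineClassifier(translated, val, cfg)
        return ClassifierResults(stub, fit, seed)

    def loss_table(self) -> pd.DataFrame:
        """Mean of each loss component over the last tenth of training."""
        h = self.history
        if not len(h):
            return pd.DataFrame()
        tail = h[h["iter"] >= h["iter"].max() * 0.9]
        return tail.groupby("phase").mean(numeric_only=True)

    def summary(self) -> str:
        h = self.history
        n_iter = int(h["iter"].max()) + 1 if len(h) else 0
        counts = h.groupby("phase").size().to_dict() if len(h) else {}
        lines = [
            "Adversarial domain adaptation "
            f"({self.model.source.domain_labels[0]} -> {self.model.target_domain})",
            f"generator {self.bundle.generator.n_parameters():,} params, "
            f"critic {self.bundle.discriminator.n_parameters():,} params",
            f"{n_iter} generator iterations "
            f"({counts.get('critic', 0)} critic / {counts.get('generator', 0)} "
            f"generator / {counts.get('task', 0)} task updates), seed {self.seed}",
        ]
        lt = self.loss_table()
        if len(lt):
            lines.append("mean losses over the final 10% of training:")
            lines.append(lt.round(4).to_string())
        return "\n".join(lines)
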