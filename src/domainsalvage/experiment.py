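"""One-command experiment harness: synthesize domains, train baselines,
adapt, fine-tune, and evaluate the four deployment strategies
(local, bespoke, global, adapted) on per-domain test sets.

Every run directory contains the exact configuration used, JSONL loss
histories, and JSON/CSV reports, so each number is traceable to a config
and a seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import train as T
from .config import RunConfig, save_config
from .data import SplitSpec, split_dataset
from .evaluation import deployment_report, evaluate_scores
from .model import BaselineClassifier, DomainAdaptation
from .networks import TaskNetSpec
from .synth import make_domains

__all__ = ["run_experiment", "global_fraction_experiment", "STAGES",
           "DEFAULT_FRACTIONS"]

STAGES = ("synth", "baselines", "adapt", "finetune", "eval")
DEFAULT_FRACTIONS = (0.001, 0.01, 0.1, 1.0)


def global_fraction_experiment(train_sets: list, val_sets: list,
                               test_sets: list, classifier_cfg,
                               task_spec=None,
                               fractions=DEFAULT_FRACTIONS,
                               seed: int = 0,
                               spread_kind: str = "population") -> pd.DataFrame:
    """Domain-spread of pooled ("global") models vs training-data amount.

    For each fraction a single model is trained on that share of the pooled
    multi-domain training data and evaluated on each per-domain test set and
    on the pooled test set.  Returns one row per fraction with per-domain
    AUCs (percent), the pooled AUC, and the inter-domain variance (spread).
    Fractions leaving fewer than two items of some class are skipped with a
    warning.
    """
    import warnings

    from .evaluation import auc_any, domain_spread

    pooled_tr = train_sets[0]
    pooled_va = val_sets[0]
    for t, v in zip(train_sets[1:], val_sets[1:]):
        pooled_tr = _concat_sets(pooled_tr, t)
        pooled_va = _concat_sets(pooled_va, v)
    pooled_te_images = np.concatenate([t.images for t in test_sets])
    pooled_te_labels = np.concatenate([t.class_labels for t in test_sets])
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        n = int(round(frac * len(pooled_tr)))
        idx = rng.permutation(len(pooled_tr))[:n]
        sub = pooled_tr.subset(np.sort(idx))
        counts = np.bincount(sub.class_labels,
                             minlength=int(pooled_tr.class_labels.max()) + 1)
        if len(sub) == 0 or counts.min() < 2:
            warnings.warn(f"fraction {frac} leaves too few items per class; skipped")
            continue
        from .model import BaselineClassifier
        res = BaselineClassifier(sub, pooled_va, classifier_cfg).fit(
            seed=int(rng.integers(0, 2 ** 31)))
        row = {"fraction": frac, "n_train": len(sub)}
        per_dom = []
        for d, te in enumerate(test_sets):
            a = 100.0 * auc_any(res.predict_proba(te.images), te.class_labels)
            row[f"auc_domain{d}"] = a
            per_dom.append(a)
        row["auc_pooled"] = 100.0 * auc_any(res.predict_proba(pooled_te_images),
                                            pooled_te_labels)
        row["spread"] = domain_spread(per_dom, spread_kind)
        rows.append(row)
    return pd.DataFrame(rows)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(type(o).__name__)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def run_experiment(cfg: RunConfig, out_dir, seed: int | None = None,
                   dry_run: bool = False, log=print) -> dict:
    """Execute the full pipeline; returns a dict of result artifacts.

    Stages: synth -> per-domain baselines -> adaptation (source -> target)
    -> translate + fine-tune -> deployment evaluation.  On stage failure a
    ``FAILED_<stage>`` marker naming the stage is left in the run directory.
    """
    seed = cfg.seed if seed is None else seed
    out = Path(out_dir)
    if dry_run:
        log(f"dry run: config OK; stages: {' -> '.join(STAGES)}")
        log(f"domains: {[s.name for s in cfg.styles]}, task {cfg.task.task}, "
            f"{cfg.task.n_per_domain}/domain, pair {cfg.source_domain}->{cfg.target_domain}, "
            f"{cfg.adaptation.total_iters} adaptation iterations, seed {seed}")
        return {"dry_run": True}
    out.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out / "config.yaml")
    (out / "seed.txt").write_text(str(seed))
    ss = np.random.SeedSequence(seed)
    s_data, s_base, s_adapt, s_ft, s_eval = (int(s.generate_state(1)[0] % 2**31)
                                             for s in ss.spawn(5))
    stage = "synth"
    try:
        log(f"[synth] generating {len(cfg.styles)} domains "
            f"({cfg.task.task}, {cfg.task.n_per_domain}/domain)")
        task = cfg.task
        task.seed = s_data
        domains = make_domains(task, cfg.styles)
        splits = [split_dataset(d, SplitSpec(seed=cfg.split_seed)) for d in domains]

        stage = "baselines"
        results = {}
        spec = cfg.task_net or TaskNetSpec(n_classes=task.n_classes,
                                           image_size=task.image_size)
        for d, (tr, va, te) in enumerate(splits):
            log(f"[baselines] domain {d} ({cfg.styles[d].name})")
            res = BaselineClassifier(tr, va, cfg.classifier, spec).fit(seed=s_base + d)
            results[d] = res
            res.history.to_json(out / f"history_baseline_{d}.jsonl",
                                orient="records", lines=True)
        src, tgt = cfg.source_domain, cfg.target_domain
        internal = 100.0 * results[tgt].auc(splits[tgt][2])
        external = 100.0 * results[src].auc(splits[tgt][2])

        stage = "adapt"
        log(f"[adapt] {src} -> {tgt}, {cfg.adaptation.total_iters} iterations")
        adapt = DomainAdaptation(splits[src][0], splits[tgt][0].images,
                                 results[src], cfg.adaptation,
                                 source_val=splits[src][1],
                                 target_domain=tgt).fit(seed=s_adapt)
        adapt.history.to_json(out / "history_adaptation.jsonl",
                              orient="records", lines=True)

        stage = "finetune"
        log("[finetune] translate source and fine-tune F_S")
        adapted = adapt.finetune(cfg.classifier, seed=s_ft)

        stage = "eval"
        log("[eval] deployment report")
        test_sets = {f"domain{d}": splits[d][2] for d in range(len(splits))}
        pooled_train = splits[0][0]  # global model trains on all domains pooled
        for d in range(1, len(splits)):
            pooled_train = _concat_sets(pooled_train, splits[d][0])
        pooled_val = splits[0][1]
        for d in range(1, len(splits)):
            pooled_val = _concat_sets(pooled_val, splits[d][1])
        log("[eval] global (pooled) baseline")
        global_res = BaselineClassifier(pooled_train, pooled_val,
                                        cfg.classifier, spec).fit(seed=s_base + 97)
        if len(cfg.global_fractions) > 1:
            log("[eval] global-model data-fraction sweep")
            frac_table = global_fraction_experiment(
                [s[0] for s in splits], [s[1] for s in splits],
                [s[2] for s in splits], cfg.classifier,
                fractions=cfg.global_fractions, seed=s_base + 131)
            frac_table.to_csv(out / "global_fractions.csv", index=False)
        models = {f"bespoke_domain{d}": results[d].predict_proba
                  for d in range(len(splits))}
        models["local_source"] = results[src].predict_proba
        models["global"] = global_res.predict_proba
        models["adapted"] = adapted.predict_proba
        report = deployment_report(models, test_sets)
        report.table.to_csv(out / "deployment_auc.csv")
        report.spread.to_csv(out / "domain_spread.csv")

        rng_eval = np.random.default_rng(s_eval)
        scores = adapted.predict_proba(splits[tgt][2])
        if scores.shape[1] == 2:
            scores = scores[:, 1]
        adapted_report = evaluate_scores(
            scores, splits[tgt][2].class_labels, cfg.n_boot, cfg.rep_size,
            rng=rng_eval, baseline_auc=external, internal_auc=internal,
            with_calibration=True)
        _write_json(out / "adapted_report.json", adapted_report.to_dict())
        if adapted_report.calibration is not None:
            adapted_report.calibration.to_csv(out / "calibration.csv", index=False)
        summary = {
            "internal_auc": internal, "external_auc": external,
            "adapted_auc": adapted_report.auc_point,
            "salvage": adapted_report.salvage,
            "rel_change": adapted_report.rel_change,
            "abs_change": adapted_report.abs_change,
            "seed": seed,
        }
        _write_json(out / "summary.json", summary)
        log(f"[done] internal {internal:.2f}% external {external:.2f}% "
            f"adapted {adapted_report.auc_point:.2f}%"
            + (f" salvage {adapted_report.salvage:.1f}%"
               if adapted_report.salvage is not None else ""))
        return {"summary": summary, "deployment": report, "adapt": adapt,
                "adapted": adapted, "baselines": results, "splits": splits}
    except Exception:
        (out / f"FAILED_{stage}").write_text(stage)
        raise


def _concat_sets(a, b):
    from .data import LabeledImageSet
    man = pd.concat([a.manifest, b.manifest], ignore_index=True) \
        if len(a.manifest) and len(b.manifest) else pd.DataFrame()
    return LabeledImageSet(np.concatenate([a.images, b.images]),
                           np.concatenate([a.class_labels, b.class_labels]),
                           np.concatenate([a.domain_labels, b.domain_labels]), man)
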