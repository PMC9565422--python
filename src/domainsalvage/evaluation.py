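"""Deployment-evaluation metrics.

AUC is the rank-based (Mann-Whitney) statistic with average ranks for ties;
multiclass problems use a macro-averaged one-vs-rest reduction.  Confidence
intervals are percentile bootstrap over replicates drawn with replacement.
``salvage`` expresses how much of the internal-to-external AUC gap an
adapted model recovers; ``domain_spread`` is the inter-domain variance of a
single model's per-domain AUCs, an a priori fragility indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "auc", "auc_multiclass", "bootstrap_ci", "BootstrapAUC", "salvage",
    "relative_change", "domain_spread", "calibration_curve", "EvalReport",
    "evaluate_scores", "deployment_report", "DeploymentReport",
]


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC for binary labels, ties averaged."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)
    return (ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def auc_multiclass(score_matrix, labels, average: str = "macro") -> float:
    """One-vs-rest AUC over an (n, N) score matrix; macro (default) averages
    the per-class AUCs, micro pools all one-vs-rest decisions."""
    s = np.asarray(score_matrix, dtype=np.float64)
    y = np.asarray(labels)
    classes = np.arange(s.shape[1])
    if average == "macro":
        # macro over classes with both positives and negatives present
        per = [auc(s[:, c], (y == c).astype(int)) for c in classes
               if 0 < (y == c).sum() < len(y)]
        if not per:
            raise ValueError("AUC requires at least two classes present")
        return float(np.mean(per))
    if average == "micro":
        flat_scores = s.ravel()
        flat_labels = (y[:, None] == classes[None, :]).astype(int).ravel()
        return auc(flat_scores, flat_labels)
    raise ValueError("average must be 'macro' or 'micro'")


def auc_any(scores, labels) -> float:
    """Dispatch: 1-d scores -> binary AUC; 2-d score matrix -> macro OVR."""
    scores = np.asarray(scores)
    if scores.ndim == 1:
        return auc(scores, labels)
    if scores.shape[1] == 2:
        return auc(scores[:, 1], labels)
    return auc_multiclass(scores, labels)


@dataclass
class BootstrapAUC:
    point: float
    low: float
    high: float
    n_replicates: int
    replicate_size: int
    n_resampled: int = 0        # replicates redrawn for missing a class


def bootstrap_ci(scores, labels, n_rep: int = 1000, rep_size: int = 1000,
                 alpha: float = 0.05, rng=None) -> BootstrapAUC:
    """Percentile bootstrap CI for the AUC.

    Replicates are drawn with replacement at ``rep_size`` (capped at the test
    set size, with a warning).  A replicate missing a class is redrawn and
    counted in ``n_resampled``.
    """
    rng = np.random.default_rng(rng)
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    n = len(labels)
    if n == 0:
        raise ValueError("empty test set")
    if rep_size > n:
        warnings.warn(f"replicate size {rep_size} capped at test-set size {n}")
        rep_size = n
    point = auc_any(scores, labels)
    binary = scores.ndim == 1 or scores.shape[1] == 2
    s1 = scores if scores.ndim == 1 else scores[:, 1]
    if binary and len(np.unique(s1)) == n:
        # all score values distinct: replicate ties can only be self-duplicates
        # (same item, same label), for which ordinal ranks give the identical
        # AUC as average ranks — so replicate AUCs vectorize exactly
        reps, n_resampled = _bootstrap_replicates_vectorized(
            s1, labels, n_rep, rep_size, rng)
    else:
        reps = np.empty(n_rep)
        n_resampled = 0
        for r in range(n_rep):
            # a replicate must contain at least two classes (multiclass
            # replicates macro-average over the classes they contain)
            for _ in range(1000):
                idx = rng.integers(0, n, rep_size)
                if len(np.unique(labels[idx])) >= 2:
                    break
                n_resampled += 1
            else:
                raise RuntimeError("could not draw a replicate containing two classes")
            reps[r] = auc_any(scores[idx], labels[idx])
    low, high = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return BootstrapAUC(point, float(low), float(high), n_rep, rep_size, n_resampled)


def _bootstrap_replicates_vectorized(scores, labels, n_rep, rep_size, rng):
    n = len(labels)
    labels01 = (labels == 1)
    idx = rng.integers(0, n, (n_rep, rep_size))
    n_resampled = 0
    for _ in range(1000):
        y = labels01[idx]
        n1 = y.sum(axis=1)
        bad = (n1 == 0) | (n1 == rep_size)
        if not bad.any():
            break
        n_resampled += int(bad.sum())
        idx[bad] = rng.integers(0, n, (int(bad.sum()), rep_size))
    else:
        raise RuntimeError("could not draw a replicate containing two classes")
    s = scores[idx]
    order = np.argsort(s, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order,
                      np.broadcast_to(np.arange(1, rep_size + 1), s.shape), axis=1)
    rsum = (ranks * y).sum(axis=1)
    return (rsum - n1 * (n1 + 1) / 2.0) / (n1 * (rep_size - n1)), n_resampled


def salvage(internal: float, external: float, adapted: float) -> float:
    """Percent of the internal-to-external AUC gap recovered by adaptation:
    100 * (adapted - external) / (internal - external)."""
    if internal <= external:
        raise ValueError("salvage undefined: internal AUC must exceed external AUC")
    return 100.0 * (adapted - external) / (internal - external)


def relative_change(baseline: float, other: float) -> float:
    """Percent change of `other` relative to `baseline`; negative = loss."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (other - baseline) / baseline


def domain_spread(per_domain_aucs, kind: str = "population") -> float:
    """Inter-domain variance of per-domain AUCs (percent units by convention)."""
    v = np.asarray(per_domain_aucs, dtype=np.float64)
    if len(v) < 2:
        raise ValueError("domain spread needs at least 2 domains")
    ddof = {"population": 0, "sample": 1}[kind]
    return float(np.var(v, ddof=ddof))


def calibration_curve(probs, labels, n_bins: int = 10) -> pd.DataFrame:
    """Equal-width reliability table over [0, 1].

    Columns: bin_low, bin_high, mean_pred, frac_pos (NaN when empty), count.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(probs, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = which == b
        cnt = int(m.sum())
        rows.append({
            "bin_low": edges[b], "bin_high": edges[b + 1],
            "mean_pred": probs[m].mean() if cnt else np.nan,
            "frac_pos": labels[m].mean() if cnt else np.nan,
            "count": cnt,
        })
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """AUC with bootstrap CI plus the derived deployment metrics (percent)."""

    auc_point: float
    ci_low: float
    ci_high: float
    n_replicates: int
    replicate_size: int
    n: int
    salvage: float | None = None
    rel_change: float | None = None
    abs_change: float | None = None
    calibration: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [f"AUC {self.auc_point:.2f}% (95% CI {self.ci_low:.2f}-{self.ci_high:.2f}%, "
                 f"n={self.n}, {self.n_replicates} bootstrap replicates of size "
                 f"{self.replicate_size})"]
        if self.abs_change is not None:
            lines.append(f"absolute change {self.abs_change:+.2f} percentage points")
        if self.rel_change is not None:
            lines.append(f"relative change {self.rel_change:+.2f}%")
        if self.salvage is not None:
            lines.append(f"salvage {self.salvage:.1f}% of the internal-external gap")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("auc_point", "ci_low", "ci_high", "n_replicates", "replicate_size",
              "n", "salvage", "rel_change", "abs_change")}
        return d


def evaluate_scores(scores, labels, n_rep: int = 1000, rep_size: int = 1000,
                    rng=None, baseline_auc: float | None = None,
                    internal_auc: float | None = None,
                    with_calibration: bool = False) -> EvalReport:
    """Full evaluation of one model on one test set, in percent units.

    ``baseline_auc``/``internal_auc`` (percent) unlock the change and
    salvage fields, treating the scored model as the adapted one.
    """
    bs = bootstrap_ci(scores, labels, n_rep, rep_size, rng=rng)
    pt = 100.0 * bs.point
    rep = EvalReport(pt, 100.0 * bs.low, 100.0 * bs.high, bs.n_replicates,
                     bs.replicate_size, len(np.asarray(labels)))
    if baseline_auc is not None:
        rep.abs_change = pt - baseline_auc
        rep.rel_change = relative_change(baseline_auc, pt)
        if internal_auc is not None and internal_auc > baseline_auc:
            rep.salvage = salvage(internal_auc, baseline_auc, pt)
    if with_calibration:
        s = np.asarray(scores)
        if s.ndim == 1 or s.shape[1] == 2:
            p = s if s.ndim == 1 else s[:, 1]
            rep.calibration = calibration_curve(p, labels)
    return rep


@dataclass
class DeploymentReport:
    """Per-strategy x per-domain AUC table with domain spread."""

    table: pd.DataFrame                 # rows: strategy, columns: domain + 'pooled'
    spread: pd.Series                   # per-strategy inter-domain variance
    pooled_outside_range: pd.Series     # flag: pooled AUC outside [min, max] of domains

    def summary(self) -> str:
        out = ["Deployment report (AUC %, rank-based):", self.table.round(2).to_string()]
        out.append("\nDomain spread (variance of per-domain AUC %):")
        out.append(self.spread.round(3).to_string())
        flagged = self.pooled_outside_range[self.pooled_outside_range]
        if len(flagged):
            out.append("\nNote: pooled AUC outside the per-domain range for: "
                       + ", ".join(flagged.index))
        return "\n".join(out)


def plot_calibration(calibration: pd.DataFrame, path) -> None:
    """Reliability diagram from a :func:`calibration_curve` table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(4, 4))
    occ = calibration[calibration["count"] > 0]
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=1)
    ax.plot(occ["mean_pred"], occ["frac_pos"], "o-")
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed positive fraction")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_domain_spread(table: pd.DataFrame, path) -> None:
    """Per-domain and pooled AUC against training-data fraction."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 4))
    for col in table.columns:
        if col.startswith("auc_"):
            ax.plot(table["fraction"], table[col], "o-",
                    label=col.removeprefix("auc_"))
    ax.set_xscale("log")
    ax.set_xlabel("fraction of pooled training data")
    ax.set_ylabel("AUC (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def deployment_report(models: dict, domain_test_sets: dict,
                      spread_kind: str = "population") -> DeploymentReport:
    """Evaluate each scoring strategy on each per-domain test set + the pool.

    ``models`` maps strategy name -> callable(images NHWC) -> scores;
    ``domain_test_sets`` maps domain name -> LabeledImageSet.  Missing
    evaluations are recorded as NaN.
    """
    domains = list(domain_test_sets)
    pooled_images = np.concatenate([domain_test_sets[d].images for d in domains])
    pooled_labels = np.concatenate([domain_test_sets[d].class_labels for d in domains])
    rows = {}
    for name, fn in models.items():
        row = {}
        for d in domains:
            ts = domain_test_sets[d]
            try:
                row[d] = 100.0 * auc_any(fn(ts.images), ts.class_labels)
            except Exception:
                row[d] = np.nan
        row["pooled"] = 100.0 * auc_any(fn(pooled_images), pooled_labels)
        rows[name] = row
    table = pd.DataFrame(rows).T[domains + ["pooled"]]
    per_dom = table[domains]
    spread = per_dom.apply(lambda r: domain_spread(r.dropna(), spread_kind)
                           if r.notna().sum() >= 2 else np.nan, axis=1)
    outside = (table["pooled"] < per_dom.min(axis=1)) | (table["pooled"] > per_dom.max(axis=1))
    return DeploymentReport(table, spread, outside)
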