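"""AUC, bootstrap, salvage/relative-change arithmetic, spread, calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from domainsalvage import evaluation as E
from domainsalvage.data import LabeledImageSet
from domainsalvage.data import normalize


def brute_force_auc(scores, labels):
    """Exhaustive pair enumeration with half-credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert E.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert E.auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_pair_counting_example(self):
        # concordant 3, discordant 1 out of 4 pairs
        assert E.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            E.auc([0.1, 0.2], [1, 1])

    @given(st.integers(0, 2 ** 31 - 1), st.integers(4, 12))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_exhaustive_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(n), 2)  # coarse grid provokes ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert E.auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        assert E.auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_macro_ovr_agrees_with_sklearn(self, rng):
        probs = rng.random((100, 4))
        probs /= probs.sum(axis=1, keepdims=True)
        y = rng.integers(0, 4, 100)
        assert E.auc_multiclass(probs, y) == pytest.approx(
            roc_auc_score(y, probs, multi_class="ovr", average="macro"), abs=1e-12)


class TestBootstrap:
    def test_degenerate_perfect_scores(self, rng):
        labels = np.array([0, 1] * 30)
        bs = E.bootstrap_ci(labels.astype(float), labels, n_rep=50, rep_size=60, rng=rng)
        assert (bs.point, bs.low, bs.high) == (1.0, 1.0, 1.0)

    def test_determinism_same_seed(self):
        rng = np.random.default_rng(1)
        scores, labels = rng.random(100), rng.integers(0, 2, 100)
        a = E.bootstrap_ci(scores, labels, 100, 100, rng=7)
        b = E.bootstrap_ci(scores, labels, 100, 100, rng=7)
        assert (a.low, a.high) == (b.low, b.high)

    def test_point_estimate_is_full_sample_auc(self, rng):
        scores, labels = rng.random(80), rng.integers(0, 2, 80)
        bs = E.bootstrap_ci(scores, labels, 20, 50, rng=rng)
        assert bs.point == E.auc(scores, labels)

    def test_replicate_size_capped_with_warning(self, rng):
        scores, labels = rng.random(40), rng.integers(0, 2, 40)
        with pytest.warns(UserWarning, match="capped"):
            bs = E.bootstrap_ci(scores, labels, 10, 1000, rng=rng)
        assert bs.replicate_size == 40


class TestSalvage:
    def test_paper_digit_arithmetic(self):
        assert round(E.salvage(99.87, 91.85, 94.66)) == 35

    def test_endpoints(self):
        assert E.salvage(90, 80, 80) == 0.0
        assert E.salvage(90, 80, 90) == 100.0

    def test_undefined_when_no_gap(self):
        with pytest.raises(ValueError):
            E.salvage(80, 85, 83)


class TestRelativeChange:
    def test_paper_cxr_loss(self):
        assert E.relative_change(78.07, 71.43) == pytest.approx(-8.51, abs=0.005)

    def test_equal_inputs_and_gain(self):
        assert E.relative_change(50, 50) == 0.0
        assert E.relative_change(50, 75) == pytest.approx(50.0)

    def test_requires_positive_baseline(self):
        with pytest.raises(ValueError):
            E.relative_change(0, 10)


class TestDomainSpread:
    def test_all_equal_is_zero(self):
        assert E.domain_spread([88.0, 88.0, 88.0]) == 0.0

    def test_population_variance_convention(self):
        assert E.domain_spread([80.0, 90.0]) == pytest.approx(25.0)
        assert E.domain_spread([80.0, 90.0], kind="sample") == pytest.approx(50.0)

    def test_permutation_invariant(self, rng):
        v = rng.random(5) * 100
        assert E.domain_spread(v) == pytest.approx(E.domain_spread(v[::-1]))

    def test_needs_two_domains(self):
        with pytest.raises(ValueError):
            E.domain_spread([90.0])


class TestCalibrationCurve:
    def test_counts_conserved_and_empty_bins(self, rng):
        probs = rng.uniform(0.0, 0.3, 100)
        tab = E.calibration_curve(probs, rng.integers(0, 2, 100), n_bins=10)
        assert tab["count"].sum() == 100
        assert (tab["count"].iloc[4:] == 0).all()
        assert tab["frac_pos"].iloc[4:].isna().all()

    def test_single_bin_half_probabilities(self):
        labels = np.array([0, 1] * 50)
        tab = E.calibration_curve(np.full(100, 0.5), labels)
        occ = tab[tab["count"] > 0]
        assert len(occ) == 1
        assert occ["frac_pos"].iloc[0] == pytest.approx(0.5)

    def test_calibrated_model_converges(self):
        rng = np.random.default_rng(3)
        n = 100_000
        p = rng.random(n)
        y = (rng.random(n) < p).astype(int)
        tab = E.calibration_curve(p, y)
        assert np.abs(tab["mean_pred"] - tab["frac_pos"]).max() < 0.02


class TestDeploymentReport:
    def _sets(self, rng):
        # channel d carries the label signal for domain d, other channels noise
        out = {}
        for d in range(2):
            n = 60
            labels = rng.integers(0, 2, n)
            raw = rng.random((n, 4, 4, 3)) * 0.3
            raw[:, :, :, d] = labels[:, None, None] * 0.5 + 0.2
            out[f"domain{d}"] = LabeledImageSet(
                normalize(raw).astype(np.float32), labels, np.full(n, d))
        return out

    def test_bespoke_diagonal_is_ceiling_and_spread(self, rng):
        sets = self._sets(rng)
        models = {f"bespoke_domain{d}":
                  (lambda images, d=d: images[:, :, :, d].mean(axis=(1, 2)))
                  for d in range(2)}
        rep = E.deployment_report(models, sets)
        assert rep.table.loc["bespoke_domain0", "domain0"] == pytest.approx(100.0)
        assert rep.table.loc["bespoke_domain1", "domain1"] == pytest.approx(100.0)
        assert rep.spread.loc["bespoke_domain0"] > 0
        assert list(rep.table.columns) == ["domain0", "domain1", "pooled"]

    def test_missing_domain_marked_absent(self, rng):
        sets = self._sets(rng)
        sets["domain1"] = LabeledImageSet(sets["domain1"].images,
                                          np.ones(len(sets["domain1"]), int),
                                          sets["domain1"].domain_labels)

        models = {"m": lambda images: np.linspace(0, 1, len(images))}
        rep = E.deployment_report(models, sets)
        assert np.isnan(rep.table.loc["m", "domain1"])


class TestGlobalFractionExperiment:
    def test_no_shift_spread_at_noise_level_and_plots(self, tmp_path):
        """A pooled model over two identically-distributed domains shows
        only sampling-noise domain spread (< 5 AUC-percent-squared)."""
        from domainsalvage import synth
        from domainsalvage.data import SplitSpec, split_dataset
        from domainsalvage.experiment import global_fraction_experiment
        from domainsalvage.train import ClassifierConfig

        doms = synth.make_domains(synth.TaskSpec(n_per_domain=250, seed=13),
                                  synth.no_shift_pair())
        splits = [split_dataset(d, SplitSpec(seed=0)) for d in doms]
        table = global_fraction_experiment(
            [s[0] for s in splits], [s[1] for s in splits],
            [s[2] for s in splits],
            ClassifierConfig(max_epochs=8, patience=4, batch_size=64),
            fractions=(0.5, 1.0), seed=3)
        assert list(table["fraction"]) == [0.5, 1.0]
        full = table.iloc[-1]
        assert full["spread"] < 5.0
        assert {"auc_domain0", "auc_domain1", "auc_pooled"} <= set(table.columns)
        E.plot_domain_spread(table, tmp_path / "spread.png")
        assert (tmp_path / "spread.png").stat().st_size > 0

    def test_tiny_fraction_skipped_with_warning(self, rng):
        from domainsalvage import synth
        from domainsalvage.data import SplitSpec, split_dataset
        from domainsalvage.experiment import global_fraction_experiment
        from domainsalvage.train import ClassifierConfig

        doms = synth.make_domains(synth.TaskSpec(n_per_domain=60, seed=5),
                                  synth.no_shift_pair())
        splits = [split_dataset(d, SplitSpec(seed=0)) for d in doms]
        with pytest.warns(UserWarning, match="skipped"):
            table = global_fraction_experiment(
                [s[0] for s in splits], [s[1] for s in splits],
                [s[2] for s in splits],
                ClassifierConfig(max_epochs=1, batch_size=32),
                fractions=(0.001, 1.0), seed=0)
        assert list(table["fraction"]) == [1.0]


class TestCalibrationPlot:
    def test_plot_written(self, tmp_path, rng):
        probs = rng.random(200)
        labels = (rng.random(200) < probs).astype(int)
        tab = E.calibration_curve(probs, labels)
        E.plot_calibration(tab, tmp_path / "cal.svg")
        assert (tmp_path / "cal.svg").stat().st_size > 0
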