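"""AUC, fold hygiene (no test-set leakage), frequencies, and feature
aggregation for the penalized-regression classifiers."""

import itertools

import numpy as np
import pandas as pd
import pytest

from laborsig.classify import (
    ClassifierConfig,
    ClassifierReport,
    FoldError,
    aggregate_model_features,
    classification_frequencies,
    cross_study_classify,
    repeated_cv,
    roc_auc,
)
from laborsig.containers import ExpressionStudy


def pairwise_auc_oracle(scores, labels):
    """Concordant-pair enumeration with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def toy_study(n_nl=8, n_il=8, n_genes=60, n_signal=15, effect=2.0, seed=0,
              study_id="toy"):
    rng = np.random.default_rng(seed)
    labels = ["NL"] * n_nl + ["IL"] * n_il
    samples = [f"{study_id}-{l}{i}" for i, l in enumerate(labels)]
    base = rng.normal(5, 1, size=(n_genes, 1))
    vals = base + rng.normal(0, 0.5, size=(n_genes, len(labels)))
    for j, l in enumerate(labels):
        if l == "IL":
            vals[:n_signal, j] += effect
    frame = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)], columns=samples)
    return ExpressionStudy(study_id=study_id, platform="intensity", values=frame,
                           phenotype=dict(zip(samples, labels)))


class TestRocAuc:
    def test_perfect_and_anti_separation(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [0, 0, 1, 1]) == 0.0

    def test_worked_example_and_oracle(self):
        scores, labels = [0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]
        assert roc_auc(scores, labels) == 0.75
        assert pairwise_auc_oracle(scores, labels) == 0.75

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_pairwise_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(4, 15))
        labels = rng.integers(0, 2, size=n)
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        scores = np.round(rng.uniform(size=n), 2)  # rounding forces some ties
        assert roc_auc(scores, labels) == pytest.approx(
            pairwise_auc_oracle(scores, labels)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestRepeatedCV:
    def test_strong_signal_and_bookkeeping(self):
        study = toy_study()
        cfg = ClassifierConfig(algorithm="lasso", k_folds=4, n_runs=3, seed=9)
        rep = repeated_cv(study, cfg)
        assert rep.mean_auc >= 0.95
        # each sample tested exactly once per run
        assert (rep.class_counts.sum(axis=1) == cfg.n_runs).all()
        # one model per (run, fold)
        assert len(rep.models) == cfg.n_runs * cfg.k_folds
        # lasso sparsity: support never exceeds the training-sample count
        n_train_max = len(study.samples) - min(
            len(m["test_samples"]) for m in rep.models
        )
        for m in rep.models:
            assert len(m["coef"]) <= n_train_max

    def test_class_smaller_than_k_rejected(self):
        study = toy_study(n_nl=3, n_il=8)
        with pytest.raises(FoldError):
            repeated_cv(study, ClassifierConfig(k_folds=4, n_runs=1))

    def test_single_class_rejected(self):
        study = toy_study(n_nl=8, n_il=0)
        study.phenotype = {s: "NL" for s in study.samples}
        with pytest.raises(ValueError):
            repeated_cv(study, ClassifierConfig(k_folds=2, n_runs=1))

    def test_no_leakage_from_test_folds(self):
        """Corrupting one sample's expression must not change models whose
        training folds exclude that sample (standardization and penalty
        selection use training data only)."""
        cfg = ClassifierConfig(algorithm="lasso", k_folds=4, n_runs=2, seed=13)
        clean = toy_study(seed=3)
        corrupted = clean.copy()
        victim = corrupted.samples[0]
        corrupted.values[victim] = corrupted.values[victim] + 1e4  # extreme outlier
        rep_a = repeated_cv(clean, cfg)
        rep_b = repeated_cv(corrupted, cfg)
        compared = 0
        for ma, mb in zip(rep_a.models, rep_b.models):
            assert ma["test_samples"] == mb["test_samples"]
            if victim in ma["test_samples"]:
                assert ma["coef"] == mb["coef"]
                compared += 1
        assert compared >= 1

    def test_permuted_labels_near_chance(self):
        study = toy_study(n_nl=10, n_il=10, seed=5)
        rng = np.random.default_rng(11)
        perm = list(rng.permutation(list(study.phenotype.values())))
        study.phenotype = dict(zip(study.samples, perm))
        rep = repeated_cv(study, ClassifierConfig(k_folds=4, n_runs=3, seed=2))
        assert 0.3 <= rep.mean_auc <= 0.7


class TestCrossStudy:
    def test_transfer_between_studies_sharing_signal(self):
        train = toy_study(seed=1, study_id="tr")
        test = toy_study(seed=2, study_id="te", n_nl=6, n_il=6)
        cfg = ClassifierConfig(algorithm="lasso", n_runs=3, seed=4)
        rep = cross_study_classify(train, test, cfg)
        assert rep.mean_auc >= 0.9
        assert (rep.class_counts.sum(axis=1) == cfg.n_runs).all()
        assert len(rep.per_run_auc) == cfg.n_runs

    def test_three_group_training_reduced_to_nl_vs_established(self):
        rng = np.random.default_rng(0)
        labels = ["NL"] * 6 + ["ILEa"] * 5 + ["ILEs"] * 5
        samples = [f"x{i}" for i in range(len(labels))]
        vals = rng.normal(5, 0.5, size=(40, len(labels)))
        vals[:10, 6:] += 2.0
        train = ExpressionStudy(
            study_id="three", platform="intensity",
            values=pd.DataFrame(vals, index=[f"g{i}" for i in range(40)], columns=samples),
            phenotype=dict(zip(samples, labels)),
        )
        test = toy_study(seed=7, n_genes=40)
        rep = cross_study_classify(train, test, ClassifierConfig(n_runs=2, seed=1))
        assert rep.mean_auc > 0.8  # ILEa samples were dropped, signal remains

    def test_no_shared_genes_rejected(self):
        a, b = toy_study(seed=1), toy_study(seed=2)
        b.values.index = [f"other{i}" for i in range(len(b.genes))]
        with pytest.raises(ValueError, match="shared"):
            cross_study_classify(a, b, ClassifierConfig(n_runs=1))


class TestFrequenciesAndFeatures:
    def _report(self):
        counts = pd.DataFrame(
            {"NL": [5, 0], "IL": [0, 5]}, index=["sampA", "sampB"]
        )
        models = [
            {"run": r, "fold": 0, "C": 1.0, "test_samples": ["sampA", "sampB"],
             "coef": {"g1": 0.2, "g2": -0.1} if r % 2 == 0 else {"g1": 0.2}}
            for r in range(5)
        ]
        return ClassifierReport(
            task_id="t", classes=["NL", "IL"], n_runs=5, k_folds=0,
            per_run_auc=[1.0] * 5, class_counts=counts, models=models,
            given_labels=pd.Series({"sampA": "NL", "sampB": "IL"}),
        )

    def test_frequency_table(self):
        freq = classification_frequencies(self._report())
        assert freq.loc["sampA", "NL"] == 5 and freq.loc["sampA", "IL"] == 0
        assert freq.loc["sampA", "freq_NL"] == 1.0
        assert (freq[["NL", "IL"]].sum(axis=1) == 5).all()

    def test_feature_aggregation(self):
        summary = aggregate_model_features(self._report())
        g1 = summary[summary.gene == "g1"].iloc[0]
        assert g1.n_models_selected == 5
        assert g1.mean_coefficient == pytest.approx(0.2)
        g2 = summary[summary.gene == "g2"].iloc[0]
        assert g2.n_models_selected == 3
        assert g2.mean_coefficient == pytest.approx(-0.1)
        # never-selected genes absent; ordering by count then name
        assert list(summary.gene) == ["g1", "g2"]

    def test_multinomial_aggregation_keyed_by_class(self):
        counts = pd.DataFrame({"NL": [1], "ILEa": [0], "ILEs": [0]}, index=["s"])
        models = [{
            "run": 0, "fold": 0, "C": 1.0, "test_samples": ["s"],
            "coef": {"NL": {"g1": -0.5}, "ILEs": {"g2": 0.3}},
        }]
        rep = ClassifierReport(
            task_id="m", classes=["NL", "ILEa", "ILEs"], n_runs=1, k_folds=1,
            per_run_auc=[1.0], class_counts=counts, models=models,
            given_labels=pd.Series({"s": "NL"}),
        )
        summary = aggregate_model_features(rep)
        assert set(summary["class"]) == {"NL", "ILEs"}
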