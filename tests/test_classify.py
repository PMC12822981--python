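"""Tests of metrics, AUC, classifiers, and patient-grouped cross-validation."""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from texent.classify import (
    ConfusionCounts,
    confusion_metrics,
    fit_predict,
    grouped_stratified_cv,
    make_classifier,
    roc_auc,
    run_experiment,
)


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=6, fp=0, tn=9, fn=0))
        assert m["accuracy"] == m["precision"] == m["recall"] == m["f1"] == 1.0

    def test_symmetric_half(self):
        m = confusion_metrics(ConfusionCounts(tp=1, fp=1, tn=1, fn=1))
        assert m["accuracy"] == m["precision"] == m["recall"] == m["f1"] == 0.5

    def test_hand_example(self):
        m = confusion_metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx(0.6)
        assert m["f1"] == pytest.approx(2.0 / 3.0)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["fpr"] == pytest.approx(0.2)

    def test_matches_closed_forms_exhaustively(self):
        """All confusion tables with total <= 12 reproduce the formulas."""
        for tp, fp, tn, fn in product(range(13), repeat=4):
            total = tp + fp + tn + fn
            if total == 0 or total > 12:
                continue
            m = confusion_metrics(ConfusionCounts(tp, fp, tn, fn))
            assert m["accuracy"] == pytest.approx((tp + tn) / total)
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            assert m["precision"] == pytest.approx(prec)
            assert m["recall"] == pytest.approx(rec)
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert m["f1"] == pytest.approx(f1)
            assert m["fpr"] == pytest.approx(fp / (fp + tn) if fp + tn else 0.0)

    def test_zero_denominator_returns_zero(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=2))
        assert m["precision"] == 0.0 and m["f1"] == 0.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(0, 0, 0, 0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_three_of_four_pairs(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])

    def test_pair_counting_equals_trapezoidal(self):
        """Rank statistic vs threshold-sweep integration on seeded vectors."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(10, 40)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.normal(0, 1, n), 1)  # coarse -> ties occur
            ours = roc_auc(labels, scores, positive=1)
            ref = roc_auc_score(labels, scores)
            assert ours == pytest.approx(ref, abs=1e-12)


def _blobs(seed=0, n=100, sep=4.0, d=5):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n, d)), rng.normal(sep, 1, (n, d))])
    y = np.array(["regular"] * n + ["irregular"] * n)
    return X, y


class TestFitPredict:
    @pytest.mark.parametrize("kind", ["knn", "svm", "lr"])
    def test_separable_blobs_perfect_accuracy(self, kind):
        X, y = _blobs()
        X_test, y_test = _blobs(seed=1)
        pred, scores = fit_predict(kind, X, y, X_test, positive="irregular")
        assert np.mean(pred == y_test) == 1.0
        # scores order the classes
        assert roc_auc(y_test, scores, positive="irregular") == 1.0

    def test_lr_scores_on_correct_side(self):
        X, y = _blobs(sep=5.0)
        pred, scores = fit_predict("lr", X, y, X, positive="irregular")
        assert np.all((scores > 0.5) == (y == "irregular"))

    def test_single_class_train_rejected(self):
        X, _ = _blobs()
        with pytest.raises(ValueError):
            fit_predict("lr", X, np.zeros(len(X)), X, positive=1)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_classifier("tree")


def _patient_table(seed=0, n_patients=20, images=4, d=8, class_shift=0.0,
                   patient_sd=2.0):
    """Feature table with patient-level structure and optional class signal."""
    rng = np.random.default_rng(seed)
    rows, labels, patients = [], [], []
    for p in range(n_patients):
        label = "irregular" if p % 2 else "regular"
        center = rng.normal(0, patient_sd, d)
        if label == "irregular":
            center = center + class_shift
        for _ in range(images):
            rows.append(center + rng.normal(0, 1, d))
            labels.append(label)
            patients.append(f"P{p:02d}")
    X = pd.DataFrame(np.asarray(rows), columns=[f"f{i}" for i in range(d)])
    return X, np.asarray(labels), np.asarray(patients)


class TestGroupedCv:
    def test_fold_partition_contract(self):
        X, y, g = _patient_table(class_shift=1.0)
        report = grouped_stratified_cv(X, y, g, classifier="lr", select_k=None)
        folds = report.fold_assignment
        assert set(folds) == set(range(5))
        df = pd.DataFrame({"fold": folds, "patient": g, "label": y})
        # no patient in two folds
        assert (df.groupby("patient")["fold"].nunique() == 1).all()
        # patient counts per class differ by <= 1 across folds
        per = df.drop_duplicates("patient").groupby(["label", "fold"]).size()
        for label in ("regular", "irregular"):
            counts = per[label]
            assert counts.max() - counts.min() <= 1

    def test_strong_signal_high_accuracy(self):
        X, y, g = _patient_table(class_shift=4.0, patient_sd=0.5)
        report = grouped_stratified_cv(X, y, g, classifier="knn", select_k=None)
        assert report.mean("accuracy") >= 0.9

    def test_label_permutation_yields_chance_accuracy(self):
        """Patient-permuted labels: grouped CV accuracy stays near 0.5."""
        accs = []
        for seed in range(6):
            X, y, g = _patient_table(seed=seed, class_shift=0.0, patient_sd=2.0)
            report = grouped_stratified_cv(X, y, g, classifier="lr", select_k=None)
            accs.append(report.mean("accuracy"))
        assert 0.38 <= np.mean(accs) <= 0.62

    def test_duplicating_images_does_not_inflate_grouped_cv(self):
        """Patient leakage detector: image duplication fools an image-level
        split but not a patient-grouped one."""
        X, y, g = _patient_table(seed=5, class_shift=0.0, patient_sd=2.0)
        dup = pd.concat([X, X], ignore_index=True)
        y2, g2 = np.tile(y, 2), np.tile(g, 2)
        grouped = grouped_stratified_cv(dup, y2, g2, classifier="knn", select_k=None)
        base = grouped_stratified_cv(X, y, g, classifier="knn", select_k=None)
        sd = max(base.sd("accuracy"), 1e-6)
        assert grouped.mean("accuracy") <= base.mean("accuracy") + max(2 * sd, 0.12)
        naive = grouped_stratified_cv(
            dup, y2, g2, classifier="knn", select_k=None, grouped=False
        )
        # with duplicates in both halves of an image-level split, kNN memorizes
        assert naive.mean("accuracy") > grouped.mean("accuracy") + 0.2

    def test_paper_mode_runs_and_differs_in_label_only(self):
        X, y, g = _patient_table(class_shift=2.0)
        safe = grouped_stratified_cv(X, y, g, classifier="lr", select_k=5, mode="safe")
        paper = grouped_stratified_cv(X, y, g, classifier="lr", select_k=5, mode="paper")
        assert safe.mode == "safe" and paper.mode == "paper"
        assert len(paper.selected_features) == 5
        # paper mode selects once: all folds share the same feature list
        assert len(set(paper.selected_features)) == 1

    def test_deterministic_given_seed(self):
        X, y, g = _patient_table(class_shift=1.0)
        a = grouped_stratified_cv(X, y, g, classifier="svm", seed=7, select_k=4)
        b = grouped_stratified_cv(X, y, g, classifier="svm", seed=7, select_k=4)
        assert a.fold_metrics.equals(b.fold_metrics)
        assert a.fold_assignment.equals(b.fold_assignment)

    def test_too_few_patients_rejected(self):
        X, y, g = _patient_table(n_patients=2)
        with pytest.raises(ValueError):
            grouped_stratified_cv(X, y, g, classifier="lr", select_k=None)

    def test_fewer_patients_than_folds_reduces_with_warning(self):
        X, y, g = _patient_table(n_patients=6, class_shift=2.0)
        with pytest.warns(UserWarning, match="reducing folds"):
            report = grouped_stratified_cv(X, y, g, classifier="lr", select_k=None)
        assert report.n_splits == 3


class TestSeparationDialRecovery:
    def test_cv_accuracy_monotone_in_class_separation(self):
        """Turning the generator's separation dial (null -> weak -> strong)
        monotonically increases mean grouped-CV accuracy."""
        from texent.features import feature_columns, feature_table
        from texent.synthetic import generate_cohort, preset_config

        means = {}
        for preset in ("null", "weak", "strong"):
            accs = []
            for seed in (19, 20, 21):
                cfg = preset_config(
                    preset, n_patients_regular=6, n_patients_irregular=6,
                    images_per_patient=3, image_size=32, seed=seed,
                )
                images, _ = generate_cohort(cfg)
                table = feature_table(images, "entropy")
                X = table[feature_columns(table)]
                report = grouped_stratified_cv(
                    X,
                    table["class_label"].to_numpy(),
                    table["patient_id"].to_numpy(),
                    classifier="lr",
                    seed=seed,
                    select_k=None,
                )
                accs.append(report.mean("accuracy"))
            means[preset] = np.mean(accs)
        assert means["null"] < means["weak"] < means["strong"]


class TestRunExperiment:
    def test_grid_shape_and_metrics(self, tiny_cohort):
        images, _ = tiny_cohort
        grid, per_fold = run_experiment(
            images,
            image_types=("raw", "median"),
            feature_sets=("entropy",),
            classifiers=("knn", "lr"),
            select_k=10,
        )
        assert len(grid) == 4  # 2 image types x 1 set x 2 classifiers
        for metric in ("accuracy", "precision", "recall", "f1", "auc"):
            assert f"{metric}_mean" in grid.columns
            assert f"{metric}_sd" in grid.columns
        # per-fold aggregation matches independent recomputation
        for _, row in grid.iterrows():
            mask = (
                (per_fold["image_type"] == row["image_type"])
                & (per_fold["classifier"] == row["classifier"])
            )
            sub = per_fold[mask]
            assert row["accuracy_mean"] == pytest.approx(sub["accuracy"].mean())
            assert row["accuracy_sd"] == pytest.approx(sub["accuracy"].std(ddof=1))

    def test_best_flags_one_per_group(self, tiny_cohort):
        images, _ = tiny_cohort
        grid, _ = run_experiment(
            images,
            image_types=("raw", "median"),
            feature_sets=("entropy",),
            classifiers=("lr",),
            select_k=10,
        )
        assert grid["accuracy_best"].sum() == 1
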