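"""Undersampling, the seven-metric report, cross-validation and training."""

import numpy as np
import pytest

from hitfinder.chem_io import standardize_molecule
from hitfinder.compound_curation import LabeledCompound
from hitfinder.model_training import (
    ConfusionCounts,
    MLP_GRID,
    RF_GRID,
    TrainedClassifier,
    TrainingConfig,
    auc_from_curve,
    compute_metrics,
    cross_validate,
    train_model,
    undersample,
)
from hitfinder.synthetic_fixtures import planted_bit_dataset
from hitfinder.vectorization import FingerprintMatrix, FingerprintSpec

SMILES_POOL = [
    "CCO", "CCN", "CCC", "CCS", "c1ccccc1", "c1ccncc1", "CCOC", "CC(C)O",
    "CCCO", "CCCN", "CCCC", "c1ccccc1C", "c1ccccc1N", "c1ccccc1O", "CC(C)C", "CCCCO",
]


def _labeled(n_active, n_inactive):
    pool = iter(SMILES_POOL)
    out = []
    for _ in range(n_active):
        out.append(LabeledCompound(standardize_molecule(next(pool)), "active"))
    for _ in range(n_inactive):
        out.append(LabeledCompound(standardize_molecule(next(pool)), "inactive"))
    return out


class TestUndersample:
    def test_balances_to_minority_size(self):
        balanced = undersample(_labeled(3, 12), seed=0)
        labels = [c.label for c in balanced]
        assert labels.count("active") == labels.count("inactive") == 3

    def test_symmetric_when_actives_are_majority(self):
        balanced = undersample(_labeled(12, 3), seed=0)
        labels = [c.label for c in balanced]
        assert labels.count("active") == labels.count("inactive") == 3

    def test_minority_class_untouched(self):
        labeled = _labeled(2, 10)
        minority_keys = {c.molecule.inchikey for c in labeled if c.label == "active"}
        balanced = undersample(labeled, seed=7)
        assert {c.molecule.inchikey for c in balanced if c.label == "active"} == minority_keys

    def test_deterministic_per_seed(self):
        labeled = _labeled(3, 12)
        keys = lambda sel: [c.molecule.inchikey for c in sel]  # noqa: E731
        assert keys(undersample(labeled, seed=5)) == keys(undersample(labeled, seed=5))
        different = [
            keys(undersample(labeled, seed=s)) != keys(undersample(labeled, seed=5))
            for s in range(6, 26)
        ]
        assert any(different)

    def test_missing_class_fatal(self):
        with pytest.raises(ValueError):
            undersample(_labeled(0, 5), seed=0)


def _brute_force_metrics(tp, fp, tn, fn, alpha):
    """Independent literal evaluation of the stated formulas."""
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    gmean = (recall * specificity) ** 0.5
    iba = (1 + alpha * (recall - specificity)) * recall * specificity
    return precision, recall, specificity, f1, gmean, iba


class TestMetrics:
    def test_oracle_on_1000_random_confusion_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(0, 500, size=4)
            if tp + fp + tn + fn == 0:
                continue
            alpha = float(rng.uniform(0, 1))
            report = compute_metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)), alpha)
            expected = _brute_force_metrics(int(tp), int(fp), int(tn), int(fn), alpha)
            got = (report.precision, report.recall, report.specificity,
                   report.f1, report.geometric_mean, report.iba)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_perfect_classifier_gives_all_ones(self):
        report = compute_metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert (report.precision, report.recall, report.specificity, report.f1,
                report.geometric_mean, report.iba) == (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)

    def test_worked_example(self):
        report = compute_metrics(ConfusionCounts(tp=8, fn=2, tn=6, fp=4), iba_alpha=0.1)
        assert report.recall == pytest.approx(0.8)
        assert report.specificity == pytest.approx(0.6)
        assert report.precision == pytest.approx(2 / 3)
        assert report.f1 == pytest.approx(0.7273, abs=1e-4)
        assert report.geometric_mean == pytest.approx(0.6928, abs=1e-4)
        assert report.iba == pytest.approx(0.4896, abs=1e-4)

    def test_gmean_consistency_invariant(self):
        report = compute_metrics(ConfusionCounts(tp=7, fp=3, tn=9, fn=1))
        assert report.geometric_mean**2 == pytest.approx(
            report.recall * report.specificity, abs=1e-12
        )

    def test_divide_by_zero_flagged(self):
        report = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=5))
        assert report.precision == 0.0
        assert "precision" in report.divide_by_zero_flags

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=1)
        with pytest.raises(ValueError):
            ConfusionCounts(tp=0, fp=0, tn=0, fn=0)


class TestAuc:
    def test_perfect_ranking(self):
        from sklearn.metrics import roc_curve

        y = np.array([0, 0, 1, 1])
        fpr, tpr, _ = roc_curve(y, y.astype(float))
        assert auc_from_curve(fpr, tpr) == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        from sklearn.metrics import roc_curve

        y = np.array([0, 1, 0, 1])
        fpr, tpr, _ = roc_curve(y, np.full(4, 0.3))
        assert auc_from_curve(fpr, tpr) == pytest.approx(0.5)

    def test_invariant_under_monotone_transform(self):
        from sklearn.metrics import roc_curve

        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=200)
        scores = rng.random(200)
        fpr1, tpr1, _ = roc_curve(y, scores)
        fpr2, tpr2, _ = roc_curve(y, np.exp(5 * scores) + 3)
        assert auc_from_curve(fpr1, tpr1) == pytest.approx(auc_from_curve(fpr2, tpr2), abs=1e-12)


class TestCrossValidate:
    def test_fold_arithmetic(self):
        X, y = planted_bit_dataset(n_per_class=100, n_bits=64, seed=1)
        config = TrainingConfig(n_folds=10, seed=1)
        reports, curves = cross_validate(X, y, "rf", config,
                                         params={"n_estimators": 50, "max_depth": 4})
        assert len(reports) == 10
        assert len(curves) == 10
        # stratified 200-sample folds: 20 test samples each, 10+10 per class
        for rep in reports:
            assert 0.0 <= rep.auc <= 1.0

    def test_misaligned_inputs_rejected(self):
        X, y = planted_bit_dataset(n_per_class=20, n_bits=32, seed=0)
        with pytest.raises(ValueError):
            cross_validate(X, y[:-1], "rf", TrainingConfig(seed=0))


class TestTrainModel:
    def test_planted_signal_recovered_and_grid_respected(self):
        X, y = planted_bit_dataset(n_per_class=60, n_bits=128, seed=3)
        matrix = FingerprintMatrix(
            keys=[f"K{i:04d}" for i in range(len(y))],
            bits=X[:, :128],
            spec=FingerprintSpec("morgan", n_bits=128),
        )
        config = TrainingConfig(
            seed=3,
            rf_grid={"n_estimators": [50, 100], "max_depth": [4, 6]},
            mlp_grid={"hidden_layer_sizes": [(50,)], "activation": ["relu"], "alpha": [0.01]},
        )
        clf = train_model(matrix, y, "rf", config)
        assert clf.mean_cv_auc >= 0.95
        assert clf.chosen_hyperparameters["n_estimators"] in [50, 100]
        assert clf.chosen_hyperparameters["max_depth"] in [4, 6]
        assert len(clf.cv_metrics) == 10

    def test_default_grids_match_documented_values(self):
        config = TrainingConfig(seed=0)
        assert config.rf_grid == RF_GRID == {"n_estimators": [50, 100, 200],
                                             "max_depth": [4, 6, 10, 12]}
        assert config.mlp_grid == MLP_GRID
        assert MLP_GRID["hidden_layer_sizes"] == [(50, 50, 50), (50, 50), (50,)]
        assert MLP_GRID["activation"] == ["tanh", "relu"]
        assert MLP_GRID["alpha"] == [0.01, 0.0001]

    def test_save_load_roundtrip_reproduces_scores(self, tmp_path):
        X, y = planted_bit_dataset(n_per_class=40, n_bits=64, seed=5)
        matrix = FingerprintMatrix(
            keys=[f"K{i:04d}" for i in range(len(y))],
            bits=X,
            spec=FingerprintSpec("morgan", n_bits=64),
        )
        config = TrainingConfig(
            seed=5,
            rf_grid={"n_estimators": [50], "max_depth": [4]},
        )
        clf = train_model(matrix, y, "rf", config)
        path = tmp_path / "model.joblib"
        clf.save(path)
        back = TrainedClassifier.load(path)
        a = clf.estimator.predict_proba(X)[:, 1]
        b = back.estimator.predict_proba(X)[:, 1]
        assert np.array_equal(a, b)
        assert back.fingerprint_spec == clf.fingerprint_spec
        assert back.chosen_hyperparameters == clf.chosen_hyperparameters
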