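"""SMOTE, boosted-tree training, cross-validation, attribution, log-odds."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from kre.benchmark import planted_training_set
from kre.model import (
    TrainingSet,
    attribute_features,
    attribution_scores,
    kfold_evaluate,
    load_model,
    log_odds_features,
    predict_positive,
    save_model,
    select_predictors,
    smote_balance,
    train_classifier,
)


def ts_from_arrays(x, y, columns=None):
    cols = columns or [f"f{i}" for i in range(np.asarray(x).shape[1])]
    return TrainingSet(pd.DataFrame(np.asarray(x, dtype=float), columns=cols), y)


def mann_whitney_auroc(scores_pos, scores_neg):
    """Brute-force AUROC: concordant pair fraction with 0.5 per tie."""
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p in scores_pos
        for n in scores_neg
    )
    return wins / (len(scores_pos) * len(scores_neg))


class TestSmote:
    def test_balanced_input_unchanged(self, rng):
        x = rng.random((40, 3))
        y = np.array([0, 1] * 20)
        out = smote_balance(ts_from_arrays(x, y), seed=0)
        assert len(out.labels) == 40
        assert np.allclose(out.features.to_numpy(), x)

    def test_duplicate_minority_rows_give_identical_synthetics(self):
        x = np.vstack([np.tile([1.0, 2.0, 3.0], (8, 1)), np.random.default_rng(0).random((30, 3))])
        y = np.array([1] * 8 + [0] * 30)
        out = smote_balance(ts_from_arrays(x, y), seed=1)
        synth = out.features.to_numpy()[len(y):]
        assert np.allclose(synth, [1.0, 2.0, 3.0])

    def test_synthetic_rows_convex_and_classes_equal(self, rng):
        x = rng.random((60, 4))
        y = np.array([1] * 12 + [0] * 48)
        out = smote_balance(ts_from_arrays(x, y), seed=2)
        assert out.labels.sum() == (1 - out.labels).sum() == 48
        lo, hi = x[:12].min(axis=0), x[:12].max(axis=0)
        synth = out.features.to_numpy()[60:]
        assert (synth >= lo - 1e-12).all() and (synth <= hi + 1e-12).all()
        # originals preserved
        assert np.allclose(out.features.to_numpy()[:60], x)

    def test_too_small_minority_suggests_smaller_k(self, rng):
        x = rng.random((20, 3))
        y = np.array([1] * 4 + [0] * 16)
        with pytest.raises(ValueError, match="k_neighbors"):
            smote_balance(ts_from_arrays(x, y), k_neighbors=5)


class TestTrainClassifier:
    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            TrainingSet(pd.DataFrame(rng.random((10, 2))), np.ones(10))

    def test_separable_planted_cohort_high_training_accuracy(self):
        ts = planted_training_set(0.95, 0.05, n_elements=400, n_features=20,
                                  n_planted=6, seed=3)
        model = train_classifier(ts, {"n_estimators": 100}, seed=0)
        pred = (predict_positive(model, ts.features) >= 0.5).astype(int)
        assert (pred == ts.labels).mean() >= 0.99

    def test_permuted_labels_give_chance_auroc(self):
        ts = planted_training_set(0.60, 0.16, n_elements=2000, n_features=40,
                                  n_planted=6, seed=4)
        rng = np.random.default_rng(4)
        y_perm = rng.permutation(ts.labels)
        perm = TrainingSet(ts.features, y_perm)
        m = kfold_evaluate(perm, k=5, seed=4, hyperparams={"n_estimators": 60})
        assert abs(np.mean(m.auroc) - 0.5) <= 0.07

    def test_save_reload_identical_probabilities(self, tmp_path):
        ts = planted_training_set(0.6, 0.16, n_elements=300, n_features=15,
                                  n_planted=4, seed=5)
        model = train_classifier(ts, {"n_estimators": 50}, seed=1)
        p1 = predict_positive(model, ts.features)
        save_model(model, tmp_path / "m.json")
        reloaded = load_model(tmp_path / "m.json")
        p2 = predict_positive(reloaded, ts.features)
        assert np.array_equal(p1, p2)


class TestKfoldEvaluate:
    def test_auroc_equals_mann_whitney_pair_count(self, rng):
        # the rank-based estimator used for fold metrics vs the O(n^2) oracle
        for _ in range(5):
            n_pos, n_neg = int(rng.integers(5, 100)), int(rng.integers(5, 100))
            pos = np.round(rng.random(n_pos), 2)   # rounding forces ties
            neg = np.round(rng.random(n_neg), 2)
            y = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
            s = np.concatenate([pos, neg])
            assert roc_auc_score(y, s) == pytest.approx(
                mann_whitney_auroc(pos, neg)
            )

    def test_hand_computed_auroc(self):
        # pos {0.9, 0.4}, neg {0.6, 0.2}: 3 of 4 concordant pairs
        assert roc_auc_score([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2]) == 0.75
        assert mann_whitney_auroc([0.9, 0.4], [0.6, 0.2]) == 0.75

    def test_k_exceeding_minority_size_rejected(self, rng):
        x = rng.random((30, 3))
        y = np.array([1] * 4 + [0] * 26)
        with pytest.raises(ValueError, match="minority"):
            kfold_evaluate(ts_from_arrays(x, y), k=5)

    def test_oversampling_stays_inside_folds(self):
        """Balancing before CV leaks synthetic rows into held-out folds and
        inflates metrics; the pipeline path must not equal that variant."""
        ts = planted_training_set(0.55, 0.25, n_elements=400, n_features=20,
                                  n_planted=4, seed=6)
        hp = {"n_estimators": 60}
        inside = kfold_evaluate(ts, k=5, seed=6, hyperparams=hp)
        leaky_ts = smote_balance(ts, seed=6)
        leaky = kfold_evaluate(leaky_ts, k=5, seed=6, hyperparams=hp,
                               oversample=False)
        assert np.mean(leaky.aupr) > np.mean(inside.aupr)
        assert not np.allclose(inside.auroc, leaky.auroc)


class TestAttribution:
    def test_constant_feature_gets_zero_attribution(self):
        ts = planted_training_set(0.7, 0.1, n_elements=300, n_features=8,
                                  n_planted=3, background=0.3, seed=7)
        ts.features["const"] = 0.0
        model = train_classifier(ts, {"n_estimators": 50}, seed=0)
        attr = attribute_features(model, ts.features)
        assert np.allclose(attr["const"], 0.0)

    def test_local_accuracy_additivity(self):
        ts = planted_training_set(0.7, 0.1, n_elements=300, n_features=10,
                                  n_planted=3, seed=8)
        model = train_classifier(ts, {"n_estimators": 50}, seed=0)
        attr = attribute_features(model, ts.features)
        total = attr.sum(axis=1).to_numpy()       # includes the bias column
        prob = predict_positive(model, ts.features)
        margin = np.log(prob / (1 - prob))
        assert np.allclose(total, margin, atol=1e-4)

    def test_planted_features_rank_top(self):
        ts = planted_training_set(0.65, 0.12, n_elements=1500, n_features=60,
                                  n_planted=12, seed=9)
        model = train_classifier(smote_balance(ts, seed=9), seed=0)
        scores = attribution_scores(attribute_features(model, ts.features))
        top15 = set(scores.sort_values(ascending=False).index[:15])
        planted = {f"TF{i:03d}" for i in range(12)}
        assert planted <= top15

    def test_feature_mismatch_rejected(self):
        ts = planted_training_set(0.7, 0.1, n_elements=200, n_features=6,
                                  n_planted=2, seed=10)
        model = train_classifier(ts, {"n_estimators": 20}, seed=0)
        wrong = ts.features.rename(columns={"TF000": "other"})
        with pytest.raises(ValueError, match="match"):
            attribute_features(model, wrong)


class TestLogOdds:
    def _matrix(self, pos_occupied, n_pos, neg_occupied, n_neg):
        col = [1] * pos_occupied + [0] * (n_pos - pos_occupied)
        col += [1] * neg_occupied + [0] * (n_neg - neg_occupied)
        ids = [f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_neg)]
        occ = pd.DataFrame({"F": col}, index=ids)
        return occ, {f"p{i}" for i in range(n_pos)}, {f"n{i}" for i in range(n_neg)}

    def test_hand_value_ln16(self):
        occ, pos, neg = self._matrix(80, 100, 20, 100)
        fw = log_odds_features(occ, pos, neg)
        assert fw.loc[0, "log_odds_ratio"] == pytest.approx(np.log(16.0))
        assert not fw.loc[0, "zero_cell_corrected"]

    def test_equal_occupancy_zero(self):
        occ, pos, neg = self._matrix(50, 100, 50, 100)
        assert log_odds_features(occ, pos, neg).loc[0, "log_odds_ratio"] == 0.0

    def test_zero_cell_haldane_correction(self):
        occ, pos, neg = self._matrix(10, 10, 0, 10)
        fw = log_odds_features(occ, pos, neg)
        assert fw.loc[0, "log_odds_ratio"] == pytest.approx(np.log(441.0))
        assert fw.loc[0, "zero_cell_corrected"]

    def test_antisymmetry_including_corrected_cells(self, rng):
        n_pos, n_neg = 30, 50
        ids = [f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_neg)]
        occ = pd.DataFrame(
            rng.integers(0, 2, size=(n_pos + n_neg, 10)),
            index=ids, columns=[f"F{j}" for j in range(10)],
        )
        occ["F9"] = [1] * n_pos + [0] * n_neg   # forces zero cells
        pos = {f"p{i}" for i in range(n_pos)}
        neg = {f"n{i}" for i in range(n_neg)}
        fwd = log_odds_features(occ, pos, neg)["log_odds_ratio"].to_numpy()
        rev = log_odds_features(occ, neg, pos)["log_odds_ratio"].to_numpy()
        assert np.allclose(fwd, -rev)

    def test_brute_force_2x2_agreement(self, rng):
        n_pos, n_neg = 40, 60
        ids = [f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_neg)]
        occ = pd.DataFrame(
            rng.integers(0, 2, size=(n_pos + n_neg, 12)),
            index=ids, columns=[f"F{j}" for j in range(12)],
        )
        pos = {f"p{i}" for i in range(n_pos)}
        neg = {f"n{i}" for i in range(n_neg)}
        fw = log_odds_features(occ, pos, neg).set_index("feature")
        for col in occ.columns:
            a = sum(occ.loc[sorted(pos), col])
            b = n_pos - a
            c = sum(occ.loc[sorted(neg), col])
            d = n_neg - c
            if 0 in (a, b, c, d):
                expected = np.log((a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5)))
            else:
                expected = np.log(a * d / (b * c))
            assert fw.loc[col, "log_odds_ratio"] == pytest.approx(expected)

    def test_overlapping_id_sets_rejected(self):
        occ, pos, neg = self._matrix(5, 10, 5, 10)
        with pytest.raises(ValueError):
            log_odds_features(occ, pos, pos)


class TestSelectPredictors:
    @pytest.mark.parametrize(
        "log_or, frac, footprint, expected",
        [
            (1.2, 0.25, True, True),
            (1.2, 0.08, True, False),
            (-0.3, 0.40, True, False),
            (1.2, 0.25, False, False),
        ],
    )
    def test_gates(self, log_or, frac, footprint, expected):
        fw = pd.DataFrame(
            {"feature": ["F"], "log_odds_ratio": [log_or],
             "positive_fraction": [frac]}
        )
        flags = pd.Series({"F": footprint})
        out = select_predictors(fw, flags)
        assert bool(out.loc[0, "selected"]) is expected

    def test_sorted_by_log_or_descending(self):
        fw = pd.DataFrame(
            {
                "feature": ["A", "B", "C"],
                "log_odds_ratio": [0.5, 2.0, 2.0],
                "positive_fraction": [0.5, 0.2, 0.4],
            }
        )
        flags = pd.Series({"A": True, "B": True, "C": True})
        out = select_predictors(fw, flags)
        assert list(out["feature"]) == ["C", "B", "A"]

    def test_missing_footprint_flag_rejected(self):
        fw = pd.DataFrame(
            {"feature": ["F"], "log_odds_ratio": [1.0], "positive_fraction": [0.5]}
        )
        with pytest.raises(ValueError):
            select_predictors(fw, pd.Series(dtype=bool))
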