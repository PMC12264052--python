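"""Metric suite: brute-force oracles, dummy identities, calibration,
confusion, attribution."""

import itertools

import numpy as np
import pandas as pd
import pytest

from periopred.evaluation import (
    binary_metrics,
    brier_skill,
    calibration_table,
    confusion,
    importance_ranking,
    multiclass_metrics,
)


def oracle_binary(y, yhat):
    """Independent brute-force metric computation from raw counts."""
    tp = sum(1 for a, b in zip(y, yhat) if a == 1 and b == 1)
    fp = sum(1 for a, b in zip(y, yhat) if a == 0 and b == 1)
    fn = sum(1 for a, b in zip(y, yhat) if a == 1 and b == 0)
    tn = sum(1 for a, b in zip(y, yhat) if a == 0 and b == 0)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    return {"accuracy": (tp + tn) / len(y), "precision": prec,
            "recall": rec, "f1": f1, "npv": npv}


def test_binary_metrics_vs_oracle_all_length6_patterns():
    """Exhaustive agreement on every label/prediction pattern of length 6."""
    import warnings
    for y in itertools.product([0, 1], repeat=6):
        for yhat in itertools.product([0, 1], repeat=6):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # single-class AUC warning
                got = binary_metrics(y, yhat, np.asarray(yhat, dtype=float))
            want = oracle_binary(y, yhat)
            for k, v in want.items():
                assert got[k] == pytest.approx(v), (y, yhat, k)


def test_binary_metrics_worked_example():
    # TP=2 FP=1 FN=2 TN=5
    y = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
    yhat = [1, 1, 0, 0, 1, 0, 0, 0, 0, 0]
    m = binary_metrics(y, yhat, np.asarray(yhat, dtype=float))
    assert m["precision"] == pytest.approx(2 / 3)
    assert m["recall"] == pytest.approx(0.5)
    assert m["f1"] == pytest.approx(4 / 7)


def test_perfect_probabilities():
    y = [0, 1, 0, 1]
    m = binary_metrics(y, y, np.asarray(y, dtype=float))
    assert m["brier"] == 0.0 and m["f1"] == 1.0 and m["roc_auc"] == 1.0


def test_prior_predictor_brier_closed_form():
    rng = np.random.default_rng(0)
    for p in (0.2, 0.38, 0.5):
        y = (rng.random(4000) < p).astype(int)
        prev = y.mean()
        m = binary_metrics(y, np.zeros_like(y), np.full(len(y), prev))
        # direct averaging equals the closed form p(1-p) exactly
        assert m["brier"] == pytest.approx(prev * (1 - prev))


def test_single_class_auc_none_with_warning():
    with pytest.warns(UserWarning, match="ROC AUC"):
        m = binary_metrics([1, 1, 1], [1, 1, 0], [0.9, 0.8, 0.2])
    assert m["roc_auc"] is None


class TestMulticlass:
    def test_majority_dummy_identities(self):
        """Majority-vote dummy at share q: class-1 F1 = 2q/(1+q),
        macro F1 = 2q/(3(1+q)), accuracy = q."""
        y = np.array([1] * 87 + [2] * 10 + [3] * 3)
        yhat = np.ones_like(y)
        proba = np.tile([0.87, 0.10, 0.03], (len(y), 1))
        m = multiclass_metrics(y, yhat, proba)
        q = 0.87
        assert m["accuracy"] == pytest.approx(q)
        assert m["class_f1"][0] == pytest.approx(2 * q / (1 + q))
        assert m["class_f1"][1:] == [0.0, 0.0]
        assert m["f1_macro"] == pytest.approx(2 * q / (3 * (1 + q)))
        # prior Brier = sum p_k(1-p_k) in the sum convention
        p = np.array([0.87, 0.10, 0.03])
        assert m["brier"] == pytest.approx(np.sum(p * (1 - p)))

    def test_half_convention(self):
        y = np.array([1, 2, 3])
        proba = np.full((3, 3), 1 / 3)
        a = multiclass_metrics(y, np.ones(3), proba, brier_convention="sum")
        b = multiclass_metrics(y, np.ones(3), proba, brier_convention="half")
        assert b["brier"] == pytest.approx(a["brier"] / 2)

    def test_perfect_predictions(self):
        y = np.array([1, 2, 3, 2])
        proba = np.eye(3)[y - 1]
        m = multiclass_metrics(y, y, proba)
        assert m["f1_macro"] == 1.0 and m["brier"] == 0.0

    def test_hand_computed_small_case(self):
        y = np.array([1, 2, 3])
        yhat = np.array([1, 1, 1])
        proba = np.tile([1.0, 0.0, 0.0], (3, 1))
        m = multiclass_metrics(y, yhat, proba)
        assert m["accuracy"] == pytest.approx(1 / 3)
        assert m["f1_macro"] == pytest.approx((0.5 + 0 + 0) / 3)

    def test_absent_class_warns_f1_zero(self):
        y = np.array([1, 1, 2])
        proba = np.tile([0.6, 0.3, 0.1], (3, 1))
        with pytest.warns(UserWarning, match="absent"):
            m = multiclass_metrics(y, np.array([1, 1, 2]), proba)
        assert m["class_f1"][2] == 0.0


class TestBrierSkill:
    def test_worked_values(self):
        assert brier_skill(0.19, 0.24) == pytest.approx(1 - 0.19 / 0.24)
        assert brier_skill(0.2, 0.2) == 0.0
        assert brier_skill(0.0, 0.3) == 1.0

    def test_reference_zero_undefined(self):
        assert brier_skill(0.1, 0.0) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            brier_skill(-0.1, 0.2)

    def test_dummy_against_itself_zero(self):
        y = (np.random.default_rng(1).random(500) < 0.38).astype(int)
        m = binary_metrics(y, np.zeros_like(y), np.full(len(y), y.mean()))
        assert brier_skill(m["brier"], m["brier"]) == 0.0


class TestCalibration:
    def test_calibrated_simulation(self):
        rng = np.random.default_rng(3)
        p = rng.random(20000)
        y = (rng.random(20000) < p).astype(int)
        table = calibration_table(y, p, n_bins=10)
        occupied = table[table["count"] > 100]
        for _, row in occupied.iterrows():
            sd = np.sqrt(row["mean_predicted"] * (1 - row["mean_predicted"])
                         / row["count"]) + 1e-9
            assert abs(row["observed_frequency"] - row["mean_predicted"]) < 5 * sd

    def test_single_occupied_bin(self):
        y = [0, 1] * 50
        table = calibration_table(y, np.full(100, 0.5))
        occupied = table[table["count"] > 0]
        assert len(occupied) == 1
        assert occupied["observed_frequency"].iloc[0] == pytest.approx(0.5)

    def test_probability_one_in_last_bin(self):
        table = calibration_table([1], [1.0], n_bins=10)
        assert table.iloc[-1]["count"] == 1

    def test_bad_bin_count(self):
        with pytest.raises(ValueError):
            calibration_table([0, 1], [0.2, 0.8], n_bins=1)


class TestConfusion:
    def test_identity_predictions_diagonal(self):
        y = [1, 2, 3, 1, 2]
        m = confusion(y, y)
        assert np.allclose(np.diag(m.to_numpy()), [2, 2, 1])
        assert m.to_numpy().sum() == 5

    def test_row_normalized_sums(self):
        y = [1, 1, 2, 2, 3]
        yhat = [1, 2, 2, 2, 1]
        m = confusion(y, yhat, normalize="row")
        sums = m.apply(lambda r: sum(v for v in r if v is not None), axis=1)
        assert np.allclose(sums, 1.0)

    def test_known_counts(self):
        y = [1, 1, 1, 2, 2, 3]
        yhat = [1, 2, 1, 2, 3, 3]
        m = confusion(y, yhat)
        assert m.loc[1, 1] == 2 and m.loc[1, 2] == 1
        assert m.loc[2, 2] == 1 and m.loc[2, 3] == 1 and m.loc[3, 3] == 1

    def test_zero_total_row_is_none_not_nan(self):
        m = confusion([1, 1], [1, 2], normalize="column")
        # predicted-class 1 and 2 totals are 1; fine — now a column with 0
        m2 = confusion([1, 1], [1, 1], normalize="row", classes=[1, 2])
        assert m2.loc[2, 1] is None

    def test_accuracy_equals_trace_over_n(self):
        rng = np.random.default_rng(5)
        y = rng.integers(1, 4, 200)
        yhat = rng.integers(1, 4, 200)
        m = confusion(y, yhat)
        proba = np.eye(3)[yhat - 1]
        metrics = multiclass_metrics(y, yhat, proba)
        assert metrics["accuracy"] == pytest.approx(
            np.trace(m.to_numpy()) / 200)


class _SingleFeatureModel:
    """Probability depends on column 'a' only."""
    def predict_proba(self, X):
        p = 1 / (1 + np.exp(-X["a"].to_numpy(dtype=float)))
        return np.column_stack([1 - p, p])


class _ConstantModel:
    def predict_proba(self, X):
        return np.tile([0.5, 0.5], (len(X), 1))


class TestImportance:
    def _rows(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n),
                             "c": rng.normal(size=n)})

    def test_single_feature_model_ranked_first(self):
        ranking = importance_ranking(_SingleFeatureModel(), self._rows(),
                                     n_samples=30, n_permutations=4, seed=1)
        assert ranking.iloc[0]["feature"] == "a"
        assert ranking.iloc[0]["mean_abs_attribution"] > 0
        others = ranking[ranking["feature"] != "a"]["mean_abs_attribution"]
        assert (others < 1e-12).all()

    def test_constant_model_all_zero(self):
        ranking = importance_ranking(_ConstantModel(), self._rows(),
                                     n_samples=20, n_permutations=3, seed=2)
        assert (ranking["mean_abs_attribution"] == 0).all()

    def test_seeded_determinism(self):
        a = importance_ranking(_SingleFeatureModel(), self._rows(),
                               n_samples=20, n_permutations=3, seed=3)
        b = importance_ranking(_SingleFeatureModel(), self._rows(),
                               n_samples=20, n_permutations=3, seed=3)
        pd.testing.assert_frame_equal(a, b)
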