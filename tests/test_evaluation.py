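"""LOSO protocol, metrics, importances, ablation, VIF and quadrant stats."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.linear_model import LinearRegression

from edagraph.evaluation import (
    ablation_retrain,
    assign_quadrant,
    fit_fold,
    fold_importance_report,
    holm_bonferroni,
    loso_folds,
    loso_rmse,
    metrics,
    normalize_importances,
    permutation_importance,
    quadrant_statistics,
    run_loso,
    vif,
)


def synth_table(n_subjects=6, n_windows=12, n_features=4, coef=None, noise=0.05,
                seed=0):
    """Linear-response feature table: labels are a fixed linear function of
    the features plus noise, shared across subjects."""
    rng = np.random.default_rng(seed)
    coef = np.asarray(coef if coef is not None else [1.0, -0.5, 0.0, 0.0][:n_features])
    rows = []
    for s in range(n_subjects):
        X = rng.normal(size=(n_windows, n_features))
        base = X @ coef
        for i in range(n_windows):
            rows.append({
                **{f"f{j}": X[i, j] for j in range(n_features)},
                "subject_id": f"S{s}",
                "arousal": 5.0 + base[i] + rng.normal(0, noise),
                "valence": 5.0 - base[i] + rng.normal(0, noise),
            })
    return pd.DataFrame(rows)


class TestMetrics:
    def test_hand_example(self):
        m = metrics([1, 4], [1, 2])
        assert m["rmse"] == pytest.approx(math.sqrt(2))
        assert m["mae"] == pytest.approx(1.0)

    def test_perfect_prediction(self):
        m = metrics([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
        assert m["rmse"] == 0.0 and m["mae"] == 0.0 and m["r2"] == 1.0

    def test_mean_prediction_r2_zero(self):
        y = np.array([1.0, 2.0, 6.0])
        m = metrics(y, np.full(3, y.mean()))
        assert m["r2"] == pytest.approx(0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            metrics([1, 2], [1])


class TestLosoFolds:
    def test_five_subjects(self):
        folds = loso_folds([f"S{i}" for i in range(5)])
        assert len(folds) == 5
        assert all(len(tr) == 4 for tr, _ in folds)

    def test_test_ids_partition_subjects(self):
        ids = [f"S{i}" for i in range(30)]
        folds = loso_folds(ids)
        assert len(folds) == 30
        assert sorted(t for _, t in folds) == sorted(ids)
        for tr, t in folds:
            assert t not in tr

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            loso_folds(["only"])


class TestFitFold:
    def test_recovers_noiseless_linear_target(self):
        table = synth_table(noise=0.0)
        train = table[table.subject_id != "S0"]
        test = table[table.subject_id == "S0"]
        res = fit_fold(train, test, "ridge", {"alpha": [1e-8]})
        assert res.scores["arousal"]["rmse"] < 1e-3
        assert res.scores["valence"]["rmse"] < 1e-3

    def test_standardization_from_training_rows_only(self):
        table = synth_table()
        train = table[table.subject_id != "S0"]
        test = table[table.subject_id == "S0"]
        res = fit_fold(train, test, "ridge")
        X_train = train[list(res.feature_names)].to_numpy()
        scaled = res.scaler.transform(X_train)
        assert np.max(np.abs(scaled.mean(axis=0))) < 1e-9
        # held-out columns are generally not centered by training statistics
        assert np.max(np.abs(res.X_test_scaled.mean(axis=0))) > 1e-3

    def test_shuffled_labels_destroy_signal(self):
        table = synth_table(n_subjects=8, n_windows=20, noise=0.01, seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(table))
        for t in ("arousal", "valence"):
            table[t] = table[t].to_numpy()[perm]
        folds = run_loso(table, "ridge", {"alpha": [1.0]})
        r2 = np.mean([f.scores[t]["r2"] for f in folds for t in ("arousal", "valence")])
        assert r2 <= 0.05

    def test_leakage_metamorphic_perturbing_test_rows(self):
        table = synth_table(seed=5)
        train = table[table.subject_id != "S1"]
        test = table[table.subject_id == "S1"].copy()
        res1 = fit_fold(train, test, "ridge", {"alpha": [0.1]})
        test2 = test.copy()
        test2[[f"f{j}" for j in range(4)]] += 100.0  # corrupt held-out rows
        res2 = fit_fold(train, test2, "ridge", {"alpha": [0.1]})
        for t in ("arousal", "valence"):
            assert np.array_equal(res1.models[t].coef_, res2.models[t].coef_)
        assert np.array_equal(res1.scaler.mean_, res2.scaler.mean_)
        assert np.array_equal(res1.scaler.scale_, res2.scaler.scale_)

    @pytest.mark.parametrize("spec", ["lasso", "elasticnet", "lgbm", "histgb", "gbr"])
    def test_all_model_families_run(self, spec):
        table = synth_table(n_subjects=4, n_windows=8)
        train = table[table.subject_id != "S0"]
        test = table[table.subject_id == "S0"]
        res = fit_fold(train, test, spec)
        assert np.isfinite(res.scores["arousal"]["rmse"])


class TestPermutationImportance:
    def test_formula_hand_example(self):
        # e_b = 1.0, permuted errors {1.2, 1.4} -> I = ((1.2-1)+(1.4-1))/2 = 0.3
        class TwoCallModel:
            def __init__(self):
                self.calls = 0

            def predict(self, X):
                # baseline call then two permuted calls with errors 1.2, 1.4
                out = {0: 1.0, 1: 1.2, 2: 1.4}[self.calls]
                self.calls += 1
                return np.full(X.shape[0], out)

        y = np.zeros(16)
        X = np.zeros((16, 1))
        imp = permutation_importance(TwoCallModel(), X, y, n_repeats=2, seed=0)
        assert imp[0] == pytest.approx(0.3)

    def test_ignored_feature_importance_exactly_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 3))
        y = 2.0 * X[:, 0]
        model = LinearRegression().fit(X[:, :1], y)

        class Wrapper:
            def predict(self, Z):
                return model.predict(Z[:, :1])

        imp = permutation_importance(Wrapper(), X, y, n_repeats=10, seed=2)
        assert imp[1] == 0.0 and imp[2] == 0.0
        assert imp[0] > 0.0

    def test_noise_feature_importance_near_zero(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 2))
        y = 3.0 * X[:, 0] + rng.normal(0, 0.1, 200)
        model = LinearRegression().fit(X, y)
        n_rep = 100
        imp = permutation_importance(model, X, y, n_repeats=n_rep, seed=5)
        # the pure-noise feature has tiny fitted weight; its importance is
        # within 3 SE of zero, the informative one is far above
        assert abs(imp[1]) < 3 * 0.1 / math.sqrt(n_rep) + 0.01
        assert imp[0] > 1.0

    def test_normalization_maps_max_to_one(self):
        v = normalize_importances(np.array([0.1, 0.4, -0.2]))
        assert v.max() == 1.0 and v.min() == 0.0
        assert np.array_equal(normalize_importances(np.zeros(3)), np.zeros(3))

    def test_fold_report_shapes(self):
        table = synth_table(n_subjects=4, n_windows=10)
        folds = run_loso(table, "ridge", {"alpha": [1.0]})
        rep = fold_importance_report(folds, "arousal", n_repeats=5, seed=0)
        assert rep.pi.shape == (4,)
        assert rep.pi_normalized.max() == pytest.approx(1.0)
        assert rep.mdi is None  # linear model exposes no impurity importance


class TestAblation:
    def test_redundant_feature_ci_covers_zero(self):
        table = synth_table(n_subjects=6, n_windows=15, seed=7)
        table["f_dup"] = table["f0"]  # exact duplicate: removal is harmless
        res = ablation_retrain(table, "f_dup", "ridge", {"alpha": 0.1},
                               bootstrap=200, seed=0)
        assert res.ci_low <= 0.0 <= res.ci_high or abs(res.mean_pct_delta_rmse) < 5.0

    def test_removing_only_informative_feature_hurts(self):
        table = synth_table(n_subjects=6, n_windows=15, n_features=2,
                            coef=[2.0, 0.0], noise=0.01, seed=8)
        res = ablation_retrain(table, "f0", "ridge", {"alpha": 0.1},
                               bootstrap=200, seed=0)
        assert res.mean_pct_delta_rmse > 100.0
        assert res.ci_low > 0.0

    def test_bootstrap_seeded_determinism(self):
        table = synth_table(n_subjects=5, n_windows=10, seed=9)
        a = ablation_retrain(table, "f1", "ridge", {"alpha": 0.1}, bootstrap=100, seed=3)
        b = ablation_retrain(table, "f1", "ridge", {"alpha": 0.1}, bootstrap=100, seed=3)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


class TestVif:
    def test_orthogonal_feature_vif_one(self):
        rng = np.random.default_rng(0)
        n = 4000
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n),
                          "c": rng.normal(size=n)})
        assert vif(X, "a") == pytest.approx(1.0, abs=0.01)

    def test_duplicate_column_infinite(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        assert math.isinf(vif(X, "a"))

    def test_matches_direct_regression_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 3))
        X[:, 2] = 0.6 * X[:, 0] + 0.2 * rng.normal(size=50)
        got = vif(X, 2)
        reg = LinearRegression().fit(X[:, :2], X[:, 2])
        r2 = reg.score(X[:, :2], X[:, 2])
        assert got == pytest.approx(1.0 / (1.0 - r2), rel=1e-9)


class TestQuadrantStatistics:
    def test_mannwhitney_exact_p(self):
        res = stats.mannwhitneyu([1, 2, 3], [4, 5, 6], alternative="two-sided",
                                 method="exact")
        assert res.pvalue == pytest.approx(0.1)

    def test_holm_hand_example(self):
        # sorted p: 0.001 <= 0.005/3 -> reject; 0.004 > 0.005/2 -> stop
        reject = holm_bonferroni([0.001, 0.004, 0.030], alpha=0.005)
        assert reject.tolist() == [True, False, False]

    def test_holm_rejects_superset_of_bonferroni(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(0, 0.1, size=12)
            alpha = 0.01
            holm = holm_bonferroni(p, alpha)
            bonf = p <= alpha / p.size
            assert np.all(holm[bonf])

    def test_identical_groups_not_rejected(self):
        rng = np.random.default_rng(3)
        rows = []
        for s in range(8):
            for quad in ("LALV", "HAHV"):
                for _ in range(6):
                    rows.append({"subject_id": f"S{s}", "quadrant": quad,
                                 "f0": rng.normal(), "arousal": 5.0, "valence": 5.0})
        df = pd.DataFrame(rows)
        out = quadrant_statistics(df, ["f0"], alpha=0.005)
        tested = out[out.testable]
        assert not tested.reject.any()

    def test_separated_groups_detected(self):
        rows = []
        rng = np.random.default_rng(4)
        for s in range(10):
            for quad, mu in (("LALV", 0.0), ("HAHV", 5.0)):
                for _ in range(6):
                    rows.append({"subject_id": f"S{s}", "quadrant": quad,
                                 "f0": mu + rng.normal(0, 0.1),
                                 "arousal": 5.0, "valence": 5.0})
        out = quadrant_statistics(pd.DataFrame(rows), ["f0"], alpha=0.005)
        pair = out[(out.pair == "LALV-HAHV")]
        assert pair.reject.all()

    def test_absent_quadrant_untestable(self):
        rows = [{"subject_id": f"S{s}", "quadrant": "LALV", "f0": float(s),
                 "arousal": 2.0, "valence": 2.0} for s in range(5)]
        out = quadrant_statistics(pd.DataFrame(rows), ["f0"])
        assert not out[out.pair == "LALV-HAHV"].testable.any()

    @pytest.mark.parametrize(
        "a,v,expected",
        [(2.0, 2.0, "LALV"), (2.0, 8.0, "LAHV"), (8.0, 2.0, "HALV"),
         (8.0, 8.0, "HAHV"), (5.2, 4.8, "Neutral"), (5.0, 6.5, "HAHV")],
    )
    def test_quadrant_assignment(self, a, v, expected):
        assert assign_quadrant(a, v) == expected


class TestLosoRmse:
    def test_signal_beats_shuffled_null(self):
        table = synth_table(n_subjects=6, n_windows=15, noise=0.05, seed=11)
        real = loso_rmse(table, "ridge", {"alpha": 0.1}, seed=0)
        null = loso_rmse(table, "ridge", {"alpha": 0.1}, shuffle_labels=True, seed=0)
        assert real < null
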