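"""Feature assembly, splitting, forest training, evaluation and analysis."""

import numpy as np
import pandas as pd
import pytest

import kld_dti as kd
from kld_dti import model as dti
from kld_dti.errors import ConfigurationError, InputError


@pytest.fixture(scope="module")
def feature_setup(three_class_collection):
    models = kd.fit_target_models(three_class_collection, cap=1000, seed=0)
    table = kd.build_feature_table(three_class_collection, models)
    return models, table


class TestBuildFeatureTable:
    def test_one_feature_per_target_ordered_by_label(self, feature_setup):
        models, table = feature_setup
        assert dti.feature_columns(table) == [
            f"KLD_{t}" for t in sorted(models)
        ]
        assert table.shape[0] == 60  # one row per ligand
        feats = table[dti.feature_columns(table)]
        assert np.isfinite(feats.to_numpy()).all()
        assert (feats.to_numpy() >= 0).all()

    def test_own_class_divergence_is_row_minimum(self, feature_setup):
        _, table = feature_setup
        cols = dti.feature_columns(table)
        own = np.array([
            row[f"KLD_{row['label']}"] == min(row[c] for c in cols)
            for _, row in table.iterrows()
        ])
        assert own.mean() >= 0.9

    def test_class_without_density_yields_fewer_features_than_labels(
            self, three_class_collection):
        """Out-of-set scenario: a 1-fingerprint class cannot support a
        density, so its ligands get rows but no feature column."""
        tiny = kd.FingerprintCollection(
            three_class_collection.packed[:1],
            three_class_collection.n_bits,
            pd.DataFrame({"class_id": ["T99"], "ligand_id": ["T99_L0000"],
                          "conformer_index": [0]}),
        )
        coll = kd.FingerprintCollection.concat([three_class_collection, tiny])
        models = kd.fit_target_models(coll, cap=1000, seed=0)
        assert "T99" not in models
        table = kd.build_feature_table(coll, models)
        assert len(dti.feature_columns(table)) == 3
        assert set(table[dti.LABEL_COLUMN]) == {"T01", "T02", "T03", "T99"}

    def test_exclude_self_changes_own_class_feature(self, three_class_collection):
        models = kd.fit_target_models(three_class_collection, cap=1000, seed=0)
        with_excl = kd.build_feature_table(three_class_collection, models,
                                           exclude_self=True)
        without = kd.build_feature_table(three_class_collection, models,
                                         exclude_self=False)
        lig = with_excl.index[0]
        own_col = f"KLD_{with_excl.loc[lig, 'label']}"
        assert with_excl.loc[lig, own_col] != without.loc[lig, own_col]


class TestSplitTrainTest:
    def test_75_25_arithmetic_and_stratification(self, feature_setup):
        _, table = feature_setup
        train, test = kd.split_train_test(table, seed=0)
        assert len(train) == 45 and len(test) == 15
        assert set(train.index).isdisjoint(test.index)
        for lbl, n_test in test[dti.LABEL_COLUMN].value_counts().items():
            total = (table[dti.LABEL_COLUMN] == lbl).sum()
            assert abs(n_test - 0.25 * total) <= 1

    def test_same_seed_identical_split(self, feature_setup):
        _, table = feature_setup
        a = kd.split_train_test(table, seed=3)[0]
        b = kd.split_train_test(table, seed=3)[0]
        assert a.index.tolist() == b.index.tolist()

    def test_singleton_class_rejected(self, feature_setup):
        _, table = feature_setup
        bad = table.copy()
        bad.iloc[0, bad.columns.get_loc(dti.LABEL_COLUMN)] = "lonely"
        with pytest.raises(InputError, match="lonely"):
            kd.split_train_test(bad)


class TestTrainRf:
    def test_separable_features_reach_perfect_training_accuracy(
            self, feature_setup):
        _, table = feature_setup
        rf = kd.train_rf(table, n_estimators=100, seed=0)
        X = table[dti.feature_columns(table)].to_numpy()
        assert rf.score(X, table[dti.LABEL_COLUMN]) == 1.0
        assert rf.oob_score_ > 0.9

    def test_deterministic_for_fixed_seed(self, feature_setup):
        _, table = feature_setup
        X = table[dti.feature_columns(table)].to_numpy()
        p1 = kd.train_rf(table, n_estimators=50, seed=9).predict(X)
        p2 = kd.train_rf(table, n_estimators=50, seed=9).predict(X)
        assert (p1 == p2).all()

    def test_single_class_rejected(self, feature_setup):
        _, table = feature_setup
        sub = table[table[dti.LABEL_COLUMN] == "T01"]
        with pytest.raises(InputError):
            kd.train_rf(sub)


class TestCrossValidate:
    def test_separable_data_near_perfect(self, feature_setup):
        _, table = feature_setup
        accs, mean = kd.cross_validate(table, folds=5, seed=0,
                                       n_estimators=100)
        assert len(accs) == 5
        assert mean > 0.9

    def test_label_permutation_drives_accuracy_to_chance(self, feature_setup):
        """Permutation-null oracle: with labels shuffled, 3-class accuracy
        collapses to ~1/3."""
        _, table = feature_setup
        rng = np.random.default_rng(1)
        perm = table.copy()
        perm[dti.LABEL_COLUMN] = rng.permutation(
            perm[dti.LABEL_COLUMN].to_numpy())
        _, mean = kd.cross_validate(perm, folds=5, seed=0, n_estimators=100)
        assert abs(mean - 1 / 3) < 0.2

    def test_class_smaller_than_folds_rejected(self, feature_setup):
        _, table = feature_setup
        with pytest.raises(InputError):
            kd.cross_validate(table, folds=25)
        with pytest.raises(ConfigurationError):
            kd.cross_validate(table, folds=1)


class TestEvaluate:
    def test_perfect_predictions_give_unit_metrics(self, feature_setup):
        _, table = feature_setup
        train, test = kd.split_train_test(table, seed=0)
        rf = kd.train_rf(train, n_estimators=100, seed=0)
        report = kd.evaluate(rf, test)
        if report.accuracy == 1.0:  # separable by construction
            assert (report.precision == 1.0).all()
            assert (report.recall == 1.0).all()
            assert (report.f1 == 1.0).all()
            assert (report.auc.dropna() == 1.0).all()
        trace = np.trace(report.confusion.to_numpy())
        assert trace / report.confusion.to_numpy().sum() == pytest.approx(
            report.accuracy)
        # row sums equal per-class test counts
        assert (report.confusion.sum(axis=1)
                == test[dti.LABEL_COLUMN].value_counts()
                .reindex(report.labels, fill_value=0)).all()

    def test_random_features_give_chance_auc(self):
        """Monte-Carlo oracle: pure-noise features on balanced 2-class
        data give one-vs-rest AUC near 0.5."""
        rng = np.random.default_rng(0)
        n = 400
        table = pd.DataFrame({
            "KLD_a": rng.random(n), "KLD_b": rng.random(n),
            dti.LABEL_COLUMN: ["a", "b"] * (n // 2),
        }, index=[f"q{i}" for i in range(n)])
        train, test = kd.split_train_test(table, seed=0)
        rf = kd.train_rf(train, n_estimators=100, seed=0)
        report = kd.evaluate(rf, test)
        assert abs(report.auc["a"] - 0.5) < 0.15

    def test_unseen_label_errors_unless_registered(self, feature_setup):
        _, table = feature_setup
        train, test = kd.split_train_test(table, seed=0)
        rf = kd.train_rf(train, n_estimators=50, seed=0)
        rogue = test.copy()
        rogue.iloc[0, rogue.columns.get_loc(dti.LABEL_COLUMN)] = "T99"
        with pytest.raises(InputError, match="T99"):
            kd.evaluate(rf, rogue)
        report = kd.evaluate(rf, rogue, out_of_set_labels=("T99",))
        assert report.n_out_of_set == 1
        # the out-of-set row counts against overall accuracy
        assert report.accuracy <= (len(rogue) - 1) / len(rogue)


class TestFeatureAnalysis:
    def test_importances_normalized_and_duplicated_column_fully_correlated(
            self, feature_setup):
        _, table = feature_setup
        dup = table.copy()
        dup["KLD_dup"] = dup["KLD_T01"]
        cols = dti.feature_columns(dup)
        dup = dup[cols + [dti.LABEL_COLUMN]]
        rf = kd.train_rf(dup, n_estimators=100, seed=0)
        fa = kd.feature_analysis(rf, dup, seed=0)
        assert fa.correlation.loc["KLD_T01", "KLD_dup"] == pytest.approx(1.0)
        assert fa.importances.sum() == pytest.approx(1.0)
        assert (fa.importances >= 0).all()

    def test_noise_feature_ranks_below_informative(self, feature_setup):
        _, table = feature_setup
        rng = np.random.default_rng(5)
        noisy = table.copy()
        noisy["KLD_noise"] = rng.random(len(noisy))
        noisy = noisy[dti.feature_columns(noisy) + [dti.LABEL_COLUMN]]
        rf = kd.train_rf(noisy, n_estimators=200, seed=0)
        fa = kd.feature_analysis(rf, noisy, seed=0)
        assert fa.importances["KLD_noise"] < fa.importances.drop("KLD_noise").min()

    def test_pruning_curve_monotone_endpoints(self, feature_setup):
        _, table = feature_setup
        rf = kd.train_rf(table, n_estimators=100, seed=0)
        fa = kd.feature_analysis(rf, table, seed=0)
        assert list(fa.pruning["n_features"]) == [1, 2, 3]
        full = fa.pruning["accuracy"].iloc[-1]
        single = fa.pruning["accuracy"].iloc[0]
        assert full >= single - 0.05  # all informative features retained

    def test_constant_column_reported_as_undefined_correlation(
            self, feature_setup):
        _, table = feature_setup
        const = table.copy()
        const["KLD_const"] = 1.0
        const = const[dti.feature_columns(const) + [dti.LABEL_COLUMN]]
        rf = kd.train_rf(const, n_estimators=50, seed=0)
        fa = kd.feature_analysis(rf, const, seed=0)
        assert fa.correlation["KLD_const"].drop("KLD_const").isna().all()
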