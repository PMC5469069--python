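import numpy as np
import pytest
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    matthews_corrcoef,
    recall_score,
    roc_auc_score,
)

from ssbdsb.classify import (
    ENSEMBLE_KEY,
    EvaluationReport,
    ModelConfig,
    auc_rank,
    downsample_majority,
    evaluate,
    independent_test,
    majority_vote,
    make_folds,
    permutation_baseline,
    run_cv,
    train_model,
)
from ssbdsb.features import FeatureMatrix, build_family_matrices
from ssbdsb.seqio import LabeledDataset, ProteinRecord
from ssbdsb.synthetic import (
    GeneratorConfig,
    generate_aaindex_table,
    generate_dataset,
    generate_pssm_profiles,
)


def make_dataset(n_dsb, n_ssb, seed=0, delta=0.0, len_min=60, len_max=200):
    return generate_dataset(
        GeneratorConfig(
            n_dsb=n_dsb, n_ssb=n_ssb, len_min=len_min, len_max=len_max,
            delta=delta, seed=seed,
        )
    )


def random_feature_matrix(rng, ids, n_features=5, family="OAAC"):
    return FeatureMatrix(
        ids=list(ids),
        names=[f"f{i}" for i in range(n_features)],
        values=rng.normal(size=(len(ids), n_features)),
        family=family,
    )


class TestDownsample:
    def test_equalizes_counts(self):
        ds = make_dataset(10, 3)
        out = downsample_majority(ds, seed=0)
        assert out.class_counts() == {"DSB": 3, "SSB": 3}

    def test_minority_fully_retained(self):
        ds = make_dataset(10, 3)
        out = downsample_majority(ds, seed=0)
        ssb_ids = {r.id for r, l in zip(ds.records, ds.labels) if l == "SSB"}
        assert ssb_ids <= set(out.ids)

    def test_balanced_input_unchanged(self):
        ds = make_dataset(5, 5)
        out = downsample_majority(ds, seed=0)
        assert out.ids == ds.ids

    def test_seed_determinism(self):
        ds = make_dataset(50, 10)
        a = downsample_majority(ds, seed=3)
        b = downsample_majority(ds, seed=3)
        c = downsample_majority(ds, seed=4)
        assert a.ids == b.ids
        assert a.ids != c.ids

    def test_single_class_raises(self):
        ds = LabeledDataset(
            records=[ProteinRecord(id="a", sequence="ACDC")], labels=["DSB"]
        )
        with pytest.raises(ValueError):
            downsample_majority(ds, seed=0)


class TestMakeFolds:
    def test_even_split(self):
        ds = make_dataset(100, 100)
        folds = make_folds(ds, k=10, seed=0)
        labels = np.asarray(ds.labels)
        for f in range(10):
            mask = folds == f
            assert mask.sum() == 20
            assert (labels[mask] == "DSB").sum() == 10

    def test_remainder_split(self):
        ds = make_dataset(95, 95)
        folds = make_folds(ds, k=10, seed=0)
        labels = np.asarray(ds.labels)
        for f in range(10):
            for cls in ("DSB", "SSB"):
                n = ((folds == f) & (labels == cls)).sum()
                assert n in (9, 10)

    def test_k1_raises(self):
        with pytest.raises(ValueError):
            make_folds(make_dataset(20, 20), k=1, seed=0)

    def test_small_class_raises(self):
        with pytest.raises(ValueError):
            make_folds(make_dataset(100, 5), k=10, seed=0)


class TestEvaluate:
    def test_perfect(self):
        r = evaluate([1, 1, 0, 0], [1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])
        assert (r.acc, r.mcc, r.f1, r.auc) == (1.0, 1.0, 1.0, 1.0)

    def test_chance(self):
        r = evaluate([1, 1, 0, 0], [1, 0, 1, 0])
        assert r.acc == 0.5
        assert r.mcc == 0.0

    def test_closed_form_worked_example(self):
        # TP=50, FP=10, TN=40, FN=5
        y_true = [1] * 55 + [0] * 50
        y_pred = [1] * 50 + [0] * 5 + [1] * 10 + [0] * 40
        r = evaluate(y_true, y_pred)
        assert (r.tp, r.fp, r.tn, r.fn) == (50, 10, 40, 5)
        assert r.mcc == pytest.approx(
            (50 * 40 - 10 * 5) / np.sqrt(60 * 55 * 50 * 45)
        )
        assert r.f1 == pytest.approx(100 / 115)

    def test_mcc_zero_marginal(self):
        r = evaluate([1, 1, 1, 1], [1, 1, 1, 1])
        assert r.mcc == 0.0

    def test_against_sklearn_oracle_1000_vectors(self, rng):
        for _ in range(1000):
            n = int(rng.integers(4, 60))
            y_true = rng.integers(0, 2, size=n)
            y_pred = rng.integers(0, 2, size=n)
            if len(np.unique(y_true)) < 2:
                continue
            r = evaluate(y_true, y_pred)
            cm = confusion_matrix(y_true, y_pred, labels=[1, 0])
            assert (r.tp, r.fn, r.fp, r.tn) == tuple(cm.ravel())
            assert r.acc == pytest.approx(accuracy_score(y_true, y_pred))
            assert r.sn == pytest.approx(recall_score(y_true, y_pred, zero_division=np.nan))
            assert r.sp == pytest.approx(
                recall_score(y_true, y_pred, pos_label=0, zero_division=np.nan)
            )
            assert r.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))
            assert r.f1 == pytest.approx(
                f1_score(y_true, y_pred, zero_division=np.nan)
            )

    def test_mcc_class_swap_symmetry(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 50))
            y_true = rng.integers(0, 2, size=n)
            y_pred = rng.integers(0, 2, size=n)
            r1 = evaluate(y_true, y_pred)
            r2 = evaluate(1 - y_true, 1 - y_pred)
            assert r1.mcc == pytest.approx(r2.mcc)


class TestAUC:
    def test_rank_auc_vs_trapezoid_oracle(self, rng):
        # 100 random score vectors incl. heavy ties; sklearn's roc_auc_score
        # is the independent trapezoidal-ROC oracle.
        for _ in range(100):
            n = int(rng.integers(6, 80))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.uniform(size=n), 1)  # induce ties
            assert auc_rank(y, scores) == pytest.approx(
                roc_auc_score(y, scores), abs=1e-10
            )

    def test_degenerate_returns_nan(self):
        assert np.isnan(auc_rank([1, 1], [0.5, 0.7]))


class TestMajorityVote:
    def test_strict_majority(self):
        assert majority_vote([1, 1, 1, 1, 0, 0], [0.9] * 6)[0] == 1
        assert majority_vote([0, 0, 0, 0, 1, 1], [0.9] * 6)[0] == 0

    def test_tie_broken_by_mean_score(self):
        scores = [0.9, 0.8, 0.9, 0.2, 0.3, 0.62]
        label, mean = majority_vote([1, 1, 1, 0, 0, 0], scores)
        assert label == 1
        assert mean == pytest.approx(np.mean(scores))
        label, _ = majority_vote([1, 1, 1, 0, 0, 0], [0.6, 0.6, 0.6, 0.1, 0.1, 0.1])
        assert label == 0

    def test_wrong_count_raises(self):
        with pytest.raises(ValueError):
            majority_vote([1, 0], [0.5, 0.5])

    def test_five_way_vote_allowed_when_expected(self):
        label, _ = majority_vote([1, 1, 1, 0, 0], [0.5] * 5, expected_n=5)
        assert label == 1


class TestTrainModel:
    def test_separable_rf_perfect_on_train(self, rng):
        ids = [f"p{i}" for i in range(40)]
        y = np.array([0] * 20 + [1] * 20)
        values = rng.normal(size=(40, 3))
        values[:, 0] = y * 10.0  # separable column
        fm = FeatureMatrix(ids=ids, names=["a", "b", "c"], values=values,
                           family="OAAC")
        model = train_model(fm, y, ModelConfig(algorithm="RF", rf_trees=50, seed=0))
        assert np.array_equal(model.predict_labels(fm).astype(int), y)

    def test_single_class_raises(self, rng):
        fm = random_feature_matrix(rng, ["a", "b"])
        with pytest.raises(ValueError):
            train_model(fm, np.array([1, 1]), ModelConfig(rf_trees=5))

    def test_seed_determinism(self, rng):
        fm = random_feature_matrix(rng, [f"p{i}" for i in range(30)])
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        cfg = ModelConfig(algorithm="RF", rf_trees=30, seed=5)
        s1 = train_model(fm, y, cfg).predict_scores(fm)
        s2 = train_model(fm, y, cfg).predict_scores(fm)
        np.testing.assert_array_equal(s1, s2)

    @pytest.mark.parametrize("algorithm", ["RF", "SVM"])
    def test_layout_mismatch_raises(self, rng, algorithm):
        fm = random_feature_matrix(rng, [f"p{i}" for i in range(20)])
        y = np.array([0, 1] * 10)
        model = train_model(
            fm, y, ModelConfig(algorithm=algorithm, rf_trees=10, seed=0)
        )
        other = FeatureMatrix(
            ids=fm.ids, names=[f"g{i}" for i in range(5)],
            values=fm.values, family="OAAC",
        )
        with pytest.raises(ValueError, match="mismatch"):
            model.predict_scores(other)

    def test_threshold_tie_goes_positive(self, rng):
        fm = random_feature_matrix(rng, [f"p{i}" for i in range(10)])
        y = np.array([0, 1] * 5)
        model = train_model(fm, y, ModelConfig(rf_trees=4, seed=0))
        scores = model.predict_scores(fm)
        labels = model.predict_labels(fm)
        assert np.array_equal(labels, scores >= 0.5)


def _cv_features(dataset, families=("OAAC", "DIPEP0"), with_pssm=False,
                 n_props=3, seed=0):
    table = generate_aaindex_table(n_props, seed=seed)
    profiles = (
        generate_pssm_profiles(dataset, noise_scale=2.0, seed=seed)
        if with_pssm
        else None
    )
    fams = list(families) + (["PSSM"] if with_pssm else [])
    return build_family_matrices(
        dataset.records, fams, table=table, profiles=profiles
    )


class TestRunCV:
    def test_pooled_test_size_equals_dataset(self):
        ds = make_dataset(40, 15, delta=0.1)
        feats = _cv_features(ds)
        res = run_cv(ds, feats, ModelConfig(rf_trees=20, seed=0), k=5, seed=0)
        for fam in feats:
            assert not np.isnan(res.scores[fam]).any()
        assert res.reports[ENSEMBLE_KEY].n == len(ds)

    def test_signal_beats_no_signal(self):
        strong = make_dataset(40, 20, delta=0.3, seed=1)
        feats = _cv_features(strong)
        cfg = ModelConfig(rf_trees=40, seed=0)
        res = run_cv(strong, feats, cfg, k=5, seed=0)
        assert res.reports["OAAC"].auc > 0.8

    def test_reproducibility_rf(self):
        ds = make_dataset(30, 15, delta=0.2)
        feats = _cv_features(ds)
        cfg = ModelConfig(rf_trees=20, seed=0)
        r1 = run_cv(ds, feats, cfg, k=5, seed=9)
        r2 = run_cv(ds, feats, cfg, k=5, seed=9)
        for fam in r1.scores:
            np.testing.assert_array_equal(r1.scores[fam], r2.scores[fam])
        assert r1.metrics_frame().equals(r2.metrics_frame())

    def test_reproducibility_svm(self):
        ds = make_dataset(30, 15, delta=0.2)
        feats = _cv_features(ds, families=("OAAC",))
        cfg = ModelConfig(algorithm="SVM", seed=0)
        r1 = run_cv(ds, feats, cfg, k=5, seed=9)
        r2 = run_cv(ds, feats, cfg, k=5, seed=9)
        np.testing.assert_array_equal(r1.scores["OAAC"], r2.scores["OAAC"])

    def test_concat_ensemble_mode(self):
        ds = make_dataset(30, 15, delta=0.2)
        feats = _cv_features(ds)
        res = run_cv(ds, feats, ModelConfig(rf_trees=20, seed=0), k=5,
                     seed=0, ensemble="concat")
        assert ENSEMBLE_KEY in res.reports
        assert res.reports[ENSEMBLE_KEY].n == len(ds)

    def test_importances_collected_for_rf(self):
        ds = make_dataset(25, 12, delta=0.2)
        feats = _cv_features(ds, families=("OAAC",))
        res = run_cv(ds, feats, ModelConfig(rf_trees=20, seed=0), k=5,
                     seed=0, collect_importances=True)
        imp = res.importances["OAAC"]
        assert len(imp) == 20
        assert (imp >= 0).all() and np.isfinite(imp).all()

    def test_metrics_frame_layout(self):
        ds = make_dataset(25, 12, delta=0.2)
        feats = _cv_features(ds)
        res = run_cv(ds, feats, ModelConfig(rf_trees=10, seed=0), k=5, seed=0)
        frame = res.metrics_frame()
        assert list(frame.columns) == ["ACC", "SN", "SP", "AUC", "MCC", "F1"]
        assert "All features" in frame.index


class TestPermutationBaseline:
    def test_baseline_near_chance_and_below_true(self):
        ds = make_dataset(60, 30, delta=0.3, seed=2)
        feats = _cv_features(ds, families=("OAAC",))
        cfg = ModelConfig(rf_trees=40, seed=0)
        true_run = run_cv(ds, feats, cfg, k=5, seed=0)
        base_run = permutation_baseline(ds, feats, cfg, k=5, seed=0)
        assert base_run.reports["OAAC"].auc < true_run.reports["OAAC"].auc
        assert 0.25 <= base_run.reports["OAAC"].auc <= 0.75

    def test_baseline_reproducible(self):
        ds = make_dataset(30, 15, delta=0.2)
        feats = _cv_features(ds, families=("OAAC",))
        cfg = ModelConfig(rf_trees=10, seed=0)
        r1 = permutation_baseline(ds, feats, cfg, k=5, seed=4)
        r2 = permutation_baseline(ds, feats, cfg, k=5, seed=4)
        np.testing.assert_array_equal(r1.scores["OAAC"], r2.scores["OAAC"])


class TestIndependentTest:
    def test_same_generator_auc_positive(self):
        train = make_dataset(40, 20, delta=0.3, seed=1)
        test = make_dataset(20, 10, delta=0.3, seed=2)
        # regenerate ids so they do not collide
        test = LabeledDataset(
            records=[
                ProteinRecord(id=f"t_{r.id}", sequence=r.sequence)
                for r in test.records
            ],
            labels=test.labels,
        )
        tf = _cv_features(train, families=("OAAC",))
        ef = build_family_matrices(test.records, ["OAAC"])
        reports = independent_test(
            train, test, tf, ef, ModelConfig(rf_trees=40, seed=0), seed=0
        )
        assert reports["OAAC"].auc > 0.7
        assert reports[ENSEMBLE_KEY].n == len(test)

    def test_id_overlap_raises(self):
        ds = make_dataset(20, 10, delta=0.1)
        feats = _cv_features(ds, families=("OAAC",))
        with pytest.raises(ValueError, match="share ids"):
            independent_test(
                ds, ds, feats, feats, ModelConfig(rf_trees=5, seed=0)
            )

    def test_empty_test_set_raises(self):
        ds = make_dataset(20, 10)
        feats = _cv_features(ds, families=("OAAC",))
        empty = LabeledDataset(records=[], labels=[])
        with pytest.raises(ValueError, match="empty"):
            independent_test(
                ds, empty, feats, {}, ModelConfig(rf_trees=5, seed=0)
            )
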