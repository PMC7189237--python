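import math

import numpy as np
import pandas as pd
import pytest

from photognn.ml import (
    ClassifierSpec,
    ConfusionMatrix,
    blast_baseline,
    compute_metrics,
    confusion_from_labels,
    gain_ratio,
    make_classifier,
    nested_cv,
    pca_reduce,
    predict_novel,
    rank_features,
    reweight_balanced,
    select_top_features,
    selection_composition,
    smote_oversample,
    train_classifier,
)
from photognn.profile import DiscretizedProfile, NeighborhoodProfile, discretize

from conftest import make_hit


# Published confusion-matrix rows for five classifiers of novel
# photosynthetic proteins (12 positives, 111 negatives), with the metric
# values reported alongside them.
NOVEL_BENCHMARK_ROWS = {
    "blastp": ((3, 94, 17, 9), (0.150, 0.250, 0.789, 0.188, 0.078)),
    "svmprot": ((6, 74, 37, 6), (0.140, 0.500, 0.650, 0.218, 0.104)),
    "scmpsp": ((3, 76, 35, 9), (0.079, 0.250, 0.642, 0.120, -0.042)),
    "gnn_model": ((6, 89, 22, 6), (0.214, 0.500, 0.772, 0.300, 0.214)),
}


class TestComputeMetrics:
    @pytest.mark.parametrize("method", sorted(NOVEL_BENCHMARK_ROWS))
    def test_reproduces_published_benchmark_rows(self, method):
        (tp, tn, fp, fn), expected = NOVEL_BENCHMARK_ROWS[method]
        m = compute_metrics(ConfusionMatrix(tp, tn, fp, fn))
        got = (m.precision, m.recall, m.accuracy, m.f1_minor, m.mcc)
        for g, e in zip(got, expected):
            # agreement to the printed 3-decimal precision (half an ulp)
            assert g == pytest.approx(e, abs=5.0001e-4)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionMatrix(10, 20, 0, 0))
        assert (m.accuracy, m.precision, m.recall, m.f1_minor, m.mcc) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_zero_denominators_yield_zero(self):
        m = compute_metrics(ConfusionMatrix(0, 5, 0, 5))
        assert m.precision == 0.0 and m.f1_minor == 0.0 and m.mcc == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(-1, 0, 0, 0)

    def test_mcc_symmetries(self):
        cm = ConfusionMatrix(30, 45, 10, 15)
        swapped = ConfusionMatrix(45, 30, 15, 10)
        flipped = ConfusionMatrix(15, 10, 45, 30)  # predictions inverted
        base = compute_metrics(cm).mcc
        assert compute_metrics(swapped).mcc == pytest.approx(base)
        assert compute_metrics(flipped).mcc == pytest.approx(-base)

    def test_confusion_from_labels_counts_not_assignable_as_wrong(self):
        cm = confusion_from_labels(
            ["T", "T", "F", "F"], ["T", "NOT_ASSIGNABLE", "F", "T"]
        )
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)


class TestGainRatio:
    def test_perfectly_informative_binary_feature(self):
        f = np.array([0, 0, 1, 1])
        y = np.array(["T", "T", "F", "F"])
        assert gain_ratio(f, y) == pytest.approx(1.0)

    def test_constant_feature_scores_zero(self):
        assert gain_ratio(np.zeros(6), np.array(list("TTTFFF"))) == 0.0

    def test_hand_computed_eight_row_table(self):
        # feature: 0,0,1,1,2,2,3,3 -> H(A) = 2 bits
        # labels per value: (T,T) (T,F) (F,F) (T,F)
        # H(Y) = 1; H(Y|A) = 1/4*0 + 1/4*1 + 1/4*0 + 1/4*1 = 0.5
        # GR = (1 - 0.5) / 2 = 0.25
        f = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        y = np.array(["T", "T", "T", "F", "F", "F", "T", "F"])
        assert gain_ratio(f, y) == pytest.approx(0.25)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gain_ratio(np.zeros(3), np.array(["T", "F"]))


def levels_profile(matrix, labels, prefix="1e-10"):
    data = pd.DataFrame(
        np.asarray(matrix),
        columns=[f"{prefix}|f{i}" for i in range(np.shape(matrix)[1])],
    )
    data.index = [f"q{i}" for i in range(len(data))]
    return DiscretizedProfile(
        data=data,
        labels=pd.Series(list(labels), index=data.index),
        q1=1.0,
        q3=2.0,
    )


class TestFeatureSelection:
    def test_identity_when_k_equals_columns(self):
        prof = levels_profile([[0, 1], [1, 0], [2, 3], [3, 2]], "TTFF")
        out = select_top_features(prof, 2)
        pd.testing.assert_frame_equal(out.data, prof.data)

    def test_single_informative_column_wins(self):
        rng = np.random.default_rng(0)
        informative = np.array([0, 0, 0, 0, 3, 3, 3, 3])
        noise = rng.integers(0, 4, size=(8, 4))
        matrix = np.column_stack([noise[:, :2], informative, noise[:, 2:]])
        prof = levels_profile(matrix, "TTTTFFFF")
        out = select_top_features(prof, 1)
        assert list(out.data.columns) == ["1e-10|f2"]

    def test_planted_columns_rank_first(self):
        rng = np.random.default_rng(7)
        n = 120
        y = np.array(["T"] * 60 + ["F"] * 60)
        planted = np.where(y == "T", 3, 0) + rng.integers(0, 1, size=n)
        half = np.where(y == "T", rng.integers(0, 4, n), rng.integers(0, 2, n))
        noise = rng.integers(0, 4, size=(n, 5))
        matrix = np.column_stack([noise[:, :2], planted, half, noise[:, 2:]])
        prof = levels_profile(matrix, y)
        ranked = rank_features(prof)
        assert ranked.index[0] == "1e-10|f2"  # fully informative column
        assert ranked.index[1] == "1e-10|f3"  # partially informative column

    def test_composition_report(self):
        cols = ["1e-10|a", "1e-10|b", "1e-50|c"]
        assert selection_composition(cols) == {"1e-10": 2, "1e-50": 1}

    def test_k_out_of_range(self):
        prof = levels_profile([[0, 1]], "T")
        with pytest.raises(ValueError):
            select_top_features(prof, 0)
        with pytest.raises(ValueError):
            select_top_features(prof, 3)


class TestPCA:
    def test_full_variance_keeps_rank_components(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(30, 3))
        matrix = np.column_stack([base, base @ rng.normal(size=(3, 4))])
        _, pca = pca_reduce(matrix, 1.0)
        assert pca.n_components_ == 3  # rank of the centered matrix

    def test_collinear_data_needs_one_component(self):
        t = np.linspace(0, 1, 40)
        matrix = np.column_stack([t, 2 * t, -t])
        transformed, pca = pca_reduce(matrix, 0.95)
        assert pca.n_components_ == 1
        assert transformed.shape == (40, 1)

    def test_component_count_matches_eigenvalue_oracle(self):
        rng = np.random.default_rng(3)
        matrix = rng.normal(size=(60, 10)) * np.linspace(3, 0.2, 10)
        eigvals = np.sort(
            np.linalg.eigvalsh(np.cov(matrix, rowvar=False))
        )[::-1]
        cum = np.cumsum(eigvals) / eigvals.sum()
        oracle = int(np.searchsorted(cum, 0.95) + 1)
        _, pca = pca_reduce(matrix, 0.95)
        assert pca.n_components_ == oracle

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pca_reduce(np.empty((0, 0)), 0.95)


class TestSMOTE:
    def _rows(self, n=20, seed=0):
        return np.random.default_rng(seed).integers(0, 4, size=(n, 6)).astype(float)

    def test_rate_100_doubles_minority(self):
        synth = smote_oversample(self._rows(20), rate=100.0, seed=1)
        assert synth.shape == (20, 6)

    def test_synthetic_rows_inside_bounding_box(self):
        rows = self._rows(30, seed=2)
        synth = smote_oversample(rows, rate=200.0, seed=2)
        assert (synth >= rows.min(axis=0) - 1e-9).all()
        assert (synth <= rows.max(axis=0) + 1e-9).all()

    def test_coincident_points_produce_copies(self):
        rows = np.tile([[1.0, 2.0, 3.0]], (8, 1))
        synth = smote_oversample(rows, k_neighbors=3, rate=100.0, seed=0)
        assert np.allclose(synth, rows[0])

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            smote_oversample(self._rows(4), k_neighbors=5)


class TestReweight:
    def test_imbalanced_class_sums_equalised(self):
        labels = np.array(["T"] * 257 + ["F"] * 772)
        w = reweight_balanced(labels)
        assert w.sum() == pytest.approx(1029.0)
        assert w[labels == "T"].sum() == pytest.approx(514.5)
        assert w[labels == "F"].sum() == pytest.approx(514.5)
        assert w[0] == pytest.approx(514.5 / 257)
        assert w[-1] == pytest.approx(514.5 / 772)

    def test_balanced_classes_weight_one(self):
        w = reweight_balanced(np.array(["T", "F", "T", "F"]))
        assert np.allclose(w, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            reweight_balanced(np.array(["T", "T"]))


def separable_profile(n_per_class=30, n_features=8, seed=0):
    rng = np.random.default_rng(seed)
    pos = np.column_stack([
        rng.uniform(2.8, 4.0, size=(n_per_class, n_features // 2)),
        rng.uniform(0, 0.2, size=(n_per_class, n_features - n_features // 2)),
    ])
    neg = np.column_stack([
        rng.uniform(0, 0.2, size=(n_per_class, n_features // 2)),
        rng.uniform(2.8, 4.0, size=(n_per_class, n_features - n_features // 2)),
    ])
    data = pd.DataFrame(
        np.vstack([pos, neg]),
        columns=[f"1e-10|f{i}" for i in range(n_features)],
    )
    data.index = [f"q{i}" for i in range(len(data))]
    labels = pd.Series(["T"] * n_per_class + ["F"] * n_per_class,
                       index=data.index)
    return NeighborhoodProfile(data, labels)


class TestClassifiers:
    @pytest.mark.parametrize("kind", ["random_forest", "bayes_net", "svm_smo"])
    def test_separable_training_accuracy(self, kind):
        prof = separable_profile()
        disc = discretize(prof, 1.0, 2.0)
        model = train_classifier(disc, kind=kind, seed=0)
        pred = model.predict(disc.data.values.astype(float))
        assert (pred == disc.labels.values).mean() == 1.0

    def test_prediction_deterministic_under_seed(self):
        prof = separable_profile(seed=3)
        disc = discretize(prof, 1.0, 2.0)
        preds = [
            train_classifier(disc, seed=11).predict(disc.data.values.astype(float))
            for _ in range(2)
        ]
        assert (preds[0] == preds[1]).all()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_classifier("boosted_stumps")

    def test_rf_beats_majority_vote_on_planted_signal(self):
        prof = separable_profile(n_per_class=25, seed=5)
        spec = ClassifierSpec(grid=[{"n_estimators": 100, "max_depth": None}])
        cv = nested_cv(prof, spec, outer=5, inner=2, seed=5)
        assert cv.mean("accuracy") > 0.5  # majority class accuracy
        assert cv.mean("mcc") > 0.8


class TestNestedCV:
    def test_reproducible_under_fixed_seed(self):
        prof = separable_profile(seed=2)
        spec = ClassifierSpec(grid=[{"n_estimators": 50, "max_depth": None}])
        a = nested_cv(prof, spec, outer=5, inner=2, seed=4)
        b = nested_cv(prof, spec, outer=5, inner=2, seed=4)
        assert a.summary() == b.summary()

    def test_separable_profile_scores_perfectly(self):
        prof = separable_profile(seed=1)
        spec = ClassifierSpec(grid=[{"n_estimators": 100, "max_depth": None}])
        cv = nested_cv(prof, spec, outer=5, inner=2, seed=1)
        assert cv.mean("accuracy") == pytest.approx(1.0)

    def test_single_class_rejected(self):
        prof = separable_profile(seed=0)
        prof.labels[:] = "T"
        with pytest.raises(ValueError):
            nested_cv(prof, ClassifierSpec(), outer=3, inner=2, seed=0)

    def test_balancing_leaves_columns_unchanged(self):
        prof = separable_profile(n_per_class=25, seed=8)
        # unbalance: drop most positives
        keep = prof.labels.index[10:]
        prof = NeighborhoodProfile(prof.data.loc[keep].copy(),
                                   prof.labels.loc[keep].copy())
        for balance in ("reweight", "smote"):
            spec = ClassifierSpec(
                grid=[{"n_estimators": 50, "max_depth": None}], balance=balance,
                smote_k=3,
            )
            cv = nested_cv(prof, spec, outer=4, inner=2, seed=8)
            assert len(cv.fold_metrics) == 4

    def test_label_permutation_destroys_signal(self):
        prof = separable_profile(n_per_class=30, seed=6)
        rng = np.random.default_rng(6)
        prof.labels[:] = rng.permutation(prof.labels.values)
        spec = ClassifierSpec(grid=[{"n_estimators": 100, "max_depth": None}])
        mccs = []
        for seed in range(3):
            cv = nested_cv(prof, spec, outer=5, inner=2, seed=seed)
            mccs.append(cv.mean("mcc"))
        assert abs(float(np.mean(mccs))) <= 0.25


class TestNovelPrediction:
    def _model_and_profile(self):
        prof = separable_profile(seed=9)
        disc = discretize(prof, 1.0, 2.0)
        model = train_classifier(disc, seed=9)
        return model, disc

    def test_majority_vote(self):
        model, disc = self._model_and_profile()
        pos_ids = [i for i in disc.data.index if disc.labels[i] == "T"][:2]
        neg_ids = [i for i in disc.data.index if disc.labels[i] == "F"][:1]
        hits = [make_hit("novel1", s, evalue=1e-5) for s in pos_ids + neg_ids]
        pred = predict_novel(["novel1"], hits, model, disc)
        assert pred["novel1"] == "T"

    def test_no_match_is_not_assignable(self):
        model, disc = self._model_and_profile()
        pred = predict_novel(["novel1"], [], model, disc)
        assert pred["novel1"] == "NOT_ASSIGNABLE"

    def test_evalue_filter_applies(self):
        model, disc = self._model_and_profile()
        hits = [make_hit("novel1", disc.data.index[0], evalue=5.0)]
        pred = predict_novel(["novel1"], hits, model, disc, evalue_max=1.0)
        assert pred["novel1"] == "NOT_ASSIGNABLE"

    def test_exact_tie_votes_negative(self):
        model, disc = self._model_and_profile()
        pos_ids = [i for i in disc.data.index if disc.labels[i] == "T"][:1]
        neg_ids = [i for i in disc.data.index if disc.labels[i] == "F"][:1]
        hits = [make_hit("novel1", s, evalue=1e-5) for s in pos_ids + neg_ids]
        pred = predict_novel(["novel1"], hits, model, disc)
        assert pred["novel1"] == "F"


class TestBlastBaseline:
    DB = {"dbT": "T", "dbF": "F"}

    def test_best_hit_label_transferred(self):
        hits = [
            make_hit("q1", "dbT", bitscore=300, evalue=1e-30),
            make_hit("q1", "dbF", bitscore=100, evalue=1e-10),
        ]
        assert blast_baseline(["q1"], hits, self.DB) == {"q1": "T"}

    def test_no_hit_under_threshold(self):
        hits = [make_hit("q1", "dbT", evalue=100.0)]
        assert blast_baseline(["q1"], hits, self.DB, evalue_max=10.0) == {
            "q1": "NOT_ASSIGNABLE"
        }

    def test_bitscore_tie_breaks_by_evalue_then_id(self):
        hits = [
            make_hit("q1", "dbF", bitscore=200, evalue=1e-20),
            make_hit("q1", "dbT", bitscore=200, evalue=1e-40),
        ]
        assert blast_baseline(["q1"], hits, self.DB) == {"q1": "T"}
        hits = [
            make_hit("q1", "dbF", bitscore=200, evalue=1e-20),
            make_hit("q1", "dbT", bitscore=200, evalue=1e-20),
        ]
        # lexicographic: dbF < dbT
        assert blast_baseline(["q1"], hits, self.DB) == {"q1": "F"}
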