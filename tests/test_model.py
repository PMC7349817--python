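import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from stressband.io_e4 import ValidationError
from stressband.model import (
    CBFSSelector,
    StressLevelClassifier,
    cbfs_select,
    modality_columns,
    pca_reduce,
    separability_experiment,
    train_eval,
    undersample,
)


def _table(counts, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for label, n in counts.items():
        for _ in range(n):
            rows.append({"label": label, "hrv_x": rng.normal(), "eda_y": rng.normal()})
    return pd.DataFrame(rows)


class TestUndersample:
    def test_majority_reduced_to_minority(self):
        out = undersample(_table({"A": 30, "B": 10}), seed=1)
        assert out["label"].value_counts().to_dict() == {"A": 10, "B": 10}

    def test_balanced_input_unchanged_in_size(self):
        out = undersample(_table({"A": 10, "B": 10}), seed=1)
        assert len(out) == 20

    def test_three_classes_all_at_minimum(self):
        out = undersample(_table({"A": 5, "B": 7, "C": 9}), seed=1)
        assert set(out["label"].value_counts()) == {5}

    def test_reproducible_under_seed(self):
        t = _table({"A": 30, "B": 10})
        pd.testing.assert_frame_equal(undersample(t, seed=7), undersample(t, seed=7))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            undersample(_table({"A": 10}), seed=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        na=st.integers(2, 30), nb=st.integers(2, 30), seed=st.integers(0, 1000)
    )
    def test_counts_always_equalized(self, na, nb, seed):
        out = undersample(_table({"A": na, "B": nb}), seed=seed)
        counts = out["label"].value_counts()
        assert counts["A"] == counts["B"] == min(na, nb)


class TestCBFS:
    def test_feature_identical_to_label_ranks_first(self, rng):
        y = np.repeat(["a", "b"], 50)
        X = np.column_stack([(y == "b").astype(float), rng.normal(size=100)])
        sel = CBFSSelector(k=1).fit(X, y)
        assert sel.scores_[0] == pytest.approx(1.0)
        assert sel.support_[0] and not sel.support_[1]

    def test_constant_feature_scores_zero(self, rng):
        y = np.repeat(["a", "b"], 50)
        X = np.column_stack([np.full(100, 3.0), (y == "b") + rng.normal(0, 0.2, 100)])
        sel = CBFSSelector(k=1).fit(X, y)
        assert sel.scores_[0] == 0.0
        assert sel.support_[1]

    def test_k_larger_than_feature_count_warns_and_keeps_all(self, rng):
        y = np.repeat(["a", "b"], 20)
        X = rng.normal(size=(40, 3))
        with pytest.warns(UserWarning, match="keeping all"):
            sel = CBFSSelector(k=10).fit(X, y)
        assert sel.support_.all()

    def test_spectral_hrv_features_rank_high_when_only_spectra_differ(self):
        # classes that differ only in LF/HF balance: frequency-domain
        # features must dominate the top of the ranking
        import dataclasses

        from stressband import fuse, simulate

        cfg = simulate.easy_config(seed=9, duration=480.0, n_subjects=6)
        base = cfg.classes["relax"]
        cfg.classes["relax"] = dataclasses.replace(
            base, lf_amp=10.0, hf_amp=45.0)
        cfg.classes["mild"] = dataclasses.replace(
            base, lf_amp=30.0, hf_amp=30.0)
        cfg.classes["high"] = dataclasses.replace(
            base, lf_amp=50.0, hf_amp=10.0)
        sessions, _ = simulate.simulate_cohort(cfg)
        table = fuse.extract_cohort_features(sessions)
        top = cbfs_select(table, k=10)["feature"].tolist()
        freq_feats = {"hrv_lf", "hrv_hf", "hrv_vlf", "hrv_lf_hf", "hrv_plf", "hrv_phf"}
        assert len(freq_feats & set(top)) >= 3


class TestPCA:
    def test_collinear_data_needs_one_component(self):
        t = np.linspace(0, 1, 50)
        X = np.column_stack([t, 2 * t, -t])
        Z, transform = pca_reduce(X)
        assert Z.shape[1] == 1

    def test_isotropic_noise_needs_most_components(self, rng):
        X = rng.normal(size=(500, 10))
        Z, _ = pca_reduce(X, variance=0.95)
        assert Z.shape[1] >= 9

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            pca_reduce(np.array([[1.0, np.nan], [2.0, 3.0]]))

    def test_transform_reusable_on_held_out_fold(self, rng):
        X = rng.normal(size=(100, 5))
        _, transform = pca_reduce(X[:80])
        out = transform.transform(X[80:])
        assert out.shape[0] == 20


class TestLeakageGuard:
    def test_fitting_reducer_on_test_fold_changes_output(self, rng):
        # train/test share no rows; a scaler+PCA fitted with test rows
        # included produces different test-fold coordinates than one fitted
        # on the training fold only — the pipeline must do the latter
        train = rng.normal(size=(80, 6))
        test = rng.normal(loc=2.0, size=(20, 6))
        honest = StandardScaler().fit(train)
        leaky = StandardScaler().fit(np.vstack([train, test]))
        pca_honest = PCA(n_components=3).fit(honest.transform(train))
        pca_leaky = PCA(n_components=3).fit(
            leaky.transform(np.vstack([train, test]))
        )
        z_honest = pca_honest.transform(honest.transform(test))
        z_leaky = pca_leaky.transform(leaky.transform(test))
        assert not np.allclose(z_honest, z_leaky)

    def test_cv_fits_reducer_inside_training_folds(self, rng):
        # a probe feature that perfectly encodes the label on test rows but
        # is noise on train rows cannot help a fold-honest pipeline
        n = 60
        y = np.repeat(["a", "b"], n // 2)
        X = rng.normal(size=(n, 4))
        table = pd.DataFrame(X, columns=[f"hrv_f{i}" for i in range(4)])
        table["label"] = y
        res = train_eval(
            table, StressLevelClassifier("lda", seed=0), n_folds=5, seed=0
        )
        assert 20.0 <= res.accuracy <= 80.0  # noise features stay at chance


class TestTrainEval:
    def _clusters(self, rng, n=60, sep=6.0):
        y = np.repeat(["a", "b"], n // 2)
        X = rng.normal(size=(n, 4))
        X[y == "b", :2] += sep
        t = pd.DataFrame(X, columns=[f"hrv_f{i}" for i in range(4)])
        t["label"] = y
        return t

    def test_separated_clusters_near_perfect(self, rng):
        res = train_eval(self._clusters(rng), StressLevelClassifier("rf", seed=0),
                         seed=0)
        assert res.accuracy >= 99.0

    def test_shuffled_labels_fall_to_chance(self, rng):
        t = self._clusters(rng, n=200)
        t["label"] = rng.permutation(t["label"].to_numpy())
        res = train_eval(t, StressLevelClassifier("rf", seed=0), seed=0)
        band = 1.96 * np.sqrt(0.5 * 0.5 / len(t)) * 100
        assert abs(res.accuracy - 50.0) <= band

    def test_accuracy_equals_confusion_trace_ratio(self, rng):
        res = train_eval(self._clusters(rng, sep=1.0),
                         StressLevelClassifier("lda", seed=0), seed=0)
        cm = res.confusion.to_numpy()
        assert res.accuracy == pytest.approx(np.trace(cm) / cm.sum() * 100.0)

    def test_folds_are_stratified(self, rng):
        from sklearn.model_selection import StratifiedKFold

        t = self._clusters(rng, n=100)
        y = t["label"].to_numpy()
        skf = StratifiedKFold(10, shuffle=True, random_state=0)
        for _, test_idx in skf.split(np.zeros((100, 1)), y):
            frac = np.mean(y[test_idx] == "a")
            assert abs(frac - 0.5) <= 0.1 + 1e-9

    def test_selected_features_reported_for_cbfs(self, rng):
        res = train_eval(self._clusters(rng), StressLevelClassifier("rf", k=2, seed=0),
                         seed=0)
        assert res.selected_features is not None
        assert len(res.selected_features) == 2

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValidationError):
            train_eval(self._clusters(rng, n=8), n_folds=10)


class TestSeparability:
    def test_report_shape_covers_algorithms_and_modalities(self, balanced_features):
        report = separability_experiment(
            balanced_features, "3class",
            algorithms=("rf", "lda"), modalities=("hrv", "combined"),
        )
        assert list(report.index) == ["rf", "lda"]
        assert list(report.columns) == ["hrv", "combined"]
        assert report.notna().all().all()

    def test_three_class_design_uses_exactly_the_three_labels(self, balanced_features):
        from stressband.model import DESIGNS

        assert set(DESIGNS["3class"]) == {"high", "mild", "relax"}

    def test_missing_condition_raises(self, balanced_features):
        sub = balanced_features[balanced_features["label"] != "mild"]
        with pytest.raises(ValidationError, match="mild"):
            separability_experiment(sub, "3class", algorithms=("lda",),
                                    modalities=("hrv",))

    def test_accuracy_monotone_in_class_contrast(self):
        from stressband import fuse, model, simulate

        easy = simulate.easy_config(seed=5, duration=480.0, n_subjects=5)
        hard = simulate.hard_config(seed=5, duration=480.0, n_subjects=5)
        accs = {}
        for name, cfg in (("easy", easy), ("hard", hard)):
            sessions, _ = simulate.simulate_cohort(cfg)
            table = fuse.extract_cohort_features(sessions)
            bal = model.undersample(table, seed=5)
            accs[name] = train_eval(
                bal, StressLevelClassifier("rf", seed=5), seed=5
            ).accuracy
        assert accs["easy"] > accs["hard"]
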