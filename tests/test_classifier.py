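import numpy as np
import pandas as pd
import pytest

from sdstrip import classifier as clf
from sdstrip.classifier import (
    ModelConfig,
    TrainingSet,
    build_training_set,
    curate_positives,
    grid_search,
    lopo_cv,
    rank_features,
    select_top_k,
    train,
)
from sdstrip.io import Annotation, AnnotationSet, Recording


def flat_recording(n_channels=2, duration_s=12000, subject="S01", rng=None):
    rng = rng or np.random.default_rng(0)
    data = rng.normal(0, 0.1, (n_channels, int(duration_s)))
    return Recording(subject, [f"ch{i+1}" for i in range(n_channels)], 1.0, data)


def toy_frame(n_subjects=3, rows_per_subject=30, n_features=10,
              informative=None, seed=0, separation=3.0):
    """Synthetic feature table; ``informative`` names one column that carries
    the labels, all others are noise."""
    rng = np.random.default_rng(seed)
    frames = []
    for s in range(n_subjects):
        y = np.tile([0, 1], rows_per_subject // 2)
        X = rng.normal(0, 1, (rows_per_subject, n_features))
        cols = {f"f{j}": X[:, j] for j in range(n_features)}
        if informative is not None:
            cols[informative] = y * separation + rng.normal(0, 0.5, rows_per_subject)
        frames.append(pd.DataFrame({
            **cols,
            "label": np.where(y == 1, clf.POS_LABEL, clf.NEG_LABEL),
            "subject": f"S{s+1:02d}",
            "channel": "ch1",
            "center_time_s": np.arange(rows_per_subject) * 1000.0,
            "segment_abs_max_mv": np.full(rows_per_subject, 5.0),
        }))
    return TrainingSet(pd.concat(frames, ignore_index=True))


class TestBuildTrainingSet:
    def test_one_positive_per_annotation(self):
        rec = flat_recording()
        ann = AnnotationSet([Annotation("S01", "ch1", t) for t in (3000, 5000, 8000)])
        ts = build_training_set(rec, ann)
        assert ts.n_positive() == 3

    def test_channel_without_sd_contributes_no_negatives(self):
        rec = flat_recording(n_channels=2)
        ann = AnnotationSet([Annotation("S01", "ch1", 5000)])
        ts = build_training_set(rec, ann)
        assert (ts.frame["channel"] == "ch2").sum() == 0

    def test_tiling_oracle_10500s(self):
        # 10,500-s channel, one SD at t=10,200: brute-force enumeration of
        # non-overlapping SD-free 1000-s tiles gives exactly 10
        rec = flat_recording(n_channels=1, duration_s=10500)
        ann = AnnotationSet([Annotation("S01", "ch1", 10200)])
        ts = build_training_set(rec, ann)
        expected = sum(
            1
            for start in range(0, 10500 - 1000 + 1, 1000)
            if not (start <= 10200 < start + 1000)
        )
        assert expected == 10
        assert ts.n_negative() == expected

    def test_edge_window_dropped(self):
        # annotation 100 s from the start: the 1000-s positive window
        # cannot be centered inside the recording
        rec = flat_recording(n_channels=1)
        ann = AnnotationSet([Annotation("S01", "ch1", 100)])
        ts = build_training_set(rec, ann)
        assert ts.n_positive() == 0

    def test_out_of_range_annotation_warns(self):
        rec = flat_recording(n_channels=1)
        ann = AnnotationSet([Annotation("S01", "ch1", 99999)])
        with pytest.warns(UserWarning, match="outside"):
            ts = build_training_set(rec, ann)
        assert ts.n_positive() == 0

    def test_no_negative_overlaps_any_annotation(self, rng):
        rec = flat_recording(n_channels=3, rng=rng)
        times = rng.uniform(600, 11400, 8)
        ann = AnnotationSet([Annotation("S01", f"ch{rng.integers(1, 4)}", t) for t in times])
        ts = build_training_set(rec, ann)
        negs = ts.frame[ts.frame["label"] == clf.NEG_LABEL]
        for row in negs.itertuples():
            lo, hi = row.center_time_s - 500, row.center_time_s + 500
            for m in ann.for_channel(row.channel):
                assert not (lo <= m.t_peak_s < hi)

    def test_requires_1hz(self):
        rec = Recording("S01", ["ch1"], 8.0, np.zeros((1, 100)))
        with pytest.raises(ValueError, match="1 Hz"):
            build_training_set(rec, AnnotationSet([]))


class TestCuratePositives:
    def test_identity_when_under_threshold(self):
        ts = toy_frame()
        out, removed = curate_positives(ts, 30.0)
        assert removed == 0
        pd.testing.assert_frame_equal(out.frame, ts.frame)

    def test_removes_only_flagged_positive(self):
        ts = toy_frame(n_subjects=1)
        idx = ts.frame.index[ts.frame["label"] == clf.POS_LABEL][0]
        ts.frame.loc[idx, "segment_abs_max_mv"] = 50.0
        neg_idx = ts.frame.index[ts.frame["label"] == clf.NEG_LABEL][0]
        ts.frame.loc[neg_idx, "segment_abs_max_mv"] = 50.0  # negatives untouched
        out, removed = curate_positives(ts, 30.0)
        assert removed == 1
        assert len(out.frame) == len(ts.frame) - 1
        assert (out.frame["segment_abs_max_mv"] > 30).sum() == 1

    def test_infinite_threshold_identity(self):
        ts = toy_frame()
        out, removed = curate_positives(ts, np.inf)
        assert removed == 0

    def test_nonpositive_threshold_errors(self):
        with pytest.raises(ValueError):
            curate_positives(toy_frame(), 0.0)


class TestRankFeatures:
    def test_informative_feature_ranked_first(self):
        ts = toy_frame(informative="f3", seed=1)
        ranking = rank_features(ts, ModelConfig(random_seed=0))
        assert ranking.iloc[0]["feature"] == "f3"

    def test_noise_labels_no_dominant_feature(self):
        shares = []
        for seed in range(3):
            ts = toy_frame(n_features=10, seed=seed)
            # scramble labels so no feature carries signal
            rng = np.random.default_rng(seed)
            ts.frame["label"] = rng.permutation(ts.frame["label"].to_numpy())
            ranking = rank_features(ts, ModelConfig(random_seed=seed))
            shares.append(ranking["importance"].max())
        assert np.mean(shares) < 3 / 10  # < 3x the uniform share

    def test_single_subject_errors(self):
        ts = toy_frame(n_subjects=1)
        with pytest.raises(ValueError):
            rank_features(ts, ModelConfig())

    def test_top_30_of_real_ranking(self, training_set):
        ranking = rank_features(training_set, ModelConfig(random_seed=1))
        assert len(select_top_k(ranking, 30)) == 30
        assert len(ranking) == 80


class TestTrain:
    def test_separable_training_accuracy(self):
        ts = toy_frame(informative="f0", separation=10.0)
        model = train(ts, ModelConfig(random_seed=0))
        pred = model.predict_proba(ts.X) >= 0.5
        assert (pred == ts.y).all()

    def test_deterministic_given_seed(self):
        ts = toy_frame(informative="f0")
        p1 = train(ts, ModelConfig(random_seed=7)).predict_proba(ts.X)
        p2 = train(ts, ModelConfig(random_seed=7)).predict_proba(ts.X)
        np.testing.assert_array_equal(p1, p2)

    def test_svm_probabilities_in_unit_interval(self):
        ts = toy_frame(informative="f0")
        model = train(ts, ModelConfig(model_kind="svm_rbf", random_seed=0))
        p = model.predict_proba(ts.X)
        assert ((p >= 0) & (p <= 1)).all()

    def test_one_class_errors(self):
        ts = toy_frame()
        ts.frame["label"] = clf.POS_LABEL
        with pytest.raises(ValueError):
            train(ts, ModelConfig())

    def test_permuted_labels_auc_near_half(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        ts = toy_frame(n_subjects=4, rows_per_subject=60, seed=3)
        ts.frame["label"] = rng.permutation(ts.frame["label"].to_numpy())
        train_mask = ts.subjects != "S04"
        model = train(TrainingSet(ts.frame[train_mask]), ModelConfig(random_seed=3))
        p = model.predict_proba(ts.frame[~train_mask])
        auc = roc_auc_score(ts.y[~train_mask], p)
        assert abs(auc - 0.5) < 0.15

    def test_missing_feature_at_predict_errors(self):
        ts = toy_frame(informative="f0")
        model = train(ts, ModelConfig(random_seed=0))
        with pytest.raises(ValueError, match="missing"):
            model.predict_proba(ts.X.drop(columns=["f0"]))


class TestLopoCv:
    def test_every_row_predicted_exactly_once(self):
        ts = toy_frame(n_subjects=3)
        result = lopo_cv(ts, ModelConfig(k_features=5, random_seed=0))
        assert result["n_folds"] == 3
        preds = result["predictions"]
        assert sorted(preds["row"]) == list(range(len(ts.frame)))

    def test_test_subject_never_in_training(self):
        # provenance: each fold's predictions carry exactly one subject
        ts = toy_frame(n_subjects=3)
        preds = lopo_cv(ts, ModelConfig(k_features=5, random_seed=0))["predictions"]
        for subject, grp in preds.groupby("subject"):
            rows = ts.frame.iloc[grp["row"]]["subject"]
            assert (rows == subject).all()

    def test_perfectly_separable_scores_one(self):
        ts = toy_frame(informative="f1", separation=20.0, rows_per_subject=40)
        result = lopo_cv(ts, ModelConfig(k_features=5, random_seed=0))
        assert result["accuracy"] == 1.0
        assert result["f1"] == 1.0

    def test_single_subject_errors(self):
        with pytest.raises(ValueError):
            lopo_cv(toy_frame(n_subjects=1), ModelConfig())


class TestModelPersistence:
    def test_save_load_round_trip(self, tmp_path):
        from sdstrip.io import load_model, save_model

        ts = toy_frame(informative="f0")
        model = train(ts, ModelConfig(random_seed=0))
        path = tmp_path / "model.bin"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.predict_proba(ts.X), model.predict_proba(ts.X))
        assert back.selected_features == model.selected_features
        # JSON sidecar present with registry version
        import json

        sidecar = json.loads((tmp_path / "model.bin.json").read_text())
        assert sidecar["feature_registry_version"] == model.registry_version

    def test_registry_mismatch_rejected(self, tmp_path):
        import json

        from sdstrip.io import load_model, save_model

        ts = toy_frame(informative="f0")
        model = train(ts, ModelConfig(random_seed=0))
        path = tmp_path / "model.bin"
        save_model(model, path)
        sidecar_path = tmp_path / "model.bin.json"
        sidecar = json.loads(sidecar_path.read_text())
        sidecar["feature_registry_version"] = "999"
        sidecar_path.write_text(json.dumps(sidecar))
        with pytest.raises(ValueError, match="registry"):
            load_model(path)


class TestGridSearch:
    def test_singleton_grid(self):
        ts = toy_frame(informative="f0")
        best, table = grid_search(ts, ModelConfig(k_features=5), {"n_estimators": [50]})
        assert best == {"n_estimators": 50}
        assert len(table) == 1

    def test_crippled_setting_rejected(self):
        # a leaf-size floor above the sample count forbids any split, so
        # that grid point degenerates to a constant predictor
        ts = toy_frame(informative="f0", rows_per_subject=40)
        best, _ = grid_search(
            ts, ModelConfig(k_features=5),
            {"min_samples_leaf": [10000, 2], "n_estimators": [50]},
        )
        assert best["min_samples_leaf"] == 2

    def test_table_row_count_is_grid_product(self):
        ts = toy_frame(informative="f0")
        _, table = grid_search(
            ts, ModelConfig(k_features=5),
            {"n_estimators": [20, 50], "max_depth": [2, 3, 4]},
        )
        assert len(table) == 6

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError):
            grid_search(toy_frame(), ModelConfig(), {})
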