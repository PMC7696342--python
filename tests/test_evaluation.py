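import numpy as np
import pytest

import semgrec as sg
from semgrec.dataset import Gesture
from semgrec.evaluation import (
    compare_label_schemes,
    confusion_matrix,
    cross_validate,
    export_embedding,
    make_fold_plan,
)
from semgrec.model import ModelSpec, TrainConfig
from semgrec.windowing import LabelScheme, WindowConfig

CV_SPEC = ModelSpec(conv_blocks=((4, 4), (8, 8)), gru_units=(8,),
                    conv_dropout=0.0, gru_dropout=0.0)
CV_CONFIG = TrainConfig(learning_rate=2e-3, batch_size=64, epochs=2, seed=0)


@pytest.fixture(scope="module")
def cv_dataset():
    return sg.generate_dataset(
        sg.SynthConfig(n_subjects=4, duration_s=2.0, seed=13, separability=1.2)
    )


class TestFoldPlan:
    def test_fifteen_subjects_five_groups_of_three(self):
        plan = make_fold_plan([f"s{i:02d}" for i in range(15)], n_groups=5, seed=0)
        assert [len(g) for g in plan.groups] == [3, 3, 3, 3, 3]
        assert plan.subjects == {f"s{i:02d}" for i in range(15)}

    def test_seven_subjects_three_groups_pigeonhole(self):
        plan = make_fold_plan([f"s{i}" for i in range(7)], n_groups=3, seed=1)
        assert sorted(len(g) for g in plan.groups) == [2, 2, 3]

    def test_same_seed_identical_plan(self):
        subjects = [f"s{i}" for i in range(10)]
        assert make_fold_plan(subjects, 5, seed=4) == make_fold_plan(subjects, 5, seed=4)

    def test_different_seed_generally_differs(self):
        subjects = [f"s{i}" for i in range(12)]
        plans = {make_fold_plan(subjects, 4, seed=s).groups for s in range(6)}
        assert len(plans) > 1

    def test_group_splits_are_disjoint_and_cover(self):
        plan = make_fold_plan([f"s{i}" for i in range(9)], n_groups=3, seed=0)
        for k in range(plan.n_folds):
            train, test = plan.split(k)
            assert not train & test
            assert train | test == plan.subjects

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError, match="2"):
            make_fold_plan(["a", "b", "c"], n_groups=1)

    def test_more_groups_than_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_fold_plan(["a", "b"], n_groups=3)


class TestConfusionMatrix:
    def test_perfect_predictions_identity(self):
        true = np.repeat(np.arange(7), 3)
        normalized, counts = confusion_matrix(true, true)
        assert np.array_equal(normalized, np.eye(7))
        assert counts.sum() == len(true)

    def test_constant_predictor_fills_column_zero(self):
        true = np.repeat(np.arange(7), 2)
        normalized, _ = confusion_matrix(true, np.zeros_like(true))
        assert np.array_equal(normalized[:, 0], np.ones(7))
        assert normalized[:, 1:].sum() == 0

    def test_nonempty_rows_sum_to_one_exactly(self):
        rng = np.random.default_rng(0)
        true = rng.integers(0, 7, 500)
        pred = rng.integers(0, 7, 500)
        normalized, counts = confusion_matrix(true, pred)
        present = counts.sum(axis=1) > 0
        assert np.allclose(normalized[present].sum(axis=1), 1.0, atol=1e-12)

    def test_random_balanced_predictions_approach_uniform(self):
        rng = np.random.default_rng(42)
        n = 7000
        true = np.repeat(np.arange(7), n // 7)
        pred = rng.integers(0, 7, n)
        normalized, _ = confusion_matrix(true, pred)
        p = 1 / 7
        se = np.sqrt(p * (1 - p) / (n // 7))
        assert np.all(np.abs(normalized - p) < 3 * se)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion_matrix([0, 1], [0])

    def test_out_of_range_class_rejected(self):
        with pytest.raises(ValueError, match="range"):
            confusion_matrix([0, 7], [0, 1])


class TestCrossValidate:
    def test_report_aggregates_and_leakage(self, cv_dataset):
        plan = make_fold_plan(cv_dataset.subjects, n_groups=2, seed=0)
        report = cross_validate(
            cv_dataset, WindowConfig(), LabelScheme(), CV_CONFIG, plan, CV_SPEC
        )
        assert len(report.folds) == 2
        assert report.mean_accuracy == pytest.approx(
            sum(f.test_accuracy for f in report.folds) / 2
        )
        for fold in report.folds:
            train, test = plan.split(fold.fold_id)
            assert set(fold.test_subjects) == test
            assert not train & test
            present = fold.confusion_counts.sum(axis=1) > 0
            assert np.allclose(fold.confusion[present].sum(axis=1), 1.0, atol=1e-12)
            assert fold.confusion_counts.sum() > 0

    def test_identical_config_reproduces_report(self, cv_dataset):
        plan = make_fold_plan(cv_dataset.subjects, n_groups=2, seed=0)
        a = cross_validate(cv_dataset, WindowConfig(), LabelScheme(), CV_CONFIG, plan, CV_SPEC)
        b = cross_validate(cv_dataset, WindowConfig(), LabelScheme(), CV_CONFIG, plan, CV_SPEC)
        assert a.accuracies.tolist() == b.accuracies.tolist()
        for fa, fb in zip(a.folds, b.folds):
            assert np.array_equal(fa.confusion_counts, fb.confusion_counts)

    def test_subject_missing_from_plan_rejected(self, cv_dataset):
        plan = make_fold_plan(list(cv_dataset.subjects)[:3], n_groups=3, seed=0)
        with pytest.raises(ValueError, match="missing"):
            cross_validate(cv_dataset, fold_plan=plan, train_config=CV_CONFIG,
                           model_spec=CV_SPEC)


class TestCompareLabelSchemes:
    def test_paired_report_shape_and_finiteness(self, cv_dataset):
        plan = make_fold_plan(cv_dataset.subjects, n_groups=2, seed=0)
        comparison = compare_label_schemes(
            cv_dataset, WindowConfig(), CV_CONFIG, plan, CV_SPEC
        )
        table = comparison.to_frame()
        assert len(table) == 2 * plan.n_folds  # one row per fold per scheme
        assert np.isfinite(table["test_accuracy"]).all()
        assert comparison.per_fold_difference.shape == (plan.n_folds,)
        assert comparison.one_hot.scheme.mode == "one_hot"
        assert comparison.smoothed.scheme.mode == "smoothed"

    def test_same_scheme_same_seed_zero_difference(self, cv_dataset):
        # self-comparison: the paired harness with an identical scheme must
        # reproduce identical fold accuracies
        plan = make_fold_plan(cv_dataset.subjects, n_groups=2, seed=0)
        a = cross_validate(cv_dataset, WindowConfig(), LabelScheme("one_hot"),
                           CV_CONFIG, plan, CV_SPEC)
        b = cross_validate(cv_dataset, WindowConfig(), LabelScheme("one_hot"),
                           CV_CONFIG, plan, CV_SPEC)
        assert np.array_equal(a.accuracies, b.accuracies)


class TestExportEmbedding:
    def test_embedding_rows_determinism_and_separability(self, tiny_trained):
        ds = sg.generate_dataset(
            sg.SynthConfig(n_subjects=2, duration_s=16.0, seed=21, separability=1.5)
        )
        ws = sg.build_training_arrays(ds)
        sel = np.arange(0, len(ws.X), 4)
        frame = export_embedding(
            tiny_trained, ws.X[sel], labels=ws.labels[sel],
            subjects=ws.subject_ids[sel], seed=0, perplexity=15.0,
        )
        assert len(frame) == len(sel)
        again = export_embedding(
            tiny_trained, ws.X[sel], labels=ws.labels[sel], seed=0, perplexity=15.0
        )
        assert np.allclose(frame[["x", "y"]].to_numpy(), again[["x", "y"]].to_numpy())
        # separability: classes should form clusters in the embedding
        coords = frame[["x", "y"]].to_numpy()
        labels = ws.labels[sel]
        centroids = np.stack([coords[labels == c].mean(axis=0) for c in np.unique(labels)])
        intra = np.mean([
            np.linalg.norm(coords[labels == c] - centroids[i], axis=1).mean()
            for i, c in enumerate(np.unique(labels))
        ])
        inter = np.mean([
            np.linalg.norm(centroids[i] - centroids[j])
            for i in range(len(centroids)) for j in range(i + 1, len(centroids))
        ])
        assert inter > intra

    def test_too_few_windows_for_perplexity_rejected(self, tiny_trained):
        x = np.zeros((10, 188, 8), dtype=np.float32)
        with pytest.raises(ValueError, match="perplexity"):
            export_embedding(tiny_trained, x, perplexity=30.0)

    def test_unknown_method_rejected(self, tiny_trained):
        with pytest.raises(ValueError, match="method"):
            export_embedding(tiny_trained, np.zeros((100, 188, 8)), method="umap")

    def test_csv_export(self, tmp_path, tiny_trained):
        x = np.random.default_rng(0).integers(-50, 50, size=(60, 188, 8)).astype(np.float32)
        path = tmp_path / "emb.csv"
        frame = export_embedding(tiny_trained, x, seed=1, perplexity=10.0, path=path)
        assert path.exists()
        import pandas as pd

        assert len(pd.read_csv(path)) == len(frame)
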