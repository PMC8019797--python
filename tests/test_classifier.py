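"""Gated-SVM classifier tests: training protocol, gate precedence,
persistence round-trips and class-recovery behavior."""

import dataclasses

import joblib
import numpy as np
import pytest

from echoforce import (
    LabeledEntry,
    LabeledFrameSet,
    PhantomConfig,
    VirtualPhantom,
    classify,
    evaluate,
    in_band_force_sampler,
    load_model,
    save_model,
    train_quality_model,
)
from echoforce.classifier import ModelFormatError, UntrainedModelError, _feature_matrix


def _in_memory_set(frames, labels):
    entries = [
        LabeledEntry(frame_id=f"f{i:03d}", path="", label=lab, frame=fr)
        for i, (fr, lab) in enumerate(zip(frames, labels))
    ]
    return LabeledFrameSet(entries=entries)


class TestTraining:
    def test_widely_separated_classes_reach_perfect_training_accuracy(self, phantom):
        # mid-band highs vs no-contact lows: two compact, far-apart
        # clusters in (f_c, f_n), separable by construction
        rng = np.random.default_rng(7)
        frames = [
            phantom.render_contact(float(rng.uniform(6.0, 8.0)), seed=i)
            for i in range(60)
        ] + [phantom.render_no_contact(seed=1000 + i) for i in range(60)]
        fs = _in_memory_set(frames, ["high"] * 60 + ["low"] * 60)
        model = train_quality_model(fs, phantom.reference, seed=7)
        assert model.metadata["train_accuracy"] == 1.0

    def test_single_class_set_rejected(self, phantom):
        frames = [phantom.render_contact(5.0, seed=s) for s in range(10)]
        fs = _in_memory_set(frames, ["high"] * 10)
        with pytest.raises(ValueError, match="both classes"):
            train_quality_model(fs, phantom.reference)

    def test_same_seed_gives_identical_held_out_predictions(self, phantom):
        dataset = phantom.generate_dataset(n_per_class=40, seed=3)
        train_set, test_set = dataset.split(0.8, seed=3)
        m1 = train_quality_model(train_set, phantom.reference, seed=5)
        m2 = train_quality_model(train_set, phantom.reference, seed=5)
        for entry in test_set.entries:
            frame = entry.load(test_set.root)
            assert classify(m1, frame, phantom.reference)[0] == classify(
                m2, frame, phantom.reference
            )[0]

    def test_standardized_training_features_have_zero_mean_unit_variance(
        self, phantom, trained_model
    ):
        dataset = phantom.generate_dataset(n_per_class=100, seed=7)
        train_set, _ = dataset.split(0.8, seed=7)
        X, _, _ = _feature_matrix(train_set, phantom.reference, trained_model.feature_config)
        Z = trained_model.pipeline.named_steps["scaler"].transform(X)
        assert np.all(np.abs(Z.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(Z.std(axis=0) - 1.0) < 1e-9)

    def test_unreadable_frame_reports_file(self, phantom, tmp_path):
        entries = [
            LabeledEntry("a", str(tmp_path / "missing.png"), "high"),
            LabeledEntry("b", str(tmp_path / "missing2.png"), "low"),
        ]
        fs = LabeledFrameSet(entries=entries)
        with pytest.raises(IOError, match="missing.png"):
            train_quality_model(fs, phantom.reference)


class TestClassify:
    def test_reference_frame_is_gated_low(self, trained_model, reference):
        v, fv = classify(trained_model, reference, reference)
        assert v == 0
        assert fv.contact == 1

    def test_good_contact_frame_is_high_quality(self, trained_model, phantom):
        frame = phantom.render_contact(7.0, seed=99)
        v, fv = classify(trained_model, frame, phantom.reference)
        assert v == 1
        assert fv.contact == 0

    def test_over_compressed_frame_is_low_quality(self, trained_model, phantom):
        frame = phantom.render_contact(19.0, seed=99)
        v, _ = classify(trained_model, frame, phantom.reference)
        assert v == 0

    def test_gate_precedence_over_svm(self, trained_model, phantom):
        """Every no-contact-like render is verdict 0 regardless of what
        the SVM would say about its (f_c, f_n)."""
        for seed in range(20):
            frame = phantom.render_no_contact(seed=seed)
            v, fv = classify(trained_model, frame, phantom.reference)
            assert fv.contact == 1
            assert v == 0

    def test_blank_frame_is_low_quality(self, trained_model, reference):
        blank = np.zeros_like(reference)
        v, fv = classify(trained_model, blank, reference)
        assert v == 0
        assert fv.no_signal

    def test_untrained_model_rejected(self, trained_model, reference):
        import sklearn.base

        untrained = dataclasses.replace(
            trained_model, pipeline=sklearn.base.clone(trained_model.pipeline)
        )
        with pytest.raises(UntrainedModelError):
            classify(untrained, reference, reference)


class TestEvaluate:
    def test_confusion_counts_sum_to_test_size(self, trained_model, phantom):
        dataset = phantom.generate_dataset(n_per_class=25, seed=13)
        report = evaluate(trained_model, dataset, phantom.reference)
        assert report.total == 50
        assert report.accuracy == pytest.approx(
            (report.tp + report.tn) / report.total
        )

    def test_no_contact_frames_labeled_low_score_perfectly_via_gate(
        self, trained_model, phantom
    ):
        frames = [phantom.render_no_contact(seed=s) for s in range(12)]
        fs = _in_memory_set(frames, ["low"] * 12)
        report = evaluate(trained_model, fs, phantom.reference)
        assert report.accuracy == 1.0

    def test_empty_test_set_rejected(self, trained_model, reference):
        with pytest.raises(ValueError, match="empty"):
            evaluate(trained_model, LabeledFrameSet(entries=[]), reference)

    def test_split_is_disjoint_and_sized(self, phantom):
        dataset = phantom.generate_dataset(n_per_class=25, seed=2)
        train_set, test_set = dataset.split(0.8, seed=2)
        assert len(train_set) == 40 and len(test_set) == 10
        assert not (
            {e.frame_id for e in train_set.entries}
            & {e.frame_id for e in test_set.entries}
        )


class TestClassRecovery:
    def test_accuracy_degrades_as_class_separation_vanishes(self):
        """Test accuracy falls monotonically (5-seed mean) from the
        default class gap through abutting regimes to identically
        distributed classes, where it approaches chance."""
        means = []
        for gap, sampler_factory in [(2.0, None), (0.0, None), (2.0, in_band_force_sampler)]:
            cfg = PhantomConfig(class_gap_n=gap)
            phantom = VirtualPhantom(cfg)
            sampler = sampler_factory(cfg) if sampler_factory else None
            accs = []
            for seed in range(5):
                dataset = phantom.generate_dataset(
                    n_per_class=100, seed=100 + seed, force_sampler=sampler
                )
                train_set, test_set = dataset.split(0.8, seed=seed)
                model = train_quality_model(train_set, phantom.reference, seed=seed)
                accs.append(evaluate(model, test_set, phantom.reference).accuracy)
            means.append(np.mean(accs))
        assert means[0] >= 0.9
        assert means[0] > means[1] > means[2]
        assert means[2] <= 0.6


class TestPersistence:
    def test_round_trip_preserves_verdicts(self, trained_model, phantom, tmp_path):
        path = tmp_path / "model.joblib"
        save_model(trained_model, path)
        loaded = load_model(path)
        rng = np.random.default_rng(8)
        for _ in range(50):
            frame = phantom.render_contact(float(rng.uniform(0, 20)), seed=int(rng.integers(2**31)))
            assert classify(loaded, frame, phantom.reference) == classify(
                trained_model, frame, phantom.reference
            )
        assert loaded.metadata == trained_model.metadata

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "nope.joblib")

    def test_corrupt_file_raises_format_error(self, tmp_path):
        path = tmp_path / "junk.joblib"
        path.write_bytes(b"this is not a model")
        with pytest.raises(ModelFormatError):
            load_model(path)

    def test_wrong_format_version_raises_format_error(self, trained_model, tmp_path):
        path = tmp_path / "old.joblib"
        joblib.dump({"format_version": 99, "pipeline": None}, path)
        with pytest.raises(ModelFormatError, match="version 99"):
            load_model(path)


class TestLabeledFrameSet:
    def test_duplicate_ids_rejected(self):
        entries = [
            LabeledEntry("a", "", "high", frame=np.zeros((4, 4), np.uint8)),
            LabeledEntry("a", "", "low", frame=np.zeros((4, 4), np.uint8)),
        ]
        with pytest.raises(ValueError, match="unique"):
            LabeledFrameSet(entries=entries)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            LabeledFrameSet(entries=[LabeledEntry("a", "", "medium")])

    def test_manifest_round_trip(self, phantom, tmp_path):
        dataset = phantom.generate_dataset(n_per_class=3, seed=4, out_dir=tmp_path / "d")
        reloaded = LabeledFrameSet.from_manifest(tmp_path / "d" / "manifest.csv")
        assert [e.frame_id for e in reloaded.entries] == [
            e.frame_id for e in dataset.entries
        ]
        assert reloaded.class_counts == {"high": 3, "low": 3}
        frame = reloaded.entries[0].load(reloaded.root)
        assert frame.dtype == np.uint8
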