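"""Gated SVM quality classifier.

A binary SVM maps the compression and noise features ``(f_c, f_n)`` of
a frame to a quality verdict ``V_svm`` (1 = high quality). The
correlation feature is not an SVM input: it acts as a *gate* — a frame
that correlates with the no-contact reference above ``t_corr`` is
declared low quality outright, because it shows no tissue. Frames with
no supra-threshold pixel at all (``no_signal``) are likewise low
quality.

Features are standardized to zero mean / unit variance on the training
set and the SVM is fit with balanced class weighting, so equal error
costs apply to both classes regardless of counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureConfig, FeatureVector, extract_features
from .frames import load_frame

MODEL_FORMAT_VERSION = 1

VALID_LABELS = ("high", "low")


class ModelFormatError(RuntimeError):
    """A persisted model file is corrupt or of an unknown format version."""


class UntrainedModelError(RuntimeError):
    """classify() was called with a model that has not been fit."""


@dataclass
class LabeledEntry:
    """One labeled frame: id, file path (relative to the set root) and
    subjective label; the pixel array may be attached for in-memory sets."""

    frame_id: str
    path: str
    label: str
    frame: np.ndarray | None = None

    def load(self, root: Path | None) -> np.ndarray:
        if self.frame is not None:
            return self.frame
        path = Path(self.path)
        if root is not None and not path.is_absolute():
            path = root / path
        try:
            return load_frame(path)
        except (FileNotFoundError, ValueError) as exc:
            raise IOError(f"cannot read frame {self.frame_id!r} from {path}: {exc}") from exc


@dataclass
class LabeledFrameSet:
    """A labeled frame collection with a CSV manifest representation."""

    entries: list[LabeledEntry]
    root: Path | None = None

    def __post_init__(self) -> None:
        ids = [e.frame_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("frame_ids must be unique")
        bad = sorted({e.label for e in self.entries} - set(VALID_LABELS))
        if bad:
            raise ValueError(f"labels must be one of {VALID_LABELS}, got {bad}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in VALID_LABELS}
        for e in self.entries:
            counts[e.label] += 1
        return counts

    @classmethod
    def from_manifest(cls, manifest_path: str | Path) -> "LabeledFrameSet":
        manifest_path = Path(manifest_path)
        df = pd.read_csv(manifest_path, dtype=str)
        required = {"frame_id", "path", "label"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"manifest must have columns {sorted(required)}, got {list(df.columns)}"
            )
        entries = [
            LabeledEntry(frame_id=r.frame_id, path=r.path, label=r.label)
            for r in df.itertuples()
        ]
        return cls(entries=entries, root=manifest_path.parent)

    def to_manifest(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(e.frame_id, e.path, e.label) for e in self.entries],
            columns=["frame_id", "path", "label"],
        )
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)

    def split(self, train_frac: float = 0.8, seed: int = 0) -> tuple["LabeledFrameSet", "LabeledFrameSet"]:
        """Seeded uniform split into disjoint train and test sets."""
        if not 0.0 < train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(self.entries))
        n_train = int(round(train_frac * len(self.entries)))
        train = [self.entries[i] for i in sorted(order[:n_train])]
        test = [self.entries[i] for i in sorted(order[n_train:])]
        return (
            LabeledFrameSet(entries=train, root=self.root),
            LabeledFrameSet(entries=test, root=self.root),
        )


@dataclass
class EvaluationReport:
    """Confusion counts and derived rates; 'high' is the positive class."""

    accuracy: float
    tp: int
    tn: int
    fp: int
    fn: int
    precision_high: float
    recall_high: float
    precision_low: float
    recall_low: float

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class QualityModel:
    """Trained gated-SVM quality model.

    ``pipeline`` is the standardizer + SVM fit on (f_c, f_n);
    ``feature_config`` carries the gate threshold and Wiener window used
    at both training and inference time; ``metadata`` records seed,
    counts and hyperparameters for reproducibility.
    """

    pipeline: Pipeline
    feature_config: FeatureConfig
    metadata: dict = field(default_factory=dict)

    @property
    def is_trained(self) -> bool:
        return hasattr(self.pipeline, "classes_") or hasattr(
            self.pipeline.named_steps.get("svm", object()), "classes_"
        )


def _label_to_int(label: str) -> int:
    return 1 if label == "high" else 0


def _feature_matrix(
    frame_set: LabeledFrameSet,
    reference: np.ndarray,
    config: FeatureConfig,
) -> tuple[np.ndarray, np.ndarray, list[FeatureVector]]:
    rows, y, fvs = [], [], []
    for entry in frame_set.entries:
        frame = entry.load(frame_set.root)
        fv = extract_features(frame, reference, config)
        rows.append((fv.compression, fv.noise))
        y.append(_label_to_int(entry.label))
        fvs.append(fv)
    return np.asarray(rows, dtype=np.float64), np.asarray(y, dtype=np.int64), fvs


def train_quality_model(
    train_set: LabeledFrameSet,
    reference: np.ndarray,
    config: FeatureConfig | None = None,
    seed: int = 0,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: str | float = "scale",
) -> QualityModel:
    """Fit the gated SVM on a labeled frame collection.

    Extracts (f_c, f_n) for every frame — correlation is the gate, not
    an SVM input — standardizes them, and fits a balanced binary SVM.
    Deterministic for a fixed seed and training set.
    """
    cfg = config or FeatureConfig()
    counts = train_set.class_counts
    if min(counts.values()) == 0:
        raise ValueError(
            f"training set must contain both classes, got counts {counts}"
        )
    X, y, _ = _feature_matrix(train_set, reference, cfg)
    pipeline = Pipeline(
        [
            ("scaler", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel=kernel,
                    C=C,
                    gamma=gamma,
                    class_weight="balanced",
                    random_state=seed,
                ),
            ),
        ]
    )
    pipeline.fit(X, y)
    train_accuracy = float((pipeline.predict(X) == y).mean())
    metadata = {
        "seed": seed,
        "kernel": kernel,
        "C": C,
        "gamma": gamma,
        "n_train": len(train_set),
        "class_counts": counts,
        "train_accuracy": train_accuracy,
        "scaler_mean": pipeline.named_steps["scaler"].mean_.tolist(),
        "scaler_scale": pipeline.named_steps["scaler"].scale_.tolist(),
    }
    return QualityModel(pipeline=pipeline, feature_config=cfg, metadata=metadata)


def classify(
    model: QualityModel,
    frame: np.ndarray,
    reference: np.ndarray,
) -> tuple[int, FeatureVector]:
    """Quality verdict for one frame.

    The contact gate has precedence: a frame resembling the no-contact
    reference (or a blank/no-signal frame) is low quality without
    consulting the SVM. Otherwise the verdict is the SVM prediction on
    the standardized (f_c, f_n).
    """
    if not hasattr(model.pipeline.named_steps["svm"], "classes_"):
        raise UntrainedModelError("model has not been trained")
    fv = extract_features(frame, reference, model.feature_config)
    if fv.contact == 1 or fv.no_signal:
        return 0, fv
    x = np.array([[fv.compression, fv.noise]], dtype=np.float64)
    v = int(model.pipeline.predict(x)[0])
    return v, fv


def evaluate(
    model: QualityModel,
    test_set: LabeledFrameSet,
    reference: np.ndarray,
) -> EvaluationReport:
    """Accuracy and confusion matrix of gated classification on a test set."""
    if len(test_set) == 0:
        raise ValueError("test set is empty")
    tp = tn = fp = fn = 0
    for entry in test_set.entries:
        frame = entry.load(test_set.root)
        v, _ = classify(model, frame, reference)
        truth = _label_to_int(entry.label)
        if truth == 1 and v == 1:
            tp += 1
        elif truth == 0 and v == 0:
            tn += 1
        elif truth == 0 and v == 1:
            fp += 1
        else:
            fn += 1
    total = tp + tn + fp + fn

    def _safe(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return EvaluationReport(
        accuracy=(tp + tn) / total,
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        precision_high=_safe(tp, tp + fp),
        recall_high=_safe(tp, tp + fn),
        precision_low=_safe(tn, tn + fn),
        recall_low=_safe(tn, tn + fp),
    )


def save_model(model: QualityModel, path: str | Path) -> None:
    """Persist a trained model as a single archive with a format-version field."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "pipeline": model.pipeline,
        "feature_config": asdict(model.feature_config),
        "metadata": model.metadata,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> QualityModel:
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such model file: {path}")
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt archive
        raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelFormatError(f"{path} is not an echoforce model archive")
    version = payload["format_version"]
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model format version {version} not supported (expected {MODEL_FORMAT_VERSION})"
        )
    fc = payload["feature_config"]
    fc["wiener_window"] = tuple(fc["wiener_window"])
    return QualityModel(
        pipeline=payload["pipeline"],
        feature_config=FeatureConfig(**fc),
        metadata=payload["metadata"],
    )
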