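"""Linear support-vector classification of sclerosis presence and side.

A linear-kernel SVM with standard parameters (C = 1, no class weighting)
is trained either as a three-class model (no HS / left HS / right HS,
one-vs-one multiclass) or as a per-hemisphere binary model (HS vs no HS).
Feature standardization is off by default and available as a switch; it
materially affects linear SVMs, so the choice is surfaced rather than
hidden.

Prediction always goes through the model's stored linear weights (the
one-vs-one vote is reproduced explicitly), so a JSON round-trip yields
bit-identical predictions by construction; a test pins the vote to the
underlying library's own predictions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .errors import SchemaError, ValidationError
from .features import LABELS, SubjectFeatures

log = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1
KINDS = ("three_class", "binary_left", "binary_right")
BINARY_LABELS = ("no_HS", "HS")


@dataclass
class TrainedClassifier:
    """A fitted linear SVM bound to a feature-schema identifier."""

    kind: str
    schema_id: str
    classes: list[str]
    coef: np.ndarray        # (n_pairs, n_features); n_pairs = C(k,2)
    intercept: np.ndarray   # (n_pairs,)
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    # -- prediction ---------------------------------------------------------

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.coef.shape[1]:
            raise SchemaError(
                f"feature dimension {X.shape[1]} != model dimension "
                f"{self.coef.shape[1]}"
            )
        if self.scaler_mean is not None:
            X = (X - self.scaler_mean) / self.scaler_scale
        return X

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Pairwise margins (one column per class pair, or one for binary)."""
        X = self._transform(X)
        return X @ self.coef.T + self.intercept

    def predict_matrix(self, X: np.ndarray) -> tuple[list[str], np.ndarray]:
        """Hard classes plus per-class scores for a feature matrix.

        Binary models return the scalar margin toward ``classes[1]``;
        multiclass models return one-vs-rest-style vote scores derived
        from the pairwise margins.
        """
        dec = self.decision_function(X)
        k = len(self.classes)
        if k == 2:
            pred = [self.classes[1] if d > 0 else self.classes[0]
                    for d in dec[:, 0]]
            return pred, dec[:, 0]
        # one-vs-one vote; positive pairwise margin favours the first class
        # of the pair, ties broken by summed margins (library convention)
        n = dec.shape[0]
        votes = np.zeros((n, k))
        conf = np.zeros((n, k))
        pair = 0
        for i in range(k):
            for j in range(i + 1, k):
                votes[:, i] += dec[:, pair] > 0
                votes[:, j] += dec[:, pair] <= 0
                conf[:, i] += dec[:, pair]
                conf[:, j] -= dec[:, pair]
                pair += 1
        scores = votes + conf / (3 * (np.abs(conf).max() + 1))
        pred = [self.classes[int(idx)] for idx in scores.argmax(axis=1)]
        return pred, scores

    def predict_features(self, feats: SubjectFeatures) -> tuple[str, np.ndarray]:
        if feats.schema_id != self.schema_id:
            raise SchemaError(
                f"schema mismatch: features {feats.schema_id!r} vs "
                f"model {self.schema_id!r}"
            )
        pred, scores = self.predict_matrix(np.asarray(feats.values))
        return pred[0], scores[0]

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "kind": self.kind,
            "schema_id": self.schema_id,
            "classes": self.classes,
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "scaler_mean": None if self.scaler_mean is None else self.scaler_mean.tolist(),
            "scaler_scale": None if self.scaler_scale is None else self.scaler_scale.tolist(),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedClassifier":
        p = json.loads(Path(path).read_text())
        if p.get("kind") not in KINDS:
            raise ValidationError(f"{path}: not a classifier model file")
        return cls(
            kind=p["kind"],
            schema_id=p["schema_id"],
            classes=list(p["classes"]),
            coef=np.asarray(p["coef"], dtype=float),
            intercept=np.asarray(p["intercept"], dtype=float),
            scaler_mean=None if p["scaler_mean"] is None
            else np.asarray(p["scaler_mean"], dtype=float),
            scaler_scale=None if p["scaler_scale"] is None
            else np.asarray(p["scaler_scale"], dtype=float),
            metadata=p.get("metadata", {}),
        )


def train(X: np.ndarray, labels: list[str], kind: str, schema_id: str,
          standardize: bool = False, C: float = 1.0,
          seed: int = 0) -> TrainedClassifier:
    """Fit a linear SVM; deterministic given fixed input order and seed."""
    if kind not in KINDS:
        raise ValidationError(f"unknown classifier kind {kind!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValidationError("training labels contain a single class")
    if X.shape[0] < len(classes):
        raise ValidationError("fewer samples than classes")

    scaler_mean = scaler_scale = None
    Xt = X
    if standardize:
        scaler_mean = X.mean(axis=0)
        scaler_scale = X.std(axis=0)
        scaler_scale[scaler_scale == 0] = 1.0
        Xt = (X - scaler_mean) / scaler_scale

    svc = SVC(kernel="linear", C=C, random_state=seed)
    svc.fit(Xt, y)
    model = TrainedClassifier(
        kind=kind,
        schema_id=schema_id,
        classes=list(svc.classes_),
        coef=np.asarray(svc.coef_, dtype=float),
        intercept=np.asarray(svc.intercept_, dtype=float),
        scaler_mean=scaler_mean,
        scaler_scale=scaler_scale,
        metadata={"n_training": int(X.shape[0]), "seed": int(seed), "C": C,
                  "standardize": bool(standardize)},
    )
    return model


def binarize_per_hemisphere(labels: list[str]) -> tuple[list[str], list[str]]:
    """Split three-class labels into per-hemisphere HS / no_HS targets."""
    left, right = [], []
    for lab in labels:
        if lab not in LABELS:
            raise ValidationError(f"unknown label {lab!r}")
        left.append("HS" if lab == "left_HS" else "no_HS")
        right.append("HS" if lab == "right_HS" else "no_HS")
    return left, right
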