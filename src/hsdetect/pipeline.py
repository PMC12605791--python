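"""End-to-end orchestration: segmentation outputs -> features -> prediction.

The pipeline starts from segmentation outputs (subfield volume tables, an
aseg-style stats file for total brain volume, and optionally a coregistered
FLAIR/label NIfTI pair); it never runs segmentation or registration itself.
The modality mode decides which feature schema — and hence which trained
model — applies: volume-only (64 features) or volume+FLAIR (128 features);
modality selection is always explicit, never silently inferred.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .atlas import SubfieldAtlas
from .classify import TrainedClassifier
from .errors import HsDetectError, ValidationError
from .features import (
    SCHEMA_VOL_FLAIR_128,
    SCHEMA_VOL_ONLY_64,
    SubjectFeatures,
    assemble,
)
from .flair import DEFAULT_TARGET_RESOLUTION, DEFAULT_Z_THRESHOLD, compute_flair_block
from .io import (
    SubjectVolumes,
    read_nifti_pair,
    read_subfield_volume_table,
    read_tbv,
    write_zscore_report,
)
from .stats import ClassifierSet, EvalReport, evaluate_external
from .volume import NormalizationModel, compute_volume_block

log = logging.getLogger(__name__)

MODES = ("mprage_only", "mprage_2dflair", "mprage_3dflair")


@dataclass
class SubjectInputs:
    """Paths to one subject's segmentation-derived inputs."""

    subject_id: str
    volumes_left: Path
    volumes_right: Path
    aseg_stats: Path
    flair: Path | None = None
    labels: Path | None = None


@dataclass
class RunConfig:
    """One pipeline run: inputs, modality mode, model, and output options."""

    mode: str = "mprage_only"
    model_path: Path | None = None
    z_threshold: float = DEFAULT_Z_THRESHOLD
    target_resolution_mm: float = DEFAULT_TARGET_RESOLUTION
    output_dir: Path = Path(".")
    seed: int = 0
    log_level: str = "INFO"

    def validate_subject(self, subj: SubjectInputs) -> None:
        if self.mode not in MODES:
            raise ValidationError(f"unknown modality mode {self.mode!r}")
        if self.mode != "mprage_only" and (subj.flair is None or subj.labels is None):
            raise ValidationError(
                f"{subj.subject_id}: mode {self.mode} requires FLAIR and "
                "label volumes"
            )
        if self.mode == "mprage_only" and subj.flair is not None:
            log.warning("%s: FLAIR supplied but mode is mprage_only; ignored",
                        subj.subject_id)

    @property
    def schema_id(self) -> str:
        return SCHEMA_VOL_ONLY_64 if self.mode == "mprage_only" else SCHEMA_VOL_FLAIR_128

    @property
    def flair_kind(self) -> str:
        return {"mprage_only": "none", "mprage_2dflair": "2D",
                "mprage_3dflair": "3D"}[self.mode]


def extract_subject_features(subj: SubjectInputs, config: RunConfig,
                             norm_model: NormalizationModel,
                             atlas: SubfieldAtlas | None = None
                             ) -> SubjectFeatures:
    """Read one subject's inputs and compute the canonical feature vector."""
    atlas = atlas if atlas is not None else SubfieldAtlas.default()
    config.validate_subject(subj)
    hemi_volumes = {
        "left": read_subfield_volume_table(subj.volumes_left, "left"),
        "right": read_subfield_volume_table(subj.volumes_right, "right"),
    }
    tbv = read_tbv(subj.aseg_stats)
    volumes = SubjectVolumes(subj.subject_id, hemi_volumes, tbv)
    log.info("%s: volumes read (TBV %.0f mm^3)", subj.subject_id, tbv)
    vol_block = compute_volume_block(volumes, norm_model)

    flair_block = None
    if config.mode != "mprage_only":
        pair = read_nifti_pair(subj.flair, subj.labels, atlas=atlas)
        flair_block = compute_flair_block(
            pair, atlas, threshold=config.z_threshold,
            target_resolution=config.target_resolution_mm)
        log.info("%s: FLAIR features computed (cortex mu %.1f, sigma %.1f)",
                 subj.subject_id, flair_block.cortex_mu, flair_block.cortex_sigma)
    return assemble(vol_block, flair_block, subject_id=subj.subject_id,
                    flair_kind=config.flair_kind)


def run_subject(subj: SubjectInputs, config: RunConfig,
                norm_model: NormalizationModel,
                model: TrainedClassifier,
                atlas: SubfieldAtlas | None = None) -> tuple[str, Path]:
    """Process one subject: features, prediction, z-score report files."""
    feats = extract_subject_features(subj, config, norm_model, atlas)
    if model.schema_id != feats.schema_id:
        raise ValidationError(
            f"{subj.subject_id}: model schema {model.schema_id} does not "
            f"match mode-implied schema {feats.schema_id}"
        )
    pred, scores = model.predict_features(feats)
    feats.label = pred
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report_path = outdir / f"{subj.subject_id}_zscores.csv"
    write_zscore_report(feats, report_path)
    (outdir / f"{subj.subject_id}_prediction.json").write_text(json.dumps({
        "subject_id": subj.subject_id,
        "prediction": pred,
        "scores": {c: float(s) for c, s in zip(model.classes, np.atleast_1d(scores))},
        "schema_id": feats.schema_id,
        "mode": config.mode,
    }, indent=2))
    log.info("%s: predicted %s", subj.subject_id, pred)
    return pred, report_path


def run_cohort(subjects: list[SubjectInputs], config: RunConfig,
               norm_model: NormalizationModel,
               models: ClassifierSet,
               labels: dict[str, str] | None = None,
               atlas: SubfieldAtlas | None = None
               ) -> tuple[dict[str, str], EvalReport | None, list[str]]:
    """Batch processing with per-subject failure isolation.

    Returns (predictions by subject, evaluation report if labels given,
    list of failed subject ids)."""
    feats_list: list[SubjectFeatures] = []
    predictions: dict[str, str] = {}
    failures: list[str] = []
    for subj in subjects:
        try:
            feats = extract_subject_features(subj, config, norm_model, atlas)
            pred, _ = models.three_class.predict_features(feats)
            feats.label = pred
            predictions[subj.subject_id] = pred
            feats_list.append(feats)
        except (HsDetectError, OSError) as exc:
            log.error("%s: failed (%s); continuing", subj.subject_id, exc)
            failures.append(subj.subject_id)
    if not feats_list:
        raise ValidationError("all subjects failed")

    report = None
    if labels is not None:
        X = np.asarray([f.values for f in feats_list], dtype=float)
        y = [labels[f.subject_id] for f in feats_list]
        report = evaluate_external(models, X, y)
    return predictions, report, failures
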