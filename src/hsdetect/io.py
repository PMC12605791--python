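"""Readers and writers for segmentation outputs, cohort tables, and reports.

All volumes are in mm^3; no unit inference is performed.  Voxel indices are
0-based and world coordinates are reached through the NIfTI affine.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import (
    AGGREGATE_COMPONENTS,
    HEMISPHERES,
    INCLUDED_SUBFIELDS,
    SubfieldAtlas,
    canonical_name,
)
from .errors import ParseError, SchemaError, ValidationError

log = logging.getLogger(__name__)

TBV_MEASURE = "BrainSegVolNotVent"


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class SubjectVolumes:
    """One subject's per-hemisphere subfield volumes plus total brain volume."""

    subject_id: str
    hemi_volumes: dict[str, dict[str, float]]
    tbv: float

    def validate(self) -> None:
        for hemi in HEMISPHERES:
            if hemi not in self.hemi_volumes:
                raise ValidationError(
                    f"{self.subject_id}: hemisphere {hemi!r} missing"
                )
        if self.tbv <= 0:
            raise ValidationError(f"{self.subject_id}: non-positive TBV {self.tbv}")
        for hemi, vols in self.hemi_volumes.items():
            for name, v in vols.items():
                if v <= 0:
                    raise ValidationError(
                        f"{self.subject_id}/{hemi}/{name}: non-positive volume {v}"
                    )
            whole = vols.get("whole-hippocampus")
            if whole is not None:
                for name, v in vols.items():
                    if name == "hippocampal-fissure":
                        continue  # CSF space, not part of the structure
                    if name != "whole-hippocampus" and v > whole * (1 + 1e-9):
                        raise ValidationError(
                            f"{self.subject_id}/{hemi}: component {name} "
                            f"({v}) exceeds whole-hippocampus ({whole})"
                        )


@dataclass
class ImagePair:
    """A FLAIR intensity grid and a subfield label grid sharing a world frame.

    The grids need not share a voxel grid; ``voxel_aligned`` records whether
    they do (resampling produces aligned pairs).
    """

    intensity: np.ndarray
    intensity_affine: np.ndarray
    labels: np.ndarray
    labels_affine: np.ndarray
    cortex_labels: frozenset[int]
    voxel_aligned: bool = False

    def validate(self, atlas: SubfieldAtlas | None = None) -> None:
        for name, aff in (("intensity", self.intensity_affine),
                          ("labels", self.labels_affine)):
            if aff.shape != (4, 4) or not np.all(np.isfinite(aff)):
                raise ValidationError(f"{name} affine is not a finite 4x4 matrix")
            if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
                raise ValidationError(f"{name} affine is singular")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("label grid must hold integer codes")
        if not _world_boxes_overlap(self.intensity.shape, self.intensity_affine,
                                    self.labels.shape, self.labels_affine):
            raise ValidationError(
                "intensity and label grids do not overlap in world space; "
                "check affine units/frames"
            )
        if not np.isin(np.asarray(sorted(self.cortex_labels)), self.labels).any():
            raise ValidationError("label grid contains no cortex voxel")
        if atlas is not None:
            present = set(np.unique(self.labels).tolist())
            for hemi in HEMISPHERES:
                for sf in atlas.included:
                    if not atlas.labels_for(sf, hemi) & present:
                        raise ValidationError(
                            f"label grid has no voxel for {sf}/{hemi}"
                        )


@dataclass
class ReferenceCohort:
    """Healthy-control subfield volumes used to fit the normalization model."""

    rows: list[SubjectVolumes] = field(default_factory=list)

    def validate(self) -> None:
        if len(self.rows) < 3:
            raise ValidationError(
                f"reference cohort needs >= 3 subjects, got {len(self.rows)}"
            )
        for row in self.rows:
            row.validate()


def _world_boxes_overlap(shape_a, aff_a, shape_b, aff_b) -> bool:
    def corners(shape, aff):
        idx = np.array(np.meshgrid(*[[0, s - 1] for s in shape],
                                   indexing="ij")).reshape(3, -1).T
        return nib.affines.apply_affine(aff, idx)

    ca, cb = corners(shape_a, aff_a), corners(shape_b, aff_b)
    return bool(np.all(ca.max(0) >= cb.min(0)) and np.all(cb.max(0) >= ca.min(0)))


# ---------------------------------------------------------------------------
# segmentation-output readers
# ---------------------------------------------------------------------------

def read_subfield_volume_table(
    path: str | Path, hemisphere: str = "left", *, require_included: bool = True
) -> dict[str, float]:
    """Parse a ``<name> <value>`` subfield volume table (one pair per line).

    Names are mapped through the alias table onto the canonical vocabulary;
    unknown names are retained under their raw name and logged.  When
    ``require_included`` is set, all 16 canonical subfields must be present.
    """
    path = Path(path)
    out: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected '<name> <value>', got {line!r}")
        name, raw_val = parts
        try:
            value = float(raw_val)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad volume {raw_val!r}") from exc
        canon = canonical_name(name)
        if canon is None:
            log.warning("%s:%d: unknown subfield name %r retained as-is",
                        path, lineno, name)
            canon = name
        out[canon] = value
    if require_included:
        missing = [s for s in INCLUDED_SUBFIELDS if s not in out]
        if missing:
            raise SchemaError(
                f"{path} ({hemisphere}): missing required subfields: {missing}"
            )
    return out


def read_tbv(path: str | Path) -> float:
    """Extract the whole-brain-without-ventricles volume from a stats file.

    Looks for the ``# Measure BrainSegVolNotVent, ..., <value>, mm^3`` line
    of an aseg-stats-style file.
    """
    path = Path(path)
    pattern = re.compile(rf"^#\s*Measure\s+{TBV_MEASURE}\s*,", re.IGNORECASE)
    for line in path.read_text().splitlines():
        if pattern.match(line):
            parts = [p.strip() for p in line.split(",")]
            for part in reversed(parts):
                try:
                    value = float(part)
                except ValueError:
                    continue
                if value <= 0:
                    raise ValidationError(
                        f"{path}: non-positive {TBV_MEASURE} value {value}"
                    )
                return value
            raise ParseError(f"{path}: no numeric value on measure line {line!r}")
    raise SchemaError(f"{path}: no '# Measure {TBV_MEASURE}' line found")


def read_nifti_pair(
    intensity_path: str | Path,
    labels_path: str | Path,
    cortex_labels: frozenset[int] | set[int] | None = None,
    atlas: SubfieldAtlas | None = None,
) -> ImagePair:
    """Load a coregistered FLAIR intensity / subfield label NIfTI pair."""
    atlas = atlas if atlas is not None else SubfieldAtlas.default()
    if cortex_labels is None:
        cortex_labels = atlas.cortex_labels
    try:
        img_i = nib.load(str(intensity_path))
        img_l = nib.load(str(labels_path))
    except Exception as exc:  # nibabel raises several types here
        raise ValidationError(f"cannot read NIfTI pair: {exc}") from exc
    intensity = np.asarray(img_i.get_fdata(), dtype=np.float64)
    labels_raw = np.asarray(img_l.get_fdata())
    if np.issubdtype(img_l.get_data_dtype(), np.integer):
        labels = np.asarray(img_l.dataobj, dtype=np.int32)
    else:
        if not np.allclose(labels_raw, np.round(labels_raw), atol=1e-6):
            raise ValidationError(f"{labels_path}: label grid holds non-integer values")
        log.warning("%s: float-typed label volume cast to int", labels_path)
        labels = np.round(labels_raw).astype(np.int32)
    pair = ImagePair(
        intensity=intensity,
        intensity_affine=np.asarray(img_i.affine, dtype=float),
        labels=labels,
        labels_affine=np.asarray(img_l.affine, dtype=float),
        cortex_labels=frozenset(cortex_labels),
        voxel_aligned=(
            intensity.shape == labels.shape
            and np.allclose(img_i.affine, img_l.affine, atol=1e-6)
        ),
    )
    pair.validate(atlas=None)
    return pair


def write_nifti_pair(pair: ImagePair, intensity_path: str | Path,
                     labels_path: str | Path) -> None:
    nib.save(nib.Nifti1Image(pair.intensity.astype(np.float32),
                             pair.intensity_affine), str(intensity_path))
    nib.save(nib.Nifti1Image(pair.labels.astype(np.int16),
                             pair.labels_affine), str(labels_path))


# ---------------------------------------------------------------------------
# reference-cohort CSV
# ---------------------------------------------------------------------------

_REF_COLUMNS = ["subject_id", "hemisphere", "subfield", "volume_mm3", "tbv_mm3"]


def write_reference_cohort(cohort: ReferenceCohort, path: str | Path) -> None:
    records = []
    for subj in cohort.rows:
        for hemi, vols in subj.hemi_volumes.items():
            for name, vol in vols.items():
                records.append((subj.subject_id, hemi, name, vol, subj.tbv))
    df = pd.DataFrame.from_records(records, columns=_REF_COLUMNS)
    # repr is the shortest round-trip float form; keeps parse/serialize exact
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_reference_cohort(path: str | Path) -> ReferenceCohort:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _REF_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: reference CSV missing columns {missing}")
    rows: list[SubjectVolumes] = []
    for sid, grp in df.groupby("subject_id", sort=False):
        tbvs = grp["tbv_mm3"].unique()
        if len(tbvs) != 1:
            raise ValidationError(f"{path}: subject {sid} has inconsistent TBV values")
        hemi_volumes: dict[str, dict[str, float]] = {}
        for hemi, hgrp in grp.groupby("hemisphere", sort=False):
            hemi_volumes[str(hemi)] = dict(
                zip(hgrp["subfield"], hgrp["volume_mm3"].astype(float))
            )
        rows.append(SubjectVolumes(str(sid), hemi_volumes, float(tbvs[0])))
    cohort = ReferenceCohort(rows)
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# z-score report
# ---------------------------------------------------------------------------

def write_zscore_report(features, path: str | Path) -> None:
    """Write a subject's raw feature values as CSV plus a JSON sidecar.

    ``features`` is a :class:`~hsdetect.features.SubjectFeatures`.  The CSV
    lists one labelled row per feature (the raw z-scores and ratios a
    reviewer inspects); the JSON repeats them machine-readably together
    with the class prediction when one is present.
    """
    path = Path(path)
    if not features.values or not features.names:
        raise ValidationError("cannot write a report for empty features")
    rows = []
    for name, value in zip(features.names, features.values):
        hemi, subfield, kind = name.split(".")
        rows.append((name, hemi, subfield, kind, value))
    df = pd.DataFrame(rows, columns=["feature", "hemisphere", "subfield",
                                     "kind", "value"])
    df.to_csv(path, index=False)
    payload = {
        "subject_id": features.subject_id,
        "schema_id": features.schema_id,
        "prediction": features.label if features.label != "unknown" else None,
        "flair_kind": features.flair_kind,
        "features": dict(zip(features.names, map(float, features.values))),
    }
    path.with_suffix(".json").write_text(json.dumps(payload, indent=2))
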