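"""Fixed-order feature vectors and dataset assembly.

Each hemisphere contributes, per included subfield, up to four features:
the inverted volume z-score, the volume left-right ratio, the FLAIR
relative z-score, and the FLAIR left-right ratio — 2 x 4 x 16 = 128
features with FLAIR, or 2 x 2 x 16 = 64 from volumetry alone.

The canonical ordering is hemisphere-major (left, right), subfield-middle
(atlas order), kind-minor; feature names are ``<hemi>.<subfield>.<kind>``.
The ordering is versioned through the schema id carried by every trained
model, so a model can never be applied to a differently laid-out vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import HEMISPHERES, INCLUDED_SUBFIELDS
from .errors import SchemaError, ValidationError
from .flair import FlairFeatureBlock
from .volume import VolumeFeatureBlock

log = logging.getLogger(__name__)

SCHEMA_VOL_FLAIR_128 = "vol_flair_128"
SCHEMA_VOL_ONLY_64 = "vol_only_64"

_KINDS_VOL = ("vol-z-atrophy", "vol-lr-ratio")
_KINDS_FLAIR = ("flair-rel-z", "flair-lr-ratio")

LABELS = ("no_HS", "left_HS", "right_HS")


def feature_names(schema_id: str) -> list[str]:
    """Canonical ordered feature names for a schema."""
    if schema_id == SCHEMA_VOL_FLAIR_128:
        kinds = _KINDS_VOL + _KINDS_FLAIR
    elif schema_id == SCHEMA_VOL_ONLY_64:
        kinds = _KINDS_VOL
    else:
        raise SchemaError(f"unknown feature schema {schema_id!r}")
    return [
        f"{hemi}.{sf}.{kind}"
        for hemi in HEMISPHERES
        for sf in INCLUDED_SUBFIELDS
        for kind in kinds
    ]


@dataclass
class SubjectFeatures:
    """One subject's ordered feature vector plus provenance."""

    subject_id: str
    schema_id: str
    names: list[str]
    values: list[float]
    label: str = "unknown"
    flair_kind: str = "none"  # {3D, 2D, none}

    def validate(self) -> None:
        expected = feature_names(self.schema_id)
        if self.names != expected:
            raise SchemaError(
                f"{self.subject_id}: feature names do not match schema "
                f"{self.schema_id}"
            )
        if len(self.values) != len(expected):
            raise SchemaError(
                f"{self.subject_id}: {len(self.values)} values for "
                f"{len(expected)}-feature schema"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.subject_id}: non-finite feature values")


def assemble(volume_block: VolumeFeatureBlock,
             flair_block: FlairFeatureBlock | None = None,
             subject_id: str = "subject",
             label: str = "unknown",
             flair_kind: str | None = None) -> SubjectFeatures:
    """Build the canonical feature vector from computed feature blocks."""
    schema_id = SCHEMA_VOL_ONLY_64 if flair_block is None else SCHEMA_VOL_FLAIR_128
    names = feature_names(schema_id)

    lookup = {
        "vol-z-atrophy": volume_block.z_atrophy,
        "vol-lr-ratio": volume_block.lr_ratio,
    }
    if flair_block is not None:
        lookup["flair-rel-z"] = flair_block.rel_z
        lookup["flair-lr-ratio"] = flair_block.lr_ratio

    values, missing = [], []
    for name in names:
        hemi, sf, kind = name.split(".")
        try:
            values.append(float(lookup[kind][(sf, hemi)]))
        except KeyError:
            missing.append(name)
    if missing:
        raise SchemaError(f"{subject_id}: incomplete feature blocks, "
                          f"missing {missing}")
    if flair_kind is None:
        flair_kind = "none" if flair_block is None else "3D"
    feats = SubjectFeatures(subject_id=subject_id, schema_id=schema_id,
                            names=names, values=values, label=label,
                            flair_kind=flair_kind)
    feats.validate()
    return feats


def build_dataset(subjects: list[SubjectFeatures], schema_id: str
                  ) -> tuple[np.ndarray, list[str], list[str]]:
    """Stack subject vectors into (matrix, labels, feature names)."""
    if not subjects:
        raise ValidationError("empty subject list")
    names = feature_names(schema_id)
    rows = []
    labels = []
    for s in subjects:
        if s.schema_id != schema_id:
            raise SchemaError(
                f"{s.subject_id}: schema {s.schema_id} != dataset schema {schema_id}"
            )
        s.validate()
        rows.append(s.values)
        labels.append(s.label)
    return np.asarray(rows, dtype=float), labels, names


def write_feature_csv(subjects: list[SubjectFeatures], schema_id: str,
                      path: str | Path) -> None:
    """Feature table: one row per subject, label column last, schema id in
    a comment header line."""
    X, labels, names = build_dataset(subjects, schema_id)
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "subject_id", [s.subject_id for s in subjects])
    df["label"] = labels
    with open(path, "w") as fh:
        fh.write(f"# schema_id={schema_id}\n")
        df.to_csv(fh, index=False, float_format=lambda v: repr(float(v)))


def read_feature_csv(path: str | Path) -> list[SubjectFeatures]:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# schema_id="):
        raise SchemaError(f"{path}: missing '# schema_id=' header line")
    schema_id = first.split("=", 1)[1]
    names = feature_names(schema_id)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in ["subject_id", "label", *names] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing[:5]}...")
    subjects = []
    for _, row in df.iterrows():
        subjects.append(SubjectFeatures(
            subject_id=str(row["subject_id"]),
            schema_id=schema_id,
            names=names,
            values=[float(row[n]) for n in names],
            label=str(row["label"]),
        ))
    return subjects


def read_labels_csv(path: str | Path) -> dict[str, str]:
    """Sidecar ``subject_id,label`` table (labels come from histopathology
    or neuroradiology reports, external to imaging)."""
    df = pd.read_csv(path)
    if not {"subject_id", "label"} <= set(df.columns):
        raise SchemaError(f"{path}: needs subject_id,label columns")
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise ValidationError(f"{path}: unknown labels {sorted(bad)}")
    return dict(zip(df["subject_id"].astype(str), df["label"].astype(str)))
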