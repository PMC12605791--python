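"""Head-size correction, reference z-scoring, and left-right volume ratios.

Subfield volumes scale with head size, so each raw volume is corrected by
the covariance method: the slope beta of the volume-on-TBV regression is
estimated in a healthy reference cohort and the subject's volume is shifted
to the reference-mean head size,

    vol_corr = vol_orig - beta * (tbv_orig - tbv_mean).

Corrected volumes are then z-scored against the reference distribution,
z = (vol_corr - mu_NC) / sigma_NC.  Only volume loss carries diagnostic
signal, so negative z-scores are inverted into a non-negative atrophy
marker (z_atrophy = max(-z, 0)) and positive deviations map to 0.
Left-right asymmetry is captured by the ratio of each subfield's corrected
volume to its contralateral counterpart.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .atlas import HEMISPHERES, INCLUDED_SUBFIELDS, contralateral
from .errors import DegenerateDataError, ValidationError
from .io import ReferenceCohort, SubjectVolumes

log = logging.getLogger(__name__)

#: Floor for a non-positive ratio denominator (mm^3); corrected volumes can
#: go non-positive for extreme head sizes and the pipeline must not crash.
RATIO_DENOM_FLOOR = 1.0

MODEL_SCHEMA_VERSION = 1


@dataclass
class NormalizationModel:
    """Per-subfield volume-on-TBV slopes and reference moments.

    Slopes are fitted per subfield *and* per hemisphere; sigma uses the
    sample SD (N-1).  Applying the model to its own reference cohort yields
    z-scores with mean 0 and SD 1 per subfield.
    """

    beta: dict[tuple[str, str], float]
    mu_nc: dict[tuple[str, str], float]
    sigma_nc: dict[tuple[str, str], float]
    tbv_mean: float
    n_reference: int = 0

    def to_json(self, path: str | Path) -> None:
        def flat(d):
            return {f"{h}.{s}": v for (s, h), v in d.items()}

        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "kind": "normalization",
            "tbv_mean": self.tbv_mean,
            "n_reference": self.n_reference,
            "beta": flat(self.beta),
            "mu_nc": flat(self.mu_nc),
            "sigma_nc": flat(self.sigma_nc),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("kind") != "normalization":
            raise ValidationError(f"{path} is not a normalization model file")

        def unflat(d):
            out = {}
            for key, v in d.items():
                hemi, subfield = key.split(".", 1)
                out[(subfield, hemi)] = float(v)
            return out

        return cls(
            beta=unflat(payload["beta"]),
            mu_nc=unflat(payload["mu_nc"]),
            sigma_nc=unflat(payload["sigma_nc"]),
            tbv_mean=float(payload["tbv_mean"]),
            n_reference=int(payload.get("n_reference", 0)),
        )


@dataclass
class VolumeFeatureBlock:
    """Atrophy z-scores and left-right ratios for one subject."""

    z_atrophy: dict[tuple[str, str], float] = field(default_factory=dict)
    lr_ratio: dict[tuple[str, str], float] = field(default_factory=dict)
    z_raw: dict[tuple[str, str], float] = field(default_factory=dict)


def fit_normalization(ref: ReferenceCohort,
                      subfields: tuple[str, ...] = INCLUDED_SUBFIELDS
                      ) -> NormalizationModel:
    """Fit per-subfield OLS slopes and reference moments on healthy controls."""
    ref.validate()
    tbv = np.array([r.tbv for r in ref.rows], dtype=float)
    tbv_mean = float(tbv.mean())
    tbv_var = float(tbv.var(ddof=1))
    if tbv_var <= 0:
        raise DegenerateDataError("reference cohort has zero TBV variance")

    beta, mu_nc, sigma_nc = {}, {}, {}
    centred = tbv - tbv_mean
    denom = float(np.dot(centred, centred))
    for hemi in HEMISPHERES:
        for sf in subfields:
            try:
                vols = np.array([r.hemi_volumes[hemi][sf] for r in ref.rows],
                                dtype=float)
            except KeyError as exc:
                raise ValidationError(
                    f"reference cohort missing {sf}/{hemi} for some subject"
                ) from exc
            b = float(np.dot(centred, vols - vols.mean()) / denom)
            corrected = vols - b * centred
            mu = float(corrected.mean())
            sd = float(corrected.std(ddof=1))
            if sd <= 0:
                raise DegenerateDataError(
                    f"{sf}/{hemi}: corrected reference volumes have zero variance"
                )
            beta[(sf, hemi)] = b
            mu_nc[(sf, hemi)] = mu
            sigma_nc[(sf, hemi)] = sd
    return NormalizationModel(beta=beta, mu_nc=mu_nc, sigma_nc=sigma_nc,
                              tbv_mean=tbv_mean, n_reference=len(ref.rows))


def correct_volume(vol_orig: float, tbv_orig: float, model: NormalizationModel,
                   subfield: str, hemi: str) -> float:
    """Shift a raw volume to the reference-mean head size."""
    return vol_orig - model.beta[(subfield, hemi)] * (tbv_orig - model.tbv_mean)


def volume_zscore(vol_corr: float, model: NormalizationModel,
                  subfield: str, hemi: str) -> tuple[float, float]:
    """Reference z-score and its inverted-negative atrophy marker."""
    sigma = model.sigma_nc[(subfield, hemi)]
    z = (vol_corr - model.mu_nc[(subfield, hemi)]) / sigma
    return z, (-z if z < 0 else 0.0)


def lr_volume_ratio(vol_corr_this: float, vol_corr_contra: float) -> float:
    """This-side over contralateral corrected volume (asymmetry feature)."""
    if vol_corr_contra <= 0:
        log.warning("contralateral corrected volume %.3f <= 0; clamping "
                    "denominator to %.1f mm^3", vol_corr_contra, RATIO_DENOM_FLOOR)
        vol_corr_contra = RATIO_DENOM_FLOOR
    return vol_corr_this / vol_corr_contra


def compute_volume_block(subject: SubjectVolumes, model: NormalizationModel,
                         subfields: tuple[str, ...] = INCLUDED_SUBFIELDS
                         ) -> VolumeFeatureBlock:
    """All volume-derived features for one subject."""
    subject.validate()
    block = VolumeFeatureBlock()
    corrected: dict[tuple[str, str], float] = {}
    for hemi in HEMISPHERES:
        for sf in subfields:
            vol = subject.hemi_volumes[hemi][sf]
            vc = correct_volume(vol, subject.tbv, model, sf, hemi)
            corrected[(sf, hemi)] = vc
            z, z_atr = volume_zscore(vc, model, sf, hemi)
            block.z_raw[(sf, hemi)] = z
            block.z_atrophy[(sf, hemi)] = z_atr
    for hemi in HEMISPHERES:
        for sf in subfields:
            block.lr_ratio[(sf, hemi)] = lr_volume_ratio(
                corrected[(sf, hemi)], corrected[(sf, contralateral(hemi))]
            )
    return block
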