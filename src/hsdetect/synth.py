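"""Synthetic phantom cohorts with controllable sclerosis effects.

Emulates the statistical structure the pipeline assumes: subfield volumes
scale linearly with total brain volume around a healthy baseline; unilateral
sclerosis removes volume from the classic subfield pattern (CA1, CA4,
granule-cell/dentate layer, molecular layer, and hence the whole-structure
aggregates) on the affected side only, in units of the reference SD, and
elevates FLAIR intensity there in units of the cortical SD.  Geometry in
the image phantoms is schematic (shells and boxes) — the features depend
only on label and intensity statistics, not anatomy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .atlas import (
    AGGREGATE_COMPONENTS,
    ATOMIC_INCLUDED,
    DEFAULT_CORTEX_LABEL,
    EXCLUDED_SUBFIELDS,
    HEMISPHERES,
    SubfieldAtlas,
)
from .errors import ValidationError
from .flair import FlairFeatureBlock, lr_flair_ratio, relative_zscore
from .io import ImagePair, ReferenceCohort, SubjectVolumes

log = logging.getLogger(__name__)

#: Healthy baseline subfield volumes (mm^3), one hemisphere; plausible
#: magnitudes for an adult hippocampus (whole structure ~3.5 cm^3).
BASELINE_VOLUMES: dict[str, float] = {
    "CA1-head": 510.0,
    "CA1-body": 130.0,
    "CA3-head": 135.0,
    "CA3-body": 90.0,
    "CA4-head": 135.0,
    "CA4-body": 125.0,
    "subiculum-head": 175.0,
    "subiculum-body": 245.0,
    "molecular-layer-head": 330.0,
    "molecular-layer-body": 245.0,
    "GC-DG-head": 150.0,
    "GC-DG-body": 140.0,
    "hippocampal-tail": 590.0,
    "presubiculum-head": 130.0,
    "presubiculum-body": 160.0,
    "parasubiculum": 60.0,
    "fimbria": 85.0,
    "HATA": 60.0,
    "hippocampal-fissure": 160.0,
}

#: Subfields atrophied/hyperintense on the affected side (the aggregates
#: inherit the effect through summation).
AFFECTED_SUBFIELDS: tuple[str, ...] = (
    "CA1-head", "CA1-body", "CA4-head", "CA4-body",
    "GC-DG-head", "GC-DG-body",
    "molecular-layer-head", "molecular-layer-body",
)


@dataclass
class SyntheticConfig:
    """Study conditions for the generators.

    Counts mirror the cohorts the method was developed on: a reference
    cohort of 256 healthy subjects, and a patient cohort of 36 controls
    plus 18 left- and 18 right-sided sclerosis cases.  Effects are in SD
    units (volume: reference SD; FLAIR: cortical SD).
    """

    n_reference: int = 256
    n_controls: int = 36
    n_left_hs: int = 18
    n_right_hs: int = 18
    tbv_mean: float = 1.15e6
    tbv_sd: float = 1.1e5
    baseline_volumes: dict[str, float] = field(
        default_factory=lambda: dict(BASELINE_VOLUMES))
    slope_true: dict[str, float] | None = None  # default: baseline/tbv_mean
    atrophy_effect: float = 3.0
    hyperintensity_effect: float = 2.0
    noise_sd: float = 0.08  # relative (fraction of baseline volume)
    n_voxels_per_subfield: int = 64
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_reference, self.n_controls,
               self.n_left_hs, self.n_right_hs) < 0:
            raise ValidationError("cohort counts must be >= 0")
        if self.atrophy_effect < 0 or self.hyperintensity_effect < 0:
            raise ValidationError("effects must be >= 0")
        if self.tbv_mean <= 0 or self.tbv_sd < 0 or self.noise_sd < 0:
            raise ValidationError("degenerate TBV/noise configuration")

    def slope(self, subfield: str) -> float:
        if self.slope_true is not None and subfield in self.slope_true:
            return self.slope_true[subfield]
        return self.baseline_volumes[subfield] / self.tbv_mean


def _draw_subject(config: SyntheticConfig, rng: np.random.Generator,
                  subject_id: str, hs_side: str | None) -> SubjectVolumes:
    tbv = float(rng.normal(config.tbv_mean, config.tbv_sd))
    tbv = max(tbv, 0.5 * config.tbv_mean)  # keep physiological
    hemi_volumes: dict[str, dict[str, float]] = {}
    for hemi in HEMISPHERES:
        vols: dict[str, float] = {}
        for sf, base in config.baseline_volumes.items():
            sd = config.noise_sd * base
            v = base + config.slope(sf) * (tbv - config.tbv_mean) \
                + float(rng.normal(0.0, sd))
            if hemi == hs_side and sf in AFFECTED_SUBFIELDS:
                v -= config.atrophy_effect * sd
            vols[sf] = max(v, 1.0)
        for agg, comps in AGGREGATE_COMPONENTS.items():
            vols[agg] = sum(vols[c] for c in comps)
        hemi_volumes[hemi] = vols
    return SubjectVolumes(subject_id, hemi_volumes, tbv)


def make_reference_cohort(config: SyntheticConfig,
                          seed: int | None = None) -> ReferenceCohort:
    """Healthy controls with volume = baseline + slope*(TBV - mean) + noise."""
    config.validate()
    if config.n_reference < 3:
        raise ValidationError("reference cohort needs n_reference >= 3")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = [_draw_subject(config, rng, f"ref{i:04d}", None)
            for i in range(config.n_reference)]
    cohort = ReferenceCohort(rows)
    cohort.validate()
    return cohort


def _simulate_flair_block(config: SyntheticConfig, rng: np.random.Generator,
                          hs_side: str | None) -> FlairFeatureBlock:
    """Per-subfield relative z-scores drawn at the voxel level.

    Voxel z-scores (already cortex-referenced) are ~ N(offset, 0.2) with
    offset = hyperintensity_effect on affected subfields of the affected
    side, 0 elsewhere; with the narrow intra-tissue spread, healthy
    subfields yield relative z-scores near 0 and affected ones near the
    effect size.
    """
    block = FlairFeatureBlock()
    nv = config.n_voxels_per_subfield
    zlists: dict[tuple[str, str], np.ndarray] = {}
    for hemi in HEMISPHERES:
        for sf in ATOMIC_INCLUDED + EXCLUDED_SUBFIELDS:
            offset = (config.hyperintensity_effect
                      if hemi == hs_side and sf in AFFECTED_SUBFIELDS else 0.0)
            zlists[(sf, hemi)] = rng.normal(offset, 0.2, size=nv)
    for hemi in HEMISPHERES:
        for agg, comps in AGGREGATE_COMPONENTS.items():
            zlists[(agg, hemi)] = np.concatenate(
                [zlists[(c, hemi)] for c in comps])
    from .atlas import INCLUDED_SUBFIELDS, contralateral
    for hemi in HEMISPHERES:
        for sf in INCLUDED_SUBFIELDS:
            block.rel_z[(sf, hemi)] = relative_zscore(zlists[(sf, hemi)])
    for hemi in HEMISPHERES:
        for sf in INCLUDED_SUBFIELDS:
            block.lr_ratio[(sf, hemi)] = lr_flair_ratio(
                block.rel_z[(sf, hemi)],
                block.rel_z[(sf, contralateral(hemi))])
    block.cortex_mu, block.cortex_sigma = 100.0, 10.0
    return block


def make_patient_cohort(config: SyntheticConfig, seed: int | None = None
                        ) -> tuple[list[SubjectVolumes],
                                   list[FlairFeatureBlock],
                                   list[str]]:
    """Patient cohort: controls plus left/right HS cases with side-specific
    atrophy and hyperintensity effects."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    plan = ([("no_HS", None)] * config.n_controls
            + [("left_HS", "left")] * config.n_left_hs
            + [("right_HS", "right")] * config.n_right_hs)
    subjects, flair_blocks, labels = [], [], []
    for i, (label, side) in enumerate(plan):
        subjects.append(_draw_subject(config, rng, f"sub{i:04d}", side))
        flair_blocks.append(_simulate_flair_block(config, rng, side))
        labels.append(label)
    return subjects, flair_blocks, labels


# ---------------------------------------------------------------------------
# 3-D image phantom
# ---------------------------------------------------------------------------

PHANTOM_SHAPE = (48, 48, 48)
PHANTOM_CORTEX_MU = 100.0
PHANTOM_CORTEX_SD = 10.0
#: intra-subfield intensity spread, as a fraction of the cortical SD
PHANTOM_TISSUE_SPREAD = 0.2


def make_image_phantom(config: SyntheticConfig, seed: int | None = None,
                       hs_side: str | None = None,
                       atlas: SubfieldAtlas | None = None) -> ImagePair:
    """Small schematic FLAIR/label NIfTI pair.

    A spherical cortical shell surrounds two blocks of 19 labelled boxes
    (one per atomic subfield and hemisphere).  Intensities sit at the
    cortical baseline; affected subfields are raised by
    ``hyperintensity_effect`` cortical SDs.
    """
    config.validate()
    atlas = atlas if atlas is not None else SubfieldAtlas.default()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    shape = PHANTOM_SHAPE
    labels = np.zeros(shape, dtype=np.int32)
    tissue_sd = PHANTOM_TISSUE_SPREAD * PHANTOM_CORTEX_SD
    # unlabeled voxels carry baseline tissue intensity so that trilinear
    # resampling at subfield borders blends toward baseline, not zero
    intensity = rng.normal(PHANTOM_CORTEX_MU, tissue_sd, size=shape)

    centre = np.array(shape) / 2.0 - 0.5
    ii, jj, kk = np.indices(shape)
    r = np.sqrt((ii - centre[0]) ** 2 + (jj - centre[1]) ** 2
                + (kk - centre[2]) ** 2)
    shell = (r >= 19) & (r <= 23)
    cortex_label = next(iter(atlas.cortex_labels))
    labels[shell] = cortex_label
    intensity[shell] = rng.normal(PHANTOM_CORTEX_MU, PHANTOM_CORTEX_SD,
                                  size=int(shell.sum()))

    atoms = ATOMIC_INCLUDED + EXCLUDED_SUBFIELDS
    # two 5x4 grids of 3^3 boxes, one block per hemisphere
    for hemi, x0 in (("left", 13), ("right", 27)):
        for idx, sf in enumerate(atoms):
            gy, gz = divmod(idx, 4)
            sl = (slice(x0, x0 + 3),
                  slice(13 + 4 * gy, 16 + 4 * gy),
                  slice(13 + 4 * gz, 16 + 4 * gz))
            code = atlas.label_map[(sf, hemi)]
            labels[sl] = code
            offset = (config.hyperintensity_effect * PHANTOM_CORTEX_SD
                      if hemi == hs_side and sf in AFFECTED_SUBFIELDS else 0.0)
            intensity[sl] = PHANTOM_CORTEX_MU + offset + rng.normal(
                0.0, tissue_sd, size=labels[sl].shape)

    affine = np.eye(4)
    affine[:3, 3] = -centre  # centre the phantom at the world origin
    pair = ImagePair(
        intensity=intensity,
        intensity_affine=affine,
        labels=labels,
        labels_affine=affine.copy(),
        cortex_labels=atlas.cortex_labels,
        voxel_aligned=True,
    )
    pair.validate(atlas=atlas)
    return pair
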