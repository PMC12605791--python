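"""Cortex-referenced FLAIR hyperintensity features.

Sclerotic hippocampal tissue is hyperintense on FLAIR.  To make intensities
comparable across scanners, each voxel of a subfield is z-scored against the
subject's own cortical intensity distribution,

    z = (I_voxel - mu_cortex) / sigma_cortex,

after resampling the FLAIR image into subfield space at 0.333-mm isotropic
resolution.  The per-subfield hyperintensity burden is the sum of voxelwise
z-scores strictly greater than a threshold (default 1), normalised by the
subfield's total voxel count — the "relative z-score".  Left-right ratios of
relative z-scores capture lateralized signal change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .atlas import HEMISPHERES, INCLUDED_SUBFIELDS, SubfieldAtlas, contralateral
from .errors import DegenerateDataError, SchemaError, ValidationError
from .io import ImagePair

log = logging.getLogger(__name__)

#: Isotropic voxel edge of the subfield analysis grid, mm.
DEFAULT_TARGET_RESOLUTION = 0.333
#: Voxelwise z-score threshold defining "hyperintense".
DEFAULT_Z_THRESHOLD = 1.0
#: Cap for a positive/zero left-right ratio.
DEFAULT_RATIO_CAP = 10.0
#: World-space margin around the subfield bounding box, mm.
BBOX_MARGIN_MM = 2.0


@dataclass
class FlairFeatureBlock:
    """Relative hyperintensity z-scores and left-right ratios per subfield."""

    rel_z: dict[tuple[str, str], float] = field(default_factory=dict)
    lr_ratio: dict[tuple[str, str], float] = field(default_factory=dict)
    cortex_mu: float = float("nan")
    cortex_sigma: float = float("nan")
    z_threshold: float = DEFAULT_Z_THRESHOLD


def resample_to_subfield_space(pair: ImagePair,
                               target_resolution: float = DEFAULT_TARGET_RESOLUTION
                               ) -> ImagePair:
    """Resample intensity (trilinear) and labels (nearest) onto a common
    isotropic grid covering the subfield bounding box plus a margin.

    Cortex voxels are kept wherever they fall inside that box; callers that
    need whole-cortex statistics should take them from the native grid via
    :func:`cortex_stats` before resampling, or use
    :func:`compute_flair_block`, which does so.
    """
    if target_resolution <= 0:
        raise ValidationError(f"target resolution must be > 0, got {target_resolution}")
    subfield_mask = (pair.labels != 0) & ~np.isin(
        pair.labels, np.asarray(sorted(pair.cortex_labels))
    )
    if not subfield_mask.any():
        raise ValidationError("no subfield voxels: empty bounding box")
    idx = np.argwhere(subfield_mask)
    import nibabel as nib
    world = nib.affines.apply_affine(pair.labels_affine, idx)
    lo = world.min(axis=0) - BBOX_MARGIN_MM
    hi = world.max(axis=0) + BBOX_MARGIN_MM
    shape = np.maximum(np.ceil((hi - lo) / target_resolution).astype(int) + 1, 1)
    target_affine = np.eye(4)
    target_affine[:3, :3] = np.eye(3) * target_resolution
    target_affine[:3, 3] = lo

    grid = np.indices(shape).reshape(3, -1).T
    world_pts = nib.affines.apply_affine(target_affine, grid)

    def sample(data, affine, order):
        vox = nib.affines.apply_affine(np.linalg.inv(affine), world_pts).T
        return ndimage.map_coordinates(
            np.asarray(data, dtype=float), vox, order=order, mode="nearest"
        ).reshape(shape)

    intensity = sample(pair.intensity, pair.intensity_affine, order=1)
    labels = sample(pair.labels, pair.labels_affine, order=0).astype(np.int32)
    return ImagePair(
        intensity=intensity,
        intensity_affine=target_affine,
        labels=labels,
        labels_affine=target_affine.copy(),
        cortex_labels=pair.cortex_labels,
        voxel_aligned=True,
    )


def _require_aligned(pair: ImagePair) -> None:
    if not pair.voxel_aligned:
        raise ValidationError(
            "intensity and label grids are not voxel-aligned; "
            "resample_to_subfield_space first"
        )


def cortex_stats(pair: ImagePair) -> tuple[float, float]:
    """Mean and sample SD of FLAIR intensity over the cortex mask."""
    _require_aligned(pair)
    mask = np.isin(pair.labels, np.asarray(sorted(pair.cortex_labels)))
    vals = pair.intensity[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValidationError("cortex mask is empty")
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if sigma <= 0:
        raise DegenerateDataError("cortex intensities have zero variance")
    return mu, sigma


def voxel_zscores(pair: ImagePair, mu: float, sigma: float,
                  subfield: str, hemi: str,
                  atlas: SubfieldAtlas | None = None) -> np.ndarray:
    """Cortex-referenced z-score of every voxel in the subfield's region."""
    if sigma <= 0:
        raise DegenerateDataError("sigma must be > 0")
    _require_aligned(pair)
    atlas = atlas if atlas is not None else SubfieldAtlas.default()
    codes = np.asarray(sorted(atlas.labels_for(subfield, hemi)))
    mask = np.isin(pair.labels, codes)
    if not mask.any():
        raise SchemaError(f"subfield {subfield}/{hemi} absent from label grid")
    vals = pair.intensity[mask]
    finite = np.isfinite(vals)
    if not finite.all():
        log.warning("%s/%s: %d non-finite voxels excluded",
                    subfield, hemi, int((~finite).sum()))
        vals = vals[finite]
    return (vals - mu) / sigma


def relative_zscore(z_list: np.ndarray, threshold: float = DEFAULT_Z_THRESHOLD
                    ) -> float:
    """Sum of z-scores strictly above ``threshold``, over total voxel count."""
    z = np.asarray(z_list, dtype=float)
    if z.size == 0:
        raise ValidationError("cannot compute a relative z-score of an empty region")
    return float(z[z > threshold].sum() / z.size)


def lr_flair_ratio(rel_z_this: float, rel_z_contra: float,
                   cap: float = DEFAULT_RATIO_CAP) -> float:
    """This-side over contralateral relative z-score.

    0/0 maps to the symmetric neutral value 1.0; x/0 with x > 0 is capped.
    """
    if rel_z_contra == 0.0:
        if rel_z_this == 0.0:
            return 1.0
        log.warning("contralateral relative z-score is 0; ratio capped at %g", cap)
        return cap
    return rel_z_this / rel_z_contra


def compute_flair_block(pair: ImagePair,
                        atlas: SubfieldAtlas | None = None,
                        threshold: float = DEFAULT_Z_THRESHOLD,
                        target_resolution: float = DEFAULT_TARGET_RESOLUTION,
                        ratio_cap: float = DEFAULT_RATIO_CAP,
                        resample: bool = True) -> FlairFeatureBlock:
    """All FLAIR-derived features for one subject.

    Cortex statistics are taken on the native-resolution grid (the whole
    cortex, not just the part near the hippocampus); the subfield voxel
    z-scores are then computed on the resampled subfield-space grid.
    """
    atlas = atlas if atlas is not None else SubfieldAtlas.default()
    _require_aligned(pair)
    mu, sigma = cortex_stats(pair)
    work = resample_to_subfield_space(pair, target_resolution) if resample else pair
    block = FlairFeatureBlock(cortex_mu=mu, cortex_sigma=sigma, z_threshold=threshold)
    for hemi in HEMISPHERES:
        for sf in INCLUDED_SUBFIELDS:
            z = voxel_zscores(work, mu, sigma, sf, hemi, atlas)
            block.rel_z[(sf, hemi)] = relative_zscore(z, threshold)
    for hemi in HEMISPHERES:
        for sf in INCLUDED_SUBFIELDS:
            block.lr_ratio[(sf, hemi)] = lr_flair_ratio(
                block.rel_z[(sf, hemi)],
                block.rel_z[(sf, contralateral(hemi))],
                cap=ratio_cap,
            )
    return block
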