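"""Hippocampal-subfield vocabulary and label-code conventions.

The classifier operates on 16 hippocampal subfields per hemisphere; six
further subfields produced by the segmentation (fissure, fimbria, HATA,
presubiculum head/body, parasubiculum) show little cross-group variability
in sclerosis and are excluded.  The order of ``INCLUDED_SUBFIELDS`` is
frozen: it defines the layout of every feature vector, so changing it
invalidates trained models.

Three of the included entries (``whole-head``, ``whole-body``,
``whole-hippocampus``) are aggregates of atomic subfields rather than
label-map regions of their own; :meth:`SubfieldAtlas.labels_for` resolves
them to unions of component label codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import SchemaError

log = logging.getLogger(__name__)

#: The 16 subfields entering the feature vector, in canonical (frozen) order.
INCLUDED_SUBFIELDS: tuple[str, ...] = (
    "CA1-head",
    "CA1-body",
    "CA3-head",
    "CA3-body",
    "CA4-head",
    "CA4-body",
    "subiculum-head",
    "subiculum-body",
    "molecular-layer-head",
    "molecular-layer-body",
    "GC-DG-head",
    "GC-DG-body",
    "hippocampal-tail",
    "whole-head",
    "whole-body",
    "whole-hippocampus",
)

#: Subfields produced by the segmentation but excluded from the features.
EXCLUDED_SUBFIELDS: tuple[str, ...] = (
    "hippocampal-fissure",
    "fimbria",
    "HATA",
    "presubiculum-head",
    "presubiculum-body",
    "parasubiculum",
)

#: Atomic (label-map) members of INCLUDED_SUBFIELDS.
ATOMIC_INCLUDED: tuple[str, ...] = INCLUDED_SUBFIELDS[:13]

#: Aggregate subfields and their atomic components.  The fissure is a CSF
#: space and never counts toward a whole-structure aggregate.
AGGREGATE_COMPONENTS: dict[str, tuple[str, ...]] = {
    "whole-head": (
        "CA1-head", "CA3-head", "CA4-head", "subiculum-head",
        "molecular-layer-head", "GC-DG-head",
        "presubiculum-head", "parasubiculum", "HATA",
    ),
    "whole-body": (
        "CA1-body", "CA3-body", "CA4-body", "subiculum-body",
        "molecular-layer-body", "GC-DG-body",
        "presubiculum-body", "fimbria",
    ),
    # whole-head + whole-body + tail
    "whole-hippocampus": (
        "CA1-head", "CA3-head", "CA4-head", "subiculum-head",
        "molecular-layer-head", "GC-DG-head",
        "presubiculum-head", "parasubiculum", "HATA",
        "CA1-body", "CA3-body", "CA4-body", "subiculum-body",
        "molecular-layer-body", "GC-DG-body",
        "presubiculum-body", "fimbria",
        "hippocampal-tail",
    ),
}

HEMISPHERES: tuple[str, str] = ("left", "right")


def contralateral(hemi: str) -> str:
    if hemi == "left":
        return "right"
    if hemi == "right":
        return "left"
    raise ValueError(f"unknown hemisphere {hemi!r}")


# Upstream segmentation dialects vary across tool versions: head/body-split
# names, underscore variants, and unsplit legacy names.  Keys are matched
# case-insensitively after normalising '_'/'.' to '-'.
NAME_ALIASES: dict[str, str] = {
    # head/body dialect (v22-style)
    "hippocampal-tail": "hippocampal-tail",
    "subiculum-head": "subiculum-head",
    "subiculum-body": "subiculum-body",
    "ca1-head": "CA1-head",
    "ca1-body": "CA1-body",
    "ca3-head": "CA3-head",
    "ca3-body": "CA3-body",
    "ca4-head": "CA4-head",
    "ca4-body": "CA4-body",
    "molecular-layer-hp-head": "molecular-layer-head",
    "molecular-layer-hp-body": "molecular-layer-body",
    "molecular-layer-head": "molecular-layer-head",
    "molecular-layer-body": "molecular-layer-body",
    "gc-ml-dg-head": "GC-DG-head",
    "gc-ml-dg-body": "GC-DG-body",
    "gc-dg-head": "GC-DG-head",
    "gc-dg-body": "GC-DG-body",
    "whole-hippocampal-head": "whole-head",
    "whole-hippocampal-body": "whole-body",
    "whole-hippocampus": "whole-hippocampus",
    "whole-head": "whole-head",
    "whole-body": "whole-body",
    "presubiculum-head": "presubiculum-head",
    "presubiculum-body": "presubiculum-body",
    "parasubiculum": "parasubiculum",
    "fimbria": "fimbria",
    "hata": "HATA",
    "hippocampal-fissure": "hippocampal-fissure",
    # unsplit legacy dialect (v21-style); mapped onto the closest canonical
    # names so old tables still parse, head/body entries simply stay missing
    "ca2-3": "CA3-head",
    "ca2/3": "CA3-head",
}


def canonical_name(raw: str) -> str | None:
    """Map an upstream subfield name onto the canonical vocabulary.

    Returns None for names outside the known dialects (callers keep the
    raw name and flag it).
    """
    key = raw.strip().replace("_", "-").replace(".", "-").lower()
    return NAME_ALIASES.get(key)


# Default label codes follow the FreeSurfer hippocampal-subfield numbering.
# The source paper's pipeline does not print them, so they are overridable.
_DEFAULT_BASE_LABELS: dict[str, int] = {
    "parasubiculum": 203,
    "HATA": 211,
    "fimbria": 212,
    "hippocampal-fissure": 215,
    "hippocampal-tail": 226,
    "presubiculum-head": 233,
    "presubiculum-body": 234,
    "subiculum-head": 235,
    "subiculum-body": 236,
    "CA1-head": 237,
    "CA1-body": 238,
    "CA3-head": 239,
    "CA3-body": 240,
    "CA4-head": 241,
    "CA4-body": 242,
    "GC-DG-head": 243,
    "GC-DG-body": 244,
    "molecular-layer-head": 245,
    "molecular-layer-body": 246,
}

#: Offset added to right-hemisphere label codes when both hemispheres live
#: in one label volume (upstream tools ship one volume per hemisphere).
RIGHT_HEMI_OFFSET = 1000

#: Default label code for the cortical ribbon in phantom label volumes.
DEFAULT_CORTEX_LABEL = 3


@dataclass(frozen=True)
class SubfieldAtlas:
    """Fixed subfield vocabulary plus the label-code map of a label volume.

    ``label_map`` maps ``(subfield, hemisphere)`` to the integer code of
    that atomic subfield; aggregates are resolved through
    :meth:`labels_for`.
    """

    included: tuple[str, ...] = INCLUDED_SUBFIELDS
    excluded: tuple[str, ...] = EXCLUDED_SUBFIELDS
    label_map: dict[tuple[str, str], int] = field(default_factory=dict)
    cortex_labels: frozenset[int] = frozenset({DEFAULT_CORTEX_LABEL})

    def __post_init__(self) -> None:
        if len(self.included) != 16:
            raise SchemaError(
                f"atlas must include exactly 16 subfields, got {len(self.included)}"
            )
        if len(self.excluded) != 6:
            raise SchemaError(
                f"atlas must exclude exactly 6 subfields, got {len(self.excluded)}"
            )
        overlap = set(self.included) & set(self.excluded)
        if overlap:
            raise SchemaError(f"subfields both included and excluded: {sorted(overlap)}")

    @classmethod
    def default(cls) -> "SubfieldAtlas":
        label_map = {}
        for name, code in _DEFAULT_BASE_LABELS.items():
            label_map[(name, "left")] = code
            label_map[(name, "right")] = code + RIGHT_HEMI_OFFSET
        return cls(label_map=label_map)

    def labels_for(self, subfield: str, hemi: str) -> frozenset[int]:
        """Label codes of a subfield (a union for aggregate subfields)."""
        if subfield in AGGREGATE_COMPONENTS:
            comps = AGGREGATE_COMPONENTS[subfield]
        else:
            comps = (subfield,)
        try:
            return frozenset(self.label_map[(c, hemi)] for c in comps)
        except KeyError as exc:
            raise SchemaError(
                f"no label code for subfield {exc.args[0]!r} in atlas"
            ) from exc
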