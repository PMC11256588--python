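"""Region dictionaries: anatomical segmentation codes and the gray-matter
sulcus/cistern atlas.

Anatomical codes follow the FreeSurfer aseg convention so that real
segmentations drop in unchanged (2/41 cerebral WM, 3/42 cortical GM,
4/43 lateral ventricles, 14/15 third/fourth ventricle, 24 CSF used here
for the subarachnoid space).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .grid import VoxelGrid

__all__ = [
    "RegionDef", "GmAtlas", "ANAT",
    "VENTRICLE_CODES", "PARENCHYMA_CODES",
]


class ANAT:
    """Anatomical segmentation label codes (FreeSurfer aseg numbering)."""

    LEFT_WM = 2
    LEFT_GM = 3
    RIGHT_WM = 41
    RIGHT_GM = 42
    LEFT_LATERAL_VENTRICLE = 4
    RIGHT_LATERAL_VENTRICLE = 43
    THIRD_VENTRICLE = 14
    FOURTH_VENTRICLE = 15
    SUBARACHNOID = 24


VENTRICLE_CODES = (
    ANAT.LEFT_LATERAL_VENTRICLE,
    ANAT.RIGHT_LATERAL_VENTRICLE,
    ANAT.THIRD_VENTRICLE,
    ANAT.FOURTH_VENTRICLE,
)

#: cerebral gray + white matter, the intraparenchymal volume codes
PARENCHYMA_CODES = (ANAT.LEFT_WM, ANAT.LEFT_GM, ANAT.RIGHT_WM, ANAT.RIGHT_GM)


@dataclass(frozen=True)
class RegionDef:
    """One labelled region: its code, name, laterality and class."""

    code: int
    name: str
    side: str  # "left" | "right" | "midline"
    region_class: str  # "sulcus" | "cistern" | "ventricle"
    merged_name: str  # bilateral pair name (equals name for midline regions)

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", "midline"):
            raise ValueError(f"bad side {self.side!r} for region {self.name!r}")
        if self.region_class not in ("sulcus", "cistern", "ventricle"):
            raise ValueError(f"bad class {self.region_class!r} for region {self.name!r}")


#: ventricle regions as carried through parcellation (not propagated).
VENTRICLE_REGIONS = {
    ANAT.LEFT_LATERAL_VENTRICLE: RegionDef(
        ANAT.LEFT_LATERAL_VENTRICLE, "lateral_ventricle_left", "left", "ventricle", "lateral_ventricle"),
    ANAT.RIGHT_LATERAL_VENTRICLE: RegionDef(
        ANAT.RIGHT_LATERAL_VENTRICLE, "lateral_ventricle_right", "right", "ventricle", "lateral_ventricle"),
    ANAT.THIRD_VENTRICLE: RegionDef(
        ANAT.THIRD_VENTRICLE, "third_ventricle", "midline", "ventricle", "third_ventricle"),
    ANAT.FOURTH_VENTRICLE: RegionDef(
        ANAT.FOURTH_VENTRICLE, "fourth_ventricle", "midline", "ventricle", "fourth_ventricle"),
}


@dataclass(frozen=True)
class GmAtlas:
    """Sulcus/cistern labels painted on cortical gray matter.

    ``labels`` is zero outside labelled GM; ``regions`` maps each code to
    its :class:`RegionDef`. Every labelled voxel must lie inside
    ``gm_mask`` when one is supplied to :meth:`validate_within`.
    """

    labels: VoxelGrid
    regions: dict[int, RegionDef]

    def __post_init__(self) -> None:
        codes = [r.code for r in self.regions.values()]
        if len(set(codes)) != len(codes):
            raise ValueError("atlas label codes must be unique")
        for code, r in self.regions.items():
            if code != r.code:
                raise ValueError(f"region dict key {code} != RegionDef.code {r.code}")
        present = set(np.unique(self.labels.data)) - {0}
        unknown = present - set(self.regions)
        if unknown:
            raise ValueError(f"atlas grid contains undeclared codes {sorted(unknown)}")

    @property
    def codes(self) -> list[int]:
        return sorted(self.regions)

    def validate_within(self, gm_mask: np.ndarray) -> None:
        """Raise if any atlas voxel falls outside the supplied GM mask."""
        outside = (self.labels.data > 0) & ~np.asarray(gm_mask, bool)
        if outside.any():
            raise ValueError(
                f"{int(outside.sum())} atlas voxels lie outside the gray-matter mask; "
                "the atlas must be restricted to GM before parcellation"
            )

    def to_json(self, path: str | Path) -> None:
        payload = {str(code): asdict(r) for code, r in sorted(self.regions.items())}
        Path(path).write_text(json.dumps(payload, indent=2))

    @staticmethod
    def regions_from_json(path: str | Path) -> dict[int, RegionDef]:
        payload = json.loads(Path(path).read_text())
        return {int(code): RegionDef(**fields) for code, fields in payload.items()}
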