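"""Tissue fractions, the pseudo-T2 contrast and the CSF mask.

The free-water fraction map stands in for the CSF partial volume; white
matter is split off the free-water-corrected FA (cFA) map by a
deterministic two-class clustering; gray matter is the remainder
(1 - CSF - WM). The pseudo-T2 contrast mixes GM and CSF fractions 1:2,
normalised into [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .atlas import ANAT, VENTRICLE_CODES
from .grid import VoxelGrid

__all__ = [
    "TissueFractions", "CsfMask", "DegenerateSegmentationWarning",
    "segment_two_class", "gm_fraction", "pseudo_t2", "csf_mask", "build_fractions",
    "FW_THRESHOLD_DEFAULT", "FW_COMPARATOR_DEFAULT", "fw_compare",
]

#: Free-water threshold selecting CSF-dominated voxels.
FW_THRESHOLD_DEFAULT = 0.8
#: One comparator is shared by the CSF mask and the fit-eligibility rule;
#: "ge" admits voxels at exactly the threshold, "gt" requires strictly more.
FW_COMPARATOR_DEFAULT = "ge"


class DegenerateSegmentationWarning(UserWarning):
    """Two-class segmentation collapsed to a single intensity class."""


def fw_compare(values: np.ndarray, threshold: float, comparator: str = FW_COMPARATOR_DEFAULT) -> np.ndarray:
    if comparator == "ge":
        return np.asarray(values) >= threshold
    if comparator == "gt":
        return np.asarray(values) > threshold
    raise ValueError(f"comparator must be 'ge' or 'gt', got {comparator!r}")


@dataclass(frozen=True)
class TissueFractions:
    """CSF/WM/GM fraction grids; fractions close to 1 at every brain voxel."""

    csf: VoxelGrid
    wm: VoxelGrid
    gm: VoxelGrid
    wm_estimated: bool = True
    n_clipped: int = 0


@dataclass(frozen=True)
class CsfMask:
    """Boolean CSF-space mask and the rule that produced it."""

    mask: VoxelGrid
    threshold: float
    comparator: str

    @property
    def n_voxels(self) -> int:
        return int(np.sum(self.mask.data))


def segment_two_class(
    cfa: VoxelGrid,
    brain_mask: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> VoxelGrid:
    """Soft two-class split of cFA intensities; the higher class is WM.

    Deterministic 2-means on the masked intensities, initialised at the
    10th/90th percentiles, followed by a soft assignment in which each
    voxel's WM fraction is its relative closeness to the WM center.
    Outside the mask the fraction is 0. A constant-intensity input has
    no second class: an all-zero WM fraction is returned with a
    :class:`DegenerateSegmentationWarning`.
    """
    mask = np.asarray(brain_mask, bool)
    vals = np.asarray(cfa.data, dtype=float)[mask]
    wm = np.zeros(cfa.shape, dtype=float)
    if vals.size == 0:
        warnings.warn("empty brain mask: no voxels to segment", DegenerateSegmentationWarning)
        return cfa.like(wm)
    lo, hi = np.percentile(vals, [10.0, 90.0])
    if hi - lo < tol:
        warnings.warn(
            "constant cFA intensities: two-class segmentation is degenerate, "
            "returning an all-zero white-matter fraction",
            DegenerateSegmentationWarning,
        )
        return cfa.like(wm)
    c = np.array([lo, hi])
    for _ in range(max_iter):
        assign = np.abs(vals[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([
            vals[assign == k].mean() if np.any(assign == k) else c[k] for k in (0, 1)
        ])
        if np.max(np.abs(new - c)) < tol:
            c = new
            break
        c = new
    c.sort()
    d_lo = np.abs(vals - c[0])
    d_hi = np.abs(vals - c[1])
    denom = d_lo + d_hi
    soft = np.where(denom > 0, d_lo / np.where(denom > 0, denom, 1.0), 0.5)
    wm[mask] = np.clip(soft, 0.0, 1.0)
    return cfa.like(wm)


def gm_fraction(
    csf: VoxelGrid,
    wm: VoxelGrid,
    brain_mask: np.ndarray | None = None,
    max_inconsistent_fraction: float = 0.01,
) -> tuple[VoxelGrid, int]:
    """Gray-matter fraction as one minus the CSF and WM fractions.

    Clipped to [0, 1]; the number of clipped voxels is returned. If the
    CSF+WM sum exceeds 1 by more than 1e-3 at over
    ``max_inconsistent_fraction`` of the (masked) voxels the inputs are
    inconsistent and an error is raised.
    """
    c = np.asarray(csf.data, float)
    w = np.asarray(wm.data, float)
    mask = np.ones(c.shape, bool) if brain_mask is None else np.asarray(brain_mask, bool)
    total = c + w
    bad = (total > 1.0 + 1e-3) & mask
    n_considered = max(int(mask.sum()), 1)
    if bad.sum() / n_considered > max_inconsistent_fraction:
        raise ValueError(
            f"CSF + WM fractions exceed 1 at {int(bad.sum())} of {n_considered} voxels; "
            "inconsistent input fraction maps"
        )
    raw = 1.0 - total
    gm = np.clip(raw, 0.0, 1.0)
    gm[~mask] = 0.0
    n_clipped = int(np.sum(((raw < 0) | (raw > 1)) & mask))
    return csf.like(gm), n_clipped


def pseudo_t2(gm: VoxelGrid, csf: VoxelGrid) -> VoxelGrid:
    """Pseudo-T2 contrast: GM and CSF fractions mixed 1:2, scaled into [0, 1]."""
    out = (np.asarray(gm.data, float) + 2.0 * np.asarray(csf.data, float)) / 3.0
    return gm.like(out)


def build_fractions(
    free_water: VoxelGrid,
    cfa: VoxelGrid,
    brain_mask: np.ndarray,
    wm: VoxelGrid | None = None,
) -> TissueFractions:
    """Assemble the full fraction triple from free-water and cFA maps.

    A precomputed WM fraction map may be supplied instead of the
    two-class cFA split (``wm_estimated`` records which path was used).
    """
    estimated = wm is None
    if wm is None:
        wm = segment_two_class(cfa, brain_mask)
    gm, n_clipped = gm_fraction(free_water, wm, brain_mask)
    return TissueFractions(free_water, wm, gm, wm_estimated=estimated, n_clipped=n_clipped)


def csf_mask(
    csf_fraction: VoxelGrid,
    anatomical_labels: VoxelGrid,
    threshold: float = FW_THRESHOLD_DEFAULT,
    comparator: str = FW_COMPARATOR_DEFAULT,
) -> CsfMask:
    """CSF-space mask: high free-water voxels inside ventricle/subarachnoid labels."""
    if csf_fraction.shape != anatomical_labels.shape:
        raise ValueError("fraction and label grids differ in shape")
    fw_ok = fw_compare(csf_fraction.data, threshold, comparator)
    label_ok = np.isin(anatomical_labels.data, VENTRICLE_CODES + (ANAT.SUBARACHNOID,))
    mask = fw_ok & label_ok
    if not mask.any():
        raise ValueError(
            "empty CSF mask: "
            f"{int(fw_ok.sum())} voxels pass the free-water rule "
            f"({comparator} {threshold}) and {int(label_ok.sum())} carry a "
            "ventricle/subarachnoid label, but none satisfy both"
        )
    return CsfMask(csf_fraction.like(mask), float(threshold), comparator)
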