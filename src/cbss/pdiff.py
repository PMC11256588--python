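"""Per-voxel pseudodiffusivity fitting and regional median summaries.

At low b-values (<= 200 s/mm^2) CSF signal attenuation is dominated by
intravoxel incoherent motion and is modelled as a single-compartment
isotropic mono-exponential decay

    S(b) = S(0) * exp(-b * D*)

where D* is the pseudodiffusivity (mm^2/s). D* is fitted per voxel by
ordinary least squares of ln S on b over all volumes with b at or below
the cutoff; every gradient direction and every b=0 volume enters as a
separate point (CSF is assumed isotropic, so direction replicates differ
only by noise). Regions are summarised by the median voxel D* (MPD);
left/right regions are combined as the volume-weighted average of the
two sides' medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fractions import FW_COMPARATOR_DEFAULT, FW_THRESHOLD_DEFAULT, fw_compare
from .grid import AcquisitionScheme, DiffusionSeries, VoxelGrid
from .parcellation import CsfParcellation

__all__ = [
    "PdiffMap", "fit_voxel_pdiff", "fit_pdiff_map",
    "region_mpd", "regional_scalar_median", "intraparenchymal_volume",
]


@dataclass(frozen=True)
class PdiffMap:
    """Per-voxel D* over the eligible CSF voxels plus fit diagnostics.

    ``dstar`` is NaN wherever a voxel is ineligible or its fit failed;
    ``r_squared`` and ``n_points`` describe the log-linear fit; the
    eligibility mask records which voxels passed the free-water rule.
    """

    dstar: VoxelGrid
    r_squared: VoxelGrid
    n_points: VoxelGrid
    eligible: VoxelGrid
    n_failed: int = 0

    @property
    def n_eligible(self) -> int:
        return int(np.sum(self.eligible.data))


def _loglinear_fit(signals: np.ndarray, bvals: np.ndarray):
    """Vectorised weighted OLS of ln S on b.

    ``signals``: (n_samples, n_volumes). Non-positive signals are dropped
    pointwise; samples with fewer than 2 distinct b-values remaining are
    marked failed (NaN D*).

    Returns (dstar, s0, r2, n_points, failed) each of shape (n_samples,).
    """
    S = np.asarray(signals, dtype=float)
    b = np.asarray(bvals, dtype=float)
    w = (S > 0) & np.isfinite(S)
    y = np.where(w, np.log(np.where(w, S, 1.0)), 0.0)
    n = w.sum(axis=1)
    # distinct b-values among the surviving points of each sample
    distinct = np.zeros(S.shape[0])
    for bv in np.unique(b):
        distinct += np.any(w & (b == bv)[None, :], axis=1)
    sw = np.maximum(n, 1)
    sx = (w * b).sum(axis=1)
    sy = y.sum(axis=1)
    mx = sx / sw
    my = sy / sw
    sxx = (w * (b - mx[:, None]) ** 2).sum(axis=1)
    sxy = (w * (b - mx[:, None]) * (y - my[:, None])).sum(axis=1)
    failed = distinct < 2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), 0.0)
        intercept = my - slope * mx
        resid = np.where(w, y - (intercept[:, None] + slope[:, None] * b[None, :]), 0.0)
        ss_res = (resid ** 2).sum(axis=1)
        ss_tot = (w * (y - my[:, None]) ** 2).sum(axis=1)
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0), 1.0)
    dstar = np.where(failed, np.nan, -slope)
    s0 = np.where(failed, np.nan, np.exp(intercept))
    r2 = np.where(failed, np.nan, r2)
    return dstar, s0, r2, n, failed


def fit_voxel_pdiff(
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    b_max: float | None = None,
) -> dict:
    """Fit D* for a single voxel's signal vector.

    Returns a dict with ``dstar`` (mm^2/s), ``s0``, ``r_squared``,
    ``n_points`` and ``missing`` (True when fewer than 2 distinct
    b-values survive the positivity filter).
    """
    signals = np.asarray(signals, dtype=float).ravel()
    if signals.size != scheme.n_volumes:
        raise ValueError(
            f"signal vector has {signals.size} entries for {scheme.n_volumes} volumes")
    low = scheme.low_b_mask(b_max)
    d, s0, r2, n, failed = _loglinear_fit(signals[None, low], scheme.bvals[low])
    return {
        "dstar": float(d[0]), "s0": float(s0[0]), "r_squared": float(r2[0]),
        "n_points": int(n[0]), "missing": bool(failed[0]),
    }


def fit_pdiff_map(
    series: DiffusionSeries,
    free_water: VoxelGrid,
    csf_mask: np.ndarray,
    threshold: float = FW_THRESHOLD_DEFAULT,
    comparator: str = FW_COMPARATOR_DEFAULT,
    b_max: float | None = None,
) -> PdiffMap:
    """Fit D* at every eligible CSF voxel of a low-b series.

    Eligibility = CSF-mask membership AND free-water fraction passing
    the shared comparator (default: 0.8 or larger).
    """
    if series.shape != free_water.shape:
        raise ValueError("series and free-water map differ in grid shape")
    eligible = np.asarray(csf_mask, bool) & fw_compare(free_water.data, threshold, comparator)
    low = series.scheme.low_b_mask(b_max)
    dstar = np.full(series.shape, np.nan)
    r2 = np.full(series.shape, np.nan)
    npts = np.zeros(series.shape, dtype=np.int32)
    idx = np.nonzero(eligible)
    n_failed = 0
    if idx[0].size:
        sig = series.data[idx][:, low]
        d, _, r, n, failed = _loglinear_fit(sig, series.scheme.bvals[low])
        dstar[idx] = d
        r2[idx] = r
        npts[idx] = n
        n_failed = int(failed.sum())
    g = free_water
    return PdiffMap(g.like(dstar), g.like(r2), g.like(npts), g.like(eligible), n_failed)


def _median(values: np.ndarray) -> float:
    """Median with the mean-of-middle-two convention for even counts."""
    return float(np.median(values))


def region_mpd(pdiff: PdiffMap, parcellation: CsfParcellation) -> pd.DataFrame:
    """Median pseudodiffusivity per (bilaterally merged) region.

    The median is taken over the voxels of each side separately; paired
    regions are then combined as the volume-weighted average of the two
    sides' medians, the weights being the sides' fitted-voxel volumes.
    Empty regions get NaN MPD and a missing flag.
    """
    if pdiff.dstar.shape != parcellation.labels.shape:
        raise ValueError("pseudodiffusivity map and parcellation differ in grid shape")
    d = pdiff.dstar.data
    labels = parcellation.labels.data
    voxvol = parcellation.labels.voxel_volume_mm3

    per_code: dict[int, tuple[float, int]] = {}
    for code in sorted(parcellation.regions):
        vals = d[labels == code]
        vals = vals[np.isfinite(vals)]
        per_code[code] = (_median(vals) if vals.size else np.nan, int(vals.size))

    by_merged: dict[str, list[int]] = {}
    for code, r in parcellation.regions.items():
        by_merged.setdefault(r.merged_name, []).append(code)

    rows = []
    for merged_name in sorted(by_merged):
        codes = sorted(by_merged[merged_name])
        meds = np.array([per_code[c][0] for c in codes])
        ns = np.array([per_code[c][1] for c in codes])
        present = np.isfinite(meds) & (ns > 0)
        if present.any():
            mpd = float(np.average(meds[present], weights=ns[present]))
        else:
            mpd = np.nan
        n_total = int(ns.sum())
        rows.append({
            "region": merged_name,
            "region_class": parcellation.regions[codes[0]].region_class,
            "mpd": mpd,
            "n_voxels": n_total,
            "volume_mm3": n_total * voxvol,
            "missing": not bool(present.any()),
            "n_sides_present": int(present.sum()),
            "n_sides": len(codes),
        })
    return pd.DataFrame(rows)


def regional_scalar_median(scalar: VoxelGrid, labels: VoxelGrid, codes=None) -> pd.Series:
    """Median of a scalar map over each label; NaN where a label is absent."""
    if scalar.shape != labels.shape:
        raise ValueError("scalar map and label grid differ in shape")
    lab = labels.data
    vals = np.asarray(scalar.data, float)
    if codes is None:
        codes = sorted(set(np.unique(lab)) - {0})
    out = {}
    for code in codes:
        v = vals[lab == code]
        v = v[np.isfinite(v)]
        out[code] = _median(v) if v.size else np.nan
    return pd.Series(out, dtype=float)


def intraparenchymal_volume(
    seg_labels: VoxelGrid,
    codes: tuple[int, ...] = (2, 3, 41, 42),
    icv_mm3: float | None = None,
) -> tuple[float, float | None]:
    """Cerebral gray+white matter volume (mm^3) and, optionally, its
    fraction of the intracranial volume."""
    n = int(np.isin(seg_labels.data, list(codes)).sum())
    volume = n * seg_labels.voxel_volume_mm3
    fraction = None
    if icv_mm3 is not None:
        if icv_mm3 <= 0:
            raise ValueError("intracranial volume must be positive")
        fraction = volume / float(icv_mm3)
    return volume, fraction
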