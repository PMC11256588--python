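"""Pseudodiffusivity fitting and regional median summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import curve_fit

from cbss import PhantomSpec, fit_voxel_pdiff, generate_subject, intraparenchymal_volume, region_mpd, regional_scalar_median
from cbss.grid import VoxelGrid, default_low_b_scheme
from cbss.parcellation import CsfParcellation
from cbss.pdiff import PdiffMap
from cbss.atlas import RegionDef

SCHEME = default_low_b_scheme()


def signals_for(dstar, s0=1000.0):
    return s0 * np.exp(-SCHEME.bvals * dstar)


@pytest.mark.parametrize("dstar", [0.5e-3, 1e-3, 3e-3, 10e-3])
def test_noiseless_exponential_recovered_exactly(dstar):
    res = fit_voxel_pdiff(signals_for(dstar), SCHEME)
    assert res["dstar"] == pytest.approx(dstar, rel=1e-9)
    assert res["s0"] == pytest.approx(1000.0, rel=1e-9)
    assert res["r_squared"] == pytest.approx(1.0, abs=1e-12)
    assert not res["missing"]


def test_constant_signal_gives_zero_dstar():
    res = fit_voxel_pdiff(np.full(SCHEME.n_volumes, 500.0), SCHEME)
    assert res["dstar"] == 0.0


def test_only_low_b_volumes_enter_the_fit():
    # corrupt every volume above the cutoff; the fit must not change
    clean = signals_for(3e-3)
    corrupted = clean.copy()
    corrupted[SCHEME.bvals > 200] = 123.0
    a = fit_voxel_pdiff(clean, SCHEME)
    b = fit_voxel_pdiff(corrupted, SCHEME)
    assert a["dstar"] == b["dstar"]
    assert a["n_points"] == b["n_points"] == int(np.sum(SCHEME.bvals <= 200))


def test_nonpositive_signals_dropped_pointwise():
    sig = signals_for(3e-3)
    k = int(np.argmax(SCHEME.bvals == 110.0))
    sig[k] = -5.0  # one bad point at b=110; two replicates at 110 remain
    res = fit_voxel_pdiff(sig, SCHEME)
    assert res["dstar"] == pytest.approx(3e-3, rel=1e-6)
    assert res["n_points"] == int(np.sum(SCHEME.bvals <= 200)) - 1


def test_too_few_distinct_b_marks_voxel_missing():
    sig = signals_for(3e-3)
    sig[(SCHEME.bvals > 0) & (SCHEME.bvals <= 200)] = -1.0  # only b=0 left
    res = fit_voxel_pdiff(sig, SCHEME)
    assert res["missing"] and np.isnan(res["dstar"])


@given(st.floats(0.1, 10.0))
def test_fit_invariant_under_signal_scaling(scale):
    base = fit_voxel_pdiff(signals_for(2e-3), SCHEME)
    scaled = fit_voxel_pdiff(scale * signals_for(2e-3), SCHEME)
    assert scaled["dstar"] == pytest.approx(base["dstar"], rel=1e-9)


def test_extra_noiseless_point_does_not_move_the_fit():
    import dataclasses
    short = dataclasses.replace(SCHEME, b_max=170.0)
    a = fit_voxel_pdiff(signals_for(3e-3), short)
    b = fit_voxel_pdiff(signals_for(3e-3), SCHEME)  # adds the b=200 triplet
    assert a["dstar"] == pytest.approx(b["dstar"], rel=1e-12)


def test_rician_noise_median_matches_nonlinear_oracle():
    """Log-linear medians agree with a direct 2-parameter exponential
    least-squares fit on the same noisy draws (independent oracle)."""
    rng = np.random.default_rng(8)
    true_d, s0, sigma = 3e-3, 1000.0, 0.02
    n_vox = 1000
    low = SCHEME.bvals <= 200
    b = SCHEME.bvals[low]
    clean = s0 * np.exp(-np.outer(np.full(n_vox, true_d), b))
    noisy = np.sqrt((clean + sigma * s0 * rng.standard_normal(clean.shape)) ** 2
                    + (sigma * s0 * rng.standard_normal(clean.shape)) ** 2)

    from cbss.pdiff import _loglinear_fit
    ours, _, _, _, _ = _loglinear_fit(noisy, b)

    def model(bb, s, d):
        return s * np.exp(-bb * d)

    oracle = np.empty(n_vox)
    for i in range(n_vox):
        popt, _ = curve_fit(model, b, noisy[i], p0=(900.0, 2e-3), maxfev=10000)
        oracle[i] = popt[1]
    assert np.median(ours) == pytest.approx(np.median(oracle), rel=0.02)


def _parcellation_two_sides():
    lab = np.zeros((8, 8, 2), dtype=int)
    lab[:2, :5, 0] = 21  # left: 10 voxels
    lab[4:, :, 0] = 22   # right: ~30 voxels
    lab[0, 0, 1] = 14
    regions = {
        21: RegionDef(21, "sylvian_left", "left", "sulcus", "sylvian"),
        22: RegionDef(22, "sylvian_right", "right", "sulcus", "sylvian"),
        14: RegionDef(14, "third_ventricle", "midline", "ventricle", "third_ventricle"),
    }
    return lab, CsfParcellation(VoxelGrid(lab), regions)


def _pdiff_from(dstar_arr, spacing=(2.0, 2.0, 4.0)):
    g = VoxelGrid(np.asarray(dstar_arr, float), spacing)
    return PdiffMap(g, g.like(np.ones(g.shape)), g.like(np.ones(g.shape, int)),
                    g.like(np.isfinite(g.data)))


def test_median_is_robust_to_outliers():
    lab = np.zeros((3, 1, 1), dtype=int)
    lab[:, 0, 0] = 14
    d = np.array([[[1e-3]], [[2e-3]], [[100e-3]]])
    parc = CsfParcellation(VoxelGrid(lab), {
        14: RegionDef(14, "third_ventricle", "midline", "ventricle", "third_ventricle")})
    tbl = region_mpd(_pdiff_from(d), parc).set_index("region")
    assert tbl.loc["third_ventricle", "mpd"] == pytest.approx(2e-3)


def test_bilateral_mpd_is_volume_weighted_average_of_side_medians():
    lab, parc = _parcellation_two_sides()
    d = np.full(lab.shape, np.nan)
    d[lab == 21] = 2e-3
    d[lab == 22] = 4e-3
    d[lab == 14] = 1e-3
    n_left = int((lab == 21).sum())
    n_right = int((lab == 22).sum())
    tbl = region_mpd(_pdiff_from(d), parc).set_index("region")
    expected = (2e-3 * n_left + 4e-3 * n_right) / (n_left + n_right)
    assert tbl.loc["sylvian", "mpd"] == pytest.approx(expected)
    assert tbl.loc["sylvian", "n_voxels"] == n_left + n_right


def test_paired_region_with_absent_side_uses_present_side():
    lab, parc = _parcellation_two_sides()
    d = np.full(lab.shape, np.nan)
    d[lab == 21] = 2e-3  # right side has no finite values
    d[lab == 14] = 1e-3
    tbl = region_mpd(_pdiff_from(d), parc).set_index("region")
    assert tbl.loc["sylvian", "mpd"] == pytest.approx(2e-3)
    assert tbl.loc["sylvian", "n_sides_present"] == 1
    assert not tbl.loc["sylvian", "missing"]


def test_empty_region_marked_missing():
    lab, parc = _parcellation_two_sides()
    d = np.full(lab.shape, np.nan)
    tbl = region_mpd(_pdiff_from(d), parc).set_index("region")
    assert bool(tbl["missing"].all())


@given(st.permutations(list(range(6))))
def test_mpd_invariant_under_voxel_order_and_bounded(perm):
    vals = np.array([1.0, 2.0, 3.0, 5.0, 8.0, 13.0])[perm] * 1e-3
    lab = np.zeros((6, 1, 1), dtype=int)
    lab[:, 0, 0] = 14
    parc = CsfParcellation(VoxelGrid(lab), {
        14: RegionDef(14, "third_ventricle", "midline", "ventricle", "third_ventricle")})
    tbl = region_mpd(_pdiff_from(vals.reshape(6, 1, 1)), parc)
    mpd = tbl["mpd"].iloc[0]
    assert vals.min() <= mpd <= vals.max()
    assert mpd == pytest.approx(np.median(vals))


def test_end_to_end_noiseless_recovery(noiseless_fitted):
    _, sub, _, parc, pm = noiseless_fitted
    tbl = region_mpd(pm, parc).set_index("region")
    for region, truth in sub.true_dstar.items():
        assert tbl.loc[region, "mpd"] == pytest.approx(truth, rel=1e-9)


def test_noise_shrinks_with_voxel_count():
    """Median-of-fit spread decreases as the region grows (10/100/1000)."""
    rng = np.random.default_rng(4)
    b = SCHEME.bvals[SCHEME.bvals <= 200]
    from cbss.pdiff import _loglinear_fit
    spreads = []
    for n in (10, 100, 1000):
        meds = []
        for _ in range(30):
            clean = 1000.0 * np.exp(-np.outer(np.full(n, 3e-3), b))
            noisy = clean + 20.0 * rng.standard_normal(clean.shape)
            d, *_ = _loglinear_fit(noisy, b)
            meds.append(np.median(d))
        spreads.append(np.std(meds))
    assert spreads[0] > spreads[1] > spreads[2]


def test_regional_scalar_median_conventions():
    lab = np.zeros((2, 2, 1), dtype=int)
    lab[0, :, 0] = 3
    vals = np.array([[[40.0], [60.0]], [[0.0], [0.0]]])
    med = regional_scalar_median(VoxelGrid(vals), VoxelGrid(lab), codes=[3, 42])
    assert med[3] == 50.0  # mean-of-middle-two on even counts
    assert np.isnan(med[42])  # absent label -> missing
    const = regional_scalar_median(VoxelGrid(np.full((2, 2, 1), 50.0)), VoxelGrid(lab))
    assert const[3] == 50.0


def test_intraparenchymal_volume():
    lab = np.zeros((10, 10, 1), dtype=int)
    lab.flat[:100] = 2
    g = VoxelGrid(lab, (2.0, 2.0, 4.0))
    vol, frac = intraparenchymal_volume(g)
    assert vol == 1600.0
    assert frac is None
    assert intraparenchymal_volume(VoxelGrid(np.zeros((3, 3, 3), int)))[0] == 0.0
    vol2, frac2 = intraparenchymal_volume(g, icv_mm3=2000.0)
    assert frac2 == pytest.approx(0.8)
    with pytest.raises(ValueError, match="positive"):
        intraparenchymal_volume(g, icv_mm3=-1.0)
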