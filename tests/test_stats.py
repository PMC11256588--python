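"""Statistics layer: CoV bootstrap, correlations, BH, ACAT, regressions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cbss import (
    acat, adjusted_association, associate_regions, bh_adjust, cohort_bootstrap_acat,
    interregional_correlation, mpd_cbf_profile_correlation, sex_difference,
    voxel_bootstrap_cov, z_transform,
)


# ---------------------------------------------------------------- z-transform

def test_z_transform_centers_and_scales():
    rng = np.random.default_rng(0)
    f = pd.DataFrame({"a": rng.normal(5, 3, 50), "sex": rng.integers(0, 2, 50)})
    z = z_transform(f)
    assert abs(z["a"].mean()) < 1e-9
    assert abs(z["a"].std(ddof=1) - 1.0) < 1e-9
    assert np.array_equal(z["sex"], f["sex"])  # sex untouched


def test_z_transform_rejects_constant_column():
    with pytest.raises(ValueError, match="constant"):
        z_transform(pd.DataFrame({"a": [1.0, 1.0, 1.0]}))


# ------------------------------------------------------------- CoV bootstrap

def test_cov_zero_for_constant_region():
    assert voxel_bootstrap_cov(np.full(50, 3e-3), seed=1) == 0.0


def test_cov_deterministic_under_seed():
    vals = np.random.default_rng(3).normal(3e-3, 5e-4, 200)
    assert voxel_bootstrap_cov(vals, seed=9) == voxel_bootstrap_cov(vals, seed=9)
    assert voxel_bootstrap_cov(vals, seed=9) != voxel_bootstrap_cov(vals, seed=10)


def test_cov_against_high_rep_oracle():
    """Default-rep CoV falls inside the Monte-Carlo interval of its own
    sampling distribution, located by an independent 1e5-rep oracle."""
    vals = np.concatenate([np.ones(60), 2.0 * np.ones(40)])

    # independent oracle: legacy RandomState + permutation-based draws
    rs = np.random.RandomState(1234)
    m = int(np.floor(0.95 * vals.size))
    meds = np.empty(100_000)
    for i in range(100_000):
        meds[i] = np.median(vals[rs.permutation(vals.size)[:m]])
    oracle = meds.std(ddof=1) / meds.mean()

    covs = np.array([voxel_bootstrap_cov(vals, reps=100, seed=s) for s in range(200)])
    lo, hi = np.percentile(covs, [2.5, 97.5])
    assert lo <= oracle <= hi


# ---------------------------------------------------- correlation matrix + BH

def test_identical_columns_correlate_perfectly():
    rng = np.random.default_rng(1)
    x = rng.normal(size=30)
    f = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=30)})
    R, P, Padj = interregional_correlation(f)
    assert R.loc["a", "b"] == pytest.approx(1.0)
    assert P.loc["a", "b"] < 1e-20
    assert np.allclose(np.diag(R), 1.0)
    assert np.allclose(R.values, R.values.T, equal_nan=True)


def test_constant_column_pairs_undefined():
    f = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0, 4.0]})
    R, P, _ = interregional_correlation(f)
    assert np.isnan(R.loc["a", "b"]) and np.isnan(P.loc["a", "b"])


def test_bh_matches_hand_stepup_on_fixture():
    # independent step-up: p_(i) * m / i, then a reverse cumulative min
    p = np.array([0.01, 0.02, 0.03, 0.04])
    m = len(p)
    scaled = np.sort(p) * m / np.arange(1, m + 1)
    hand = np.minimum.accumulate(scaled[::-1])[::-1]
    assert np.allclose(hand, 0.04)
    assert np.allclose(bh_adjust(p), hand)


@given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=12))
def test_bh_adjusted_never_below_raw_and_monotone(ps):
    p = np.array(ps)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)  # step-up monotonicity


def test_pearson_type_one_error_near_nominal():
    """On independent normals (n=93) the raw Pearson p rejects at ~5%."""
    from scipy import stats as sps
    rng = np.random.default_rng(7)
    n_sims, n = 1000, 93
    hits = 0
    for _ in range(n_sims):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        hits += sps.pearsonr(x, y)[1] < 0.05
    rate = hits / n_sims
    tol = 2 * np.sqrt(0.05 * 0.95 / n_sims)
    assert abs(rate - 0.05) <= tol


# ------------------------------------------------------------------- ACAT

def test_acat_identity_and_center():
    assert acat([0.2]) == pytest.approx(0.2, abs=1e-12)
    assert acat([0.5, 0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)


def test_acat_matches_arbitrary_precision_evaluation():
    import sympy

    ps = [0.01, 0.04, 0.6]
    T = sum(sympy.tan((sympy.Rational(1, 2) - sympy.Rational(p)) * sympy.pi)
            for p in ps) / 3
    expected = float(sympy.N(sympy.Rational(1, 2) - sympy.atan(T) / sympy.pi, 50))
    assert acat(ps) == pytest.approx(expected, rel=1e-12)


def test_acat_clamps_degenerate_pvalues():
    assert 0.0 < acat([0.0, 0.5]) < 1.0
    assert 0.0 < acat([1.0, 0.5]) < 1.0
    with pytest.raises(ValueError):
        acat([])
    with pytest.raises(ValueError):
        acat([1.5])


@given(st.lists(st.floats(1e-6, 1 - 1e-6), min_size=1, max_size=10),
       st.randoms(use_true_random=False))
def test_acat_in_unit_interval_and_permutation_invariant(ps, rnd):
    combined = acat(ps)
    assert 0.0 < combined < 1.0
    shuffled = list(ps)
    rnd.shuffle(shuffled)
    assert acat(shuffled) == pytest.approx(combined, rel=1e-12)


def test_cohort_bootstrap_acat_deterministic():
    rng = np.random.default_rng(5)
    f = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
    out1 = cohort_bootstrap_acat(f, seed=3)
    out2 = cohort_bootstrap_acat(f, seed=3)
    pd.testing.assert_frame_equal(out1, out2)
    assert len(out1) == 3  # all unique pairs
    assert ((out1["p_acat"] > 0) & (out1["p_acat"] < 1)).all()
    with pytest.raises(ValueError, match="replicate"):
        cohort_bootstrap_acat(f, reps=0)


# ------------------------------------------------------- adjusted association

def test_outcome_equal_to_predictor():
    rng = np.random.default_rng(2)
    x = rng.normal(size=40)
    f = z_transform(pd.DataFrame({"x": x, "y": x}), exclude=())
    res = adjusted_association(f, "x", "y")
    assert res.slope == pytest.approx(1.0, abs=1e-12)
    assert res.p_value < 1e-30


def test_collinear_covariate_rejected():
    rng = np.random.default_rng(2)
    x = rng.normal(size=40)
    f = pd.DataFrame({"x": x, "y": rng.normal(size=40), "cov": x})
    with pytest.raises(ValueError, match="collinear"):
        adjusted_association(f, "x", "y", ("cov",))


def test_standardized_simple_slope_equals_pearson_r():
    rng = np.random.default_rng(6)
    f = pd.DataFrame({"x": rng.normal(size=60), "y": rng.normal(size=60)})
    zf = z_transform(f, exclude=())
    res = adjusted_association(zf, "x", "y")
    assert res.slope == pytest.approx(res.r, abs=1e-12)


def test_slope_recovery_monte_carlo():
    """y = 0.4 x + e with Var(e) = 0.84: mean estimate over 200
    replicates at n=500 recovers 0.40 within 0.05."""
    rng = np.random.default_rng(11)
    est = []
    for _ in range(200):
        x = rng.standard_normal(500)
        y = 0.4 * x + np.sqrt(0.84) * rng.standard_normal(500)
        f = z_transform(pd.DataFrame({"x": x, "y": y}), exclude=())
        est.append(adjusted_association(f, "x", "y").slope)
    assert np.mean(est) == pytest.approx(0.40, abs=0.05)


def test_associate_regions_bh_family_is_per_outcome():
    rng = np.random.default_rng(3)
    f = pd.DataFrame(rng.normal(size=(50, 4)), columns=["r1", "r2", "r3", "out"])
    zf = z_transform(f, exclude=())
    tbl = associate_regions(zf, ["r1", "r2", "r3"], "out")
    assert len(tbl) == 3
    assert np.allclose(tbl["p_adjusted"], bh_adjust(tbl["p_value"].to_numpy()))
    assert (tbl["p_adjusted"] >= tbl["p_value"] - 1e-12).all()


def test_insufficient_rows_rejected():
    f = pd.DataFrame({"x": [0.1, 0.2, 0.3], "y": [1.0, 2.0, 1.5], "c": [1.0, 0.0, 2.0]})
    with pytest.raises(ValueError, match="degrees of freedom"):
        adjusted_association(f, "x", "y", ("c",))


# --------------------------------------------------------------- rank tests

def test_wilcoxon_exact_on_separated_triplets():
    f = pd.DataFrame({"mpd": [1, 2, 3, 4, 5, 6], "sex": [0, 0, 0, 1, 1, 1]})
    stat, p = sex_difference(f, "mpd")
    # oracle: exhaustive enumeration of every C(6,3)=20 assignment
    vals = np.array([1, 2, 3, 4, 5, 6], float)
    observed = vals[:3].sum()
    ranks = vals  # values are their own ranks here
    sums = [ranks[list(c)].sum() for c in itertools.combinations(range(6), 3)]
    center = np.mean(sums)
    extreme = np.mean([abs(s - center) >= abs(observed - center) for s in sums])
    assert extreme == pytest.approx(0.1)
    assert p == pytest.approx(0.1)


def test_identical_groups_give_null_pvalue():
    f = pd.DataFrame({"mpd": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0], "sex": [0, 0, 0, 1, 1, 1]})
    _, p = sex_difference(f, "mpd")
    assert p == pytest.approx(1.0)


def test_wilcoxon_symmetric_under_label_swap():
    rng = np.random.default_rng(8)
    f = pd.DataFrame({"mpd": rng.normal(size=20), "sex": [0] * 10 + [1] * 10})
    g = f.copy()
    g["sex"] = 1 - g["sex"]
    assert sex_difference(f, "mpd")[1] == sex_difference(g, "mpd")[1]


def test_one_empty_group_rejected():
    f = pd.DataFrame({"mpd": [1.0, 2.0], "sex": [0, 0]})
    with pytest.raises(ValueError, match="both sexes"):
        sex_difference(f, "mpd")


# ------------------------------------------------------- MPD-CBF profiles

def _profile_frame(cbf_fn):
    mpds = np.array([[2.0, 3.0, 4.0, 5.0], [1.0, 4.0, 2.0, 6.0]])
    rows = []
    for i, m in enumerate(mpds):
        row = {"age": 60.0 + 10 * i}
        for j, v in enumerate(m):
            row[f"mpd_r{j}"] = v
            row[f"cbf_mpd_r{j}"] = cbf_fn(v)
        rows.append(row)
    return pd.DataFrame(rows)


def test_proportional_profiles_give_unit_correlation():
    f = _profile_frame(lambda v: 2.0 * v)
    rs, assoc = mpd_cbf_profile_correlation(f, [f"mpd_r{j}" for j in range(4)])
    assert np.allclose(rs, 1.0)
    assert assoc is None  # constant per-subject R: age association degenerate
    f2 = _profile_frame(lambda v: -v)
    rs2, _ = mpd_cbf_profile_correlation(f2, [f"mpd_r{j}" for j in range(4)])
    assert np.allclose(rs2, -1.0)


def test_too_few_regions_marks_subject_missing():
    f = _profile_frame(lambda v: 2.0 * v)
    f.loc[0, ["cbf_mpd_r0", "cbf_mpd_r1"]] = np.nan  # only 2 pairs left
    rs, _ = mpd_cbf_profile_correlation(f, [f"mpd_r{j}" for j in range(4)])
    assert np.isnan(rs.iloc[0]) and rs.iloc[1] == pytest.approx(1.0)


def test_planted_age_coupling_recovered():
    """Cohort with an age-increasing MPD-CBF coupling yields a positive
    age slope on the per-subject profile correlations."""
    from cbss import PhantomSpec, generate_cohort
    from cbss.phantom import PHANTOM_ATLAS_REGIONS

    spec = PhantomSpec(cohort_size=80, seed=17, noise_model="none",
                       cbf_coupling_base=0.2, cbf_age_coupling=0.6)
    subjects, table = generate_cohort(spec)
    merged = sorted({r.merged_name for r in PHANTOM_ATLAS_REGIONS.values()})
    rows = []
    for s in subjects:
        lab = s.atlas.labels.data
        row = {"age": s.covariates["age"]}
        for m in merged:
            codes = [c for c, r in PHANTOM_ATLAS_REGIONS.items() if r.merged_name == m]
            row[f"mpd_{m}"] = s.true_dstar[m]
            row[f"cbf_mpd_{m}"] = float(np.median(s.cbf.data[np.isin(lab, codes)]))
        rows.append(row)
    f = pd.DataFrame(rows)
    rs, assoc = mpd_cbf_profile_correlation(f, [f"mpd_{m}" for m in merged])
    assert assoc.slope > 0
    assert assoc.p_value < 0.05
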