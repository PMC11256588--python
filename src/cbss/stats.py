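"""Cohort statistics over regional pseudodiffusivity tables.

Implements the analysis battery run on the subjects x regions table:

* voxel-subsampling reproducibility (coefficient of variation of the
  regional median over 100 draws of 95% of the voxels);
* inter-regional Pearson correlation with Benjamini-Hochberg control
  over all unique region pairs, plus a cohort bootstrap whose
  replicate p-values are combined by the aggregated Cauchy association
  test (ACAT);
* covariate-adjusted linear associations between regional MPD and
  cognition (all continuous variables z-transformed; sex kept binary
  and assessed by the Wilcoxon rank-sum test), BH-corrected across
  regions per outcome;
* per-participant MPD-CBF profile correlations and their association
  with age.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "z_transform",
    "voxel_bootstrap_cov",
    "interregional_correlation",
    "acat",
    "cohort_bootstrap_acat",
    "adjusted_association",
    "associate_regions",
    "sex_difference",
    "mpd_cbf_profile_correlation",
    "bh_adjust",
]


@dataclass(frozen=True)
class AssociationResult:
    """One covariate-adjusted association between a predictor and an outcome."""

    predictor: str
    outcome: str
    slope: float  # standardized regression slope of the predictor
    r: float  # marginal Pearson correlation on the rows used
    p_value: float
    n_used: int
    covariates: tuple[str, ...] = ()
    p_adjusted: float | None = None


def z_transform(frame: pd.DataFrame, exclude: tuple[str, ...] = ("sex",)) -> pd.DataFrame:
    """Z-score every numeric column except the excluded ones.

    Mean and standard deviation are taken over non-missing entries; a
    constant column raises (its z-score is undefined).
    """
    out = frame.copy()
    for col in frame.columns:
        if col in exclude or not pd.api.types.is_numeric_dtype(frame[col]):
            continue
        vals = frame[col].astype(float)
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} is constant; z-transform undefined")
        out[col] = (vals - vals.mean()) / sd
    return out


def voxel_bootstrap_cov(
    values: np.ndarray,
    subsample: float = 0.95,
    reps: int = 100,
    seed: int | np.random.Generator = 0,
) -> float:
    """Reproducibility of a regional median under voxel subsampling.

    Draws ``reps`` subsets of ``floor(subsample * n)`` voxels without
    replacement, recomputes the median for each, and returns the
    coefficient of variation (sd / mean) of the replicate medians.
    """
    vals = np.asarray(values, float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return np.nan
    m = int(np.floor(subsample * vals.size))
    if m < 1:
        raise ValueError("subsample fraction leaves no voxels")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    meds = np.empty(reps)
    for i in range(reps):
        meds[i] = np.median(rng.choice(vals, size=m, replace=False))
    mean = meds.mean()
    if mean == 0:
        raise ValueError("mean of replicate medians is zero; CoV undefined")
    return float(meds.std(ddof=1) / mean)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(pvalues, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def interregional_correlation(frame: pd.DataFrame, min_pairs: int = 3):
    """Pearson correlation between every pair of regional MPD columns.

    Missing values are handled pairwise-complete. BH adjustment treats
    all unique off-diagonal pairs as one family. Pairs involving a
    constant column are left undefined (NaN).

    Returns (R, p_raw, p_adj) as symmetric DataFrames with unit diagonal.
    """
    cols = list(frame.columns)
    k = len(cols)
    R = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    P = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    np.fill_diagonal(P.values, 0.0)
    pairs = list(itertools.combinations(range(k), 2))
    raw = []
    for i, j in pairs:
        sub = frame.iloc[:, [i, j]].dropna()
        if len(sub) < min_pairs:
            raise ValueError(
                f"fewer than {min_pairs} complete pairs for "
                f"({cols[i]!r}, {cols[j]!r})")
        x, y = sub.iloc[:, 0].to_numpy(float), sub.iloc[:, 1].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = sps.pearsonr(x, y)
        R.iloc[i, j] = R.iloc[j, i] = r
        P.iloc[i, j] = P.iloc[j, i] = p
        raw.append(p)
    adj = bh_adjust(np.array(raw))
    Padj = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    np.fill_diagonal(Padj.values, 0.0)
    for (i, j), a in zip(pairs, adj):
        Padj.iloc[i, j] = Padj.iloc[j, i] = a
    return R, P, Padj


def acat(pvalues: np.ndarray, eps: float = 1e-15) -> float:
    """Aggregated Cauchy association test with equal weights.

    T = mean(tan((0.5 - p_i) * pi)); combined p = 0.5 - arctan(T) / pi.
    Exact 0 or 1 inputs are clamped to [eps, 1 - eps]. The transform is
    the identity for a single p-value and returns 0.5 when every input
    is 0.5.
    """
    p = np.asarray(pvalues, float).ravel()
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    p = np.clip(p, eps, 1.0 - eps)
    T = np.mean(np.tan((0.5 - p) * np.pi))
    return float(0.5 - np.arctan(T) / np.pi)


def cohort_bootstrap_acat(
    frame: pd.DataFrame,
    subsample: float = 0.95,
    reps: int = 10,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Robustness bootstrap of the pairwise MPD correlations.

    Each replicate draws ``floor(subsample * n)`` subjects without
    replacement and recomputes every pairwise Pearson correlation. Per
    pair, the replicate correlations are averaged and the replicate
    p-values combined with ACAT.
    """
    if reps < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(frame)
    m = int(np.floor(subsample * n))
    if m < 3:
        raise ValueError("subsample leaves fewer than 3 subjects")
    cols = list(frame.columns)
    pairs = list(itertools.combinations(cols, 2))
    rs = {pair: [] for pair in pairs}
    ps = {pair: [] for pair in pairs}
    for _ in range(reps):
        take = rng.choice(n, size=m, replace=False)
        sub = frame.iloc[take]
        for a, b in pairs:
            s = sub[[a, b]].dropna()
            r, p = sps.pearsonr(s[a].to_numpy(float), s[b].to_numpy(float))
            rs[(a, b)].append(r)
            ps[(a, b)].append(p)
    rows = []
    for pair in pairs:
        rows.append({
            "region_a": pair[0], "region_b": pair[1],
            "mean_r": float(np.mean(rs[pair])),
            "p_acat": acat(np.array(ps[pair])),
            "n_reps": reps,
        })
    return pd.DataFrame(rows)


def adjusted_association(
    frame: pd.DataFrame,
    predictor: str,
    outcome: str,
    covariates: tuple[str, ...] = (),
) -> AssociationResult:
    """OLS of outcome on predictor plus covariates; rows with any missing
    value among the used columns are dropped (listwise deletion).

    The reported slope is the coefficient of the predictor (standardized
    when the frame has been z-transformed); ``r`` is the marginal
    Pearson correlation between predictor and outcome on the same rows.
    """
    import statsmodels.api as sm

    cols = [outcome, predictor, *covariates]
    sub = frame[cols].dropna()
    n = len(sub)
    if n <= len(covariates) + 2:
        raise ValueError(
            f"only {n} complete rows for {len(covariates)} covariates; "
            "not enough degrees of freedom")
    X = sm.add_constant(sub[[predictor, *covariates]].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"collinear design for predictor {predictor!r} with covariates "
            f"{list(covariates)}")
    fit = sm.OLS(sub[outcome].astype(float), X).fit()
    r, _ = sps.pearsonr(sub[predictor].astype(float), sub[outcome].astype(float))
    return AssociationResult(
        predictor=predictor,
        outcome=outcome,
        slope=float(fit.params[predictor]),
        r=float(r),
        p_value=float(fit.pvalues[predictor]),
        n_used=n,
        covariates=tuple(covariates),
    )


def associate_regions(
    frame: pd.DataFrame,
    predictors: list[str],
    outcome: str,
    covariates: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Run :func:`adjusted_association` per region and BH-adjust across
    regions for this outcome (the multiplicity family)."""
    results = [adjusted_association(frame, p, outcome, covariates) for p in predictors]
    adj = bh_adjust(np.array([r.p_value for r in results]))
    rows = []
    for res, a in zip(results, adj):
        rows.append({
            "predictor": res.predictor, "outcome": res.outcome,
            "slope": res.slope, "r": res.r, "p_value": res.p_value,
            "p_adjusted": float(a), "n_used": res.n_used,
            "covariates": ",".join(res.covariates),
        })
    return pd.DataFrame(rows)


def sex_difference(frame: pd.DataFrame, region: str, sex_col: str = "sex", exact_max_n: int = 25):
    """Two-sided Wilcoxon rank-sum test of regional MPD between sexes.

    Uses the exact null distribution when both groups have at most
    ``exact_max_n`` observations and there are no ties; otherwise the
    tie-corrected normal approximation.
    """
    sub = frame[[region, sex_col]].dropna()
    groups = [g[region].to_numpy(float) for _, g in sub.groupby(sex_col)]
    if len(groups) != 2 or any(len(g) == 0 for g in groups):
        raise ValueError("both sexes must be present with at least one observation")
    x, y = groups
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mpd_cbf_profile_correlation(
    frame: pd.DataFrame,
    regions: list[str],
    cbf_prefix: str = "cbf_",
    age_col: str = "age",
    min_regions: int = 3,
) -> tuple[pd.Series, AssociationResult | None]:
    """Per-participant correlation between the regional MPD profile and
    the matched regional CBF profile, then its association with age.

    For each subject, Pearson R is computed across the selected regions
    between MPD and CBF; subjects with fewer than ``min_regions``
    complete region pairs are missing. The resulting per-subject R is
    associated with age by unadjusted linear regression on z-scored
    variables; the association is None when it is degenerate (fewer
    than four complete subjects, or a constant R or age column).
    """
    rs = []
    for _, row in frame.iterrows():
        pairs = []
        for reg in regions:
            m, c = row.get(reg), row.get(cbf_prefix + reg)
            if pd.notna(m) and pd.notna(c):
                pairs.append((float(m), float(c)))
        if len(pairs) < min_regions:
            rs.append(np.nan)
            continue
        arr = np.array(pairs)
        if np.std(arr[:, 0]) == 0 or np.std(arr[:, 1]) == 0:
            rs.append(np.nan)
            continue
        rs.append(sps.pearsonr(arr[:, 0], arr[:, 1])[0])
    per_subject = pd.Series(rs, index=frame.index, name="mpd_cbf_r")
    tmp = pd.DataFrame({"mpd_cbf_r": per_subject, age_col: frame[age_col]}).dropna()
    if len(tmp) < 4 or tmp["mpd_cbf_r"].std(ddof=1) == 0 or tmp[age_col].std(ddof=1) == 0:
        return per_subject, None
    tmp = z_transform(tmp, exclude=())
    assoc = adjusted_association(tmp, age_col, "mpd_cbf_r", covariates=())
    return per_subject, assoc
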