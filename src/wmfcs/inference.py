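"""Group inference, dose associations and power for region-wise FCS.

Per-region covariate-adjusted linear models compare the two groups, with
Benjamini-Hochberg FDR control applied separately within the WW and GW
families.  Dose-response analysis uses partial correlation (residualising
both variables on the covariates, df = n - 2 - g).  Post hoc power for a
two-sample comparison is evaluated from the noncentral t distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TTestResult",
    "PartialCorrResult",
    "PowerResult",
    "region_group_test",
    "ols_group_ttests",
    "pooled_t_from_summary",
    "fdr_bh",
    "partial_corr",
    "dose_association",
    "posthoc_power_two_sample",
    "demographics_table",
    "chi2_from_counts",
]

DEFAULT_COVARIATES = ("age", "sex", "mean_fd")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class PartialCorrResult:
    r: float
    t: float
    p: float
    n: int
    g: int  # number of covariates

    @property
    def df(self) -> int:
        return self.n - 2 - self.g


@dataclass(frozen=True)
class PowerResult:
    effect_size: float  # Cohen's d (pooled-SD units)
    power: float
    alpha: float = 0.05


def pooled_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> TTestResult:
    """Student's pooled-variance two-sample t from group summaries.

    The sign follows group2 - group1, so a lower second-group mean gives a
    negative t.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("group SDs must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (m2 - m1) / se
    return TTestResult(float(t), df, float(2 * stats.t.sf(abs(t), df)))


def fdr_bh(pvalues: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the family size; it may exceed the number of supplied p-values
    when the supplied subset is known to contain the smallest ones (as when
    adjusting only a table's reported rows).  Adjusted value for the i-th
    smallest p is min over j >= i of m * p_(j) / j, clipped at 1; ties keep
    stable order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    k = p.size
    if m is None:
        m = k
    if m < k:
        raise ValueError(f"family size m={m} smaller than number of p-values {k}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _encode_sex(values: pd.Series) -> np.ndarray:
    """male=1, female=0; numeric input passes through."""
    if values.dtype.kind in "ifb":
        return values.to_numpy(dtype=float)
    mapping = {"male": 1.0, "female": 0.0, "m": 1.0, "f": 0.0}
    out = values.astype(str).str.lower().map(mapping)
    if out.isna().any():
        raise ValueError("sex column must be male/female or numeric")
    return out.to_numpy(dtype=float)


def _encode_group(values: pd.Series) -> np.ndarray:
    """post=1, pre=0 (so a negative coefficient means post < pre)."""
    mapping = {"pre": 0.0, "post": 1.0}
    out = values.astype(str).str.lower().map(mapping)
    if out.isna().any():
        raise ValueError("group column must contain only 'pre'/'post'")
    return out.to_numpy(dtype=float)


def _design_matrix(
    rec: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(rec)), _encode_group(rec["group"])]
    names = ["intercept", "group_post"]
    for cov in covariates:
        if cov not in rec.columns:
            raise ValueError(f"covariate {cov!r} missing from records")
        col = _encode_sex(rec[cov]) if cov == "sex" else rec[cov].to_numpy(dtype=float)
        if np.nanstd(col) <= 1e-12 * max(1.0, abs(np.nanmean(col))):
            warnings.warn(f"covariate {cov!r} is constant; dropped from the model")
            continue
        cols.append(col)
        names.append(cov)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X[~np.isnan(X).any(axis=1)])
    if rank < X.shape[1]:
        raise ValueError(f"collinear design; columns: {names}")
    return X, names


def ols_group_ttests(
    Y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of each column of ``Y`` on the shared design ``X``.

    ``X`` must carry the intercept in column 0 and the group indicator in
    column 1; returns (beta, t, p) arrays for the group coefficient, one
    entry per column of ``Y``.  Vectorised across columns, which makes the
    per-region group test cheap enough for calibration studies with many
    simulated cohorts.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != X.shape[0]:
        raise ValueError("Y must be subjects x regions, aligned with X rows")
    n, k = X.shape
    if n <= k:
        raise ValueError("not enough subjects for the covariate model")
    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ X.T @ Y
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / (n - k)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    t = B[1] / se
    p = 2 * stats.t.sf(np.abs(t), n - k)
    return B[1], t, p


def _ols_group_t(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    beta, t, p = ols_group_ttests(y[:, None], X)
    return float(beta[0]), float(t[0]), float(p[0])


def region_group_test(
    fcs: pd.DataFrame,
    records: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    family_sizes: Mapping[str, int] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Covariate-adjusted group comparison of FCS, region by region.

    ``fcs`` is long format (subject_id, region, family, value); ``records``
    a participants table with group, age, sex and mean_fd.  For each region,
    FCS is regressed on [intercept, group(post=1), age, sex(male=1), mean FD]
    with listwise deletion of missing values; the reported t and two-sided p
    are for the group coefficient.  BH adjustment is applied separately per
    family with family size max(observed regions, family_sizes[family]).
    """
    rec = records.set_index("subject_id")
    rows = []
    for family, fam_df in fcs.groupby("family", sort=False):
        fam_rows = []
        for region, df in fam_df.groupby("region", sort=False):
            merged = df.set_index("subject_id").join(rec, how="inner")
            needed = ["value", "group"] + [c for c in covariates if c != "sex"]
            mask = merged[needed].notna().all(axis=1)
            if "sex" in covariates:
                mask &= merged["sex"].notna()
            merged = merged[mask]
            n_dropped = int((~mask).sum())
            if n_dropped:
                warnings.warn(
                    f"region {region}: {n_dropped} subject(s) dropped listwise"
                )
            g = _encode_group(merged["group"])
            if (g == 1).sum() < 2 or (g == 0).sum() < 2:
                raise ValueError(f"region {region}: fewer than 2 subjects per group")
            X, _ = _design_matrix(merged, covariates)
            y = merged["value"].to_numpy(dtype=float)
            beta, t, p = _ols_group_t(X, y)
            pre_vals = y[g == 0]
            post_vals = y[g == 1]
            fam_rows.append(
                {
                    "region": region,
                    "family": family,
                    "beta_group": beta,
                    "t": t,
                    "p": p,
                    "mean_pre": pre_vals.mean(),
                    "sd_pre": pre_vals.std(ddof=1),
                    "mean_post": post_vals.mean(),
                    "sd_post": post_vals.std(ddof=1),
                    "n_pre": int((g == 0).sum()),
                    "n_post": int((g == 1).sum()),
                }
            )
        fam = pd.DataFrame(fam_rows)
        m = len(fam)
        if family_sizes and family in family_sizes:
            m = max(m, int(family_sizes[family]))
        fam["p_fdr"] = fdr_bh(fam["p"].to_numpy(), m=m)
        fam["significant"] = fam["p_fdr"] < alpha
        rows.append(fam)
    return pd.concat(rows, ignore_index=True)


def partial_corr(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | None = None,
) -> PartialCorrResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualised on [intercept, covariates] by least
    squares and the residuals correlated; t = r * sqrt(df / (1 - r^2)) with
    df = n - 2 - g, two-sided p from the t distribution (the convention of
    the standard partial-correlation packages).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    g = C.shape[1]
    if n <= g + 2:
        raise ValueError(f"need n > g + 2 (n={n}, g={g})")
    X = np.column_stack([np.ones(n), C])
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero-variance residuals; partial correlation undefined")
    r = float(np.dot(rx, ry) / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    df = n - 2 - g
    r_ = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_ * np.sqrt(df / (1 - r_**2))
    p = 2 * stats.t.sf(abs(t), df)
    return PartialCorrResult(r, float(t), float(p), n, g)


def dose_association(
    fcs: pd.DataFrame,
    records: pd.DataFrame,
    dose_variables: Sequence[str] = ("mdrt_brainstem", "mdrt_left_temporal"),
    regions: Sequence[str] | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Partial correlation between region FCS and each dose variable.

    Only subjects with the dose recorded enter each analysis (the others are
    excluded with a logged count); covariates are residualised out on both
    sides.  One row per (region, dose variable).
    """
    rec = records.set_index("subject_id")
    if regions is None:
        regions = sorted(fcs["region"].unique())
    rows = []
    for dose_var in dose_variables:
        if dose_var not in rec.columns:
            raise ValueError(f"dose variable {dose_var!r} missing from records")
        for region in regions:
            sub = fcs[fcs["region"] == region].set_index("subject_id").join(
                rec, how="inner"
            )
            cols = ["value", dose_var] + list(covariates)
            work = sub.copy()
            work["sex"] = _encode_sex(sub["sex"]) if "sex" in covariates else sub.get("sex")
            mask = work[cols].notna().all(axis=1)
            n_excluded = int((~mask).sum())
            work = work[mask]
            if len(work) == 0:
                raise ValueError(f"no dose-complete subjects for {dose_var}")
            C = np.column_stack([work[c].to_numpy(dtype=float) for c in covariates])
            res = partial_corr(
                work["value"].to_numpy(dtype=float),
                work[dose_var].to_numpy(dtype=float),
                C,
            )
            rows.append(
                {
                    "region": region,
                    "dose_variable": dose_var,
                    "r": res.r,
                    "t": res.t,
                    "p": res.p,
                    "n": res.n,
                    "df": res.df,
                    "n_excluded": n_excluded,
                }
            )
    return pd.DataFrame(rows)


def posthoc_power_two_sample(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int,
    alpha: float = 0.05,
) -> PowerResult:
    """Power of the two-sided pooled-variance t test at the observed effect.

    d = |m1 - m2| / pooled SD; noncentrality d * sqrt(n1 n2 / (n1 + n2));
    df = n1 + n2 - 2.  d = 0 returns exactly alpha.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 subjects")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("group SDs must be positive")
    df = n1 + n2 - 2
    sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df)
    d = abs(m1 - m2) / sp
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    power = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    return PowerResult(float(d), float(power), alpha)


def chi2_from_counts(table: np.ndarray, correction: bool) -> TTestResult:
    """Chi-square test of independence on a contingency table.

    ``correction`` applies the Yates continuity correction (used for the 2x2
    sex table); staging uses the uncorrected statistic.
    """
    table = np.asarray(table, dtype=float)
    res = stats.chi2_contingency(table, correction=correction)
    return TTestResult(float(res.statistic), float(res.dof), float(res.pvalue))


def demographics_table(records: pd.DataFrame) -> pd.DataFrame:
    """Group comparisons of the demographics rows.

    Continuous rows (age, mean FD) use the pooled two-sample t test;
    the 2x2 sex table uses the continuity-corrected chi-square; clinical
    staging (optional ``staging`` column, levels like 'I/II' / 'III/IV')
    uses the uncorrected chi-square over available cases, with missing
    counts footnoted.
    """
    pre = records[records["group"] == "pre"]
    post = records[records["group"] == "post"]
    if len(pre) < 2 or len(post) < 2:
        raise ValueError("need at least 2 subjects per group")
    rows = []

    def cont_row(name: str, col: str) -> None:
        a = pre[col].dropna().to_numpy(dtype=float)
        b = post[col].dropna().to_numpy(dtype=float)
        res = pooled_t_from_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        rows.append(
            {
                "parameter": name,
                "pre": f"{a.mean():.2f} ({a.std(ddof=1):.2f})",
                "post": f"{b.mean():.2f} ({b.std(ddof=1):.2f})",
                "test": "pooled t",
                "statistic": res.t,
                "p": res.p,
                "note": "",
            }
        )

    cont_row("age", "age")

    counts = pd.crosstab(records["sex"], records["group"])
    counts = counts.reindex(index=["male", "female"], columns=["pre", "post"]).fillna(0)
    if (counts.to_numpy() == 0).any():
        warnings.warn("empty sex category; using Fisher's exact test")
        res_p = stats.fisher_exact(counts.to_numpy())[1]
        rows.append(
            {
                "parameter": "sex (male/female)",
                "pre": f"{int(counts.loc['male', 'pre'])}/{int(counts.loc['female', 'pre'])}",
                "post": f"{int(counts.loc['male', 'post'])}/{int(counts.loc['female', 'post'])}",
                "test": "fisher exact",
                "statistic": np.nan,
                "p": float(res_p),
                "note": "",
            }
        )
    else:
        res = chi2_from_counts(counts.to_numpy(), correction=True)
        rows.append(
            {
                "parameter": "sex (male/female)",
                "pre": f"{int(counts.loc['male', 'pre'])}/{int(counts.loc['female', 'pre'])}",
                "post": f"{int(counts.loc['male', 'post'])}/{int(counts.loc['female', 'post'])}",
                "test": "chi2 (Yates)",
                "statistic": res.t,
                "p": res.p,
                "note": "",
            }
        )

    if "staging" in records.columns and records["staging"].notna().any():
        avail = records[records["staging"].notna()]
        n_missing = len(records) - len(avail)
        ct = pd.crosstab(avail["staging"], avail["group"])
        ct = ct.reindex(columns=["pre", "post"]).fillna(0)
        res = chi2_from_counts(ct.to_numpy(), correction=False)
        rows.append(
            {
                "parameter": "clinical staging",
                "pre": "/".join(str(int(v)) for v in ct["pre"]),
                "post": "/".join(str(int(v)) for v in ct["post"]),
                "test": "chi2",
                "statistic": res.t,
                "p": res.p,
                "note": f"{n_missing} missing" if n_missing else "",
            }
        )

    if records["mean_fd"].notna().any():
        cont_row("mean_fd", "mean_fd")
    return pd.DataFrame(rows)
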