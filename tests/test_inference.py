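"""Group tests, BH-FDR, partial correlation, power and demographics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wmfcs.inference import (
    chi2_from_counts,
    demographics_table,
    dose_association,
    fdr_bh,
    ols_group_ttests,
    partial_corr,
    pooled_t_from_summary,
    posthoc_power_two_sample,
    region_group_test,
)

#: the five published WW-family group-difference p-values used as a
#: worked example for the step-up adjustment (family size 50)
WW_TABLE_PVALUES = [0.0035, 0.0018, 0.00039, 0.0012, 0.0033]


class TestPooledT:
    def test_published_fcs_row(self):
        res = pooled_t_from_summary(0.25, 0.11, 47, 0.19, 0.10, 64)
        assert round(res.t, 2) == -2.99
        assert res.df == 109

    def test_equal_means_zero(self):
        res = pooled_t_from_summary(0.3, 0.1, 20, 0.3, 0.2, 30)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_age_row_p_value(self):
        res = pooled_t_from_summary(46.70, 9.55, 47, 43.39, 9.93, 64)
        assert res.df == 109
        assert round(res.p, 3) == 0.081

    def test_matches_scipy_on_raw_data(self, rng):
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.4, 1.2, 35)
        res = pooled_t_from_summary(
            a.mean(), a.std(ddof=1), 25, b.mean(), b.std(ddof=1), 35
        )
        ref = stats.ttest_ind(b, a, equal_var=True)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pooled_t_from_summary(0, 0.0, 5, 1, 1.0, 5)
        with pytest.raises(ValueError):
            pooled_t_from_summary(0, 1.0, 1, 1, 1.0, 5)


class TestFdrBH:
    def test_published_family_hand_computation(self):
        q = fdr_bh(WW_TABLE_PVALUES, m=50)
        by_p = dict(zip(WW_TABLE_PVALUES, q))
        assert by_p[0.00039] == pytest.approx(0.0195, abs=1e-12)
        assert by_p[0.0012] == pytest.approx(0.030, abs=1e-12)
        assert by_p[0.0018] == pytest.approx(0.030, abs=1e-12)
        assert by_p[0.0033] == pytest.approx(0.035, abs=1e-12)
        assert by_p[0.0035] == pytest.approx(0.035, abs=1e-12)

    def test_single_p_unchanged(self):
        assert fdr_bh([0.04], m=1)[0] == pytest.approx(0.04)

    def test_all_ones(self):
        assert np.allclose(fdr_bh([1.0, 1.0, 1.0]), 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.5])
        with pytest.raises(ValueError):
            fdr_bh([0.1, 0.2], m=1)

    def test_exhaustive_stepup_oracle(self, rng):
        """Rejection sets agree with the definition: reject the k smallest
        p-values for the largest k with p_(k) <= k * alpha / m."""
        for _ in range(200):
            k = rng.integers(1, 25)
            p = rng.uniform(size=k) ** rng.uniform(0.5, 3)
            m = k + rng.integers(0, 10)
            q = fdr_bh(p, m=int(m))
            for alpha in (0.01, 0.05, 0.1, 0.25):
                srt = np.sort(p)
                thresh = (np.arange(1, k + 1) * alpha) / m
                passing = np.flatnonzero(srt <= thresh)
                k_max = passing[-1] + 1 if passing.size else 0
                cutoff = srt[k_max - 1] if k_max else -1.0
                expected = p <= cutoff
                assert np.array_equal(q <= alpha, expected)

    def test_matches_statsmodels_when_family_is_full(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=40)
        q = fdr_bh(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_ref, atol=1e-12)


class TestPartialCorr:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.normal(size=(2, 50))
        res = partial_corr(x, y)
        ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_null_after_covariate_removal(self, rng):
        n = 5000
        cov = rng.normal(size=(n, 2))
        y = cov @ [1.0, -2.0] + rng.normal(size=n)
        x = rng.normal(size=n)
        assert abs(partial_corr(x, y, cov).r) < 0.05

    def test_residualisation_oracle_small_instance(self, rng):
        n, g = 12, 3
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        cov = rng.normal(size=(n, g))
        res = partial_corr(x, y, cov)
        X = np.column_stack([np.ones(n), cov])
        rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
        ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert res.r == pytest.approx(stats.pearsonr(rx, ry).statistic, abs=1e-12)
        assert res.df == n - 2 - g

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        n = 40
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "y": rng.normal(size=n),
                "c1": rng.normal(size=n),
                "c2": rng.normal(size=n),
            }
        )
        df["y"] += 0.5 * df["x"] + 0.3 * df["c1"]
        res = partial_corr(df["x"], df["y"], df[["c1", "c2"]].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_zero_variance_fails(self, rng):
        with pytest.raises(ValueError):
            partial_corr(np.ones(20), rng.normal(size=20))


class TestRegionGroupTest:
    def _tables(self, rng, n_per_group=30, delta=0.0):
        n = 2 * n_per_group
        values = rng.normal(0.3, 0.1, n)
        values[n_per_group:] -= delta
        records = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "group": ["pre"] * n_per_group + ["post"] * n_per_group,
                "age": rng.normal(45, 10, n),
                "sex": rng.choice(["male", "female"], n),
                "mean_fd": rng.uniform(0.05, 0.3, n),
            }
        )
        fcs = pd.DataFrame(
            {
                "subject_id": records["subject_id"],
                "region": "wm_001",
                "family": "WW",
                "value": values,
            }
        )
        return fcs, records, values

    def test_reduces_to_pooled_t_without_covariates(self, rng):
        fcs, records, values = self._tables(rng, delta=0.05)
        out = region_group_test(fcs, records, covariates=())
        ref = stats.ttest_ind(values[30:], values[:30], equal_var=True)
        assert out.loc[0, "t"] == pytest.approx(ref.statistic, abs=1e-10)
        assert out.loc[0, "p"] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_constant_covariates_dropped_and_reduce_to_pooled_t(self, rng):
        fcs, records, values = self._tables(rng, delta=0.05)
        records["age"] = 50.0
        records["sex"] = "male"
        records["mean_fd"] = 0.2
        with pytest.warns(UserWarning, match="constant"):
            out = region_group_test(fcs, records)
        ref = stats.ttest_ind(values[30:], values[:30], equal_var=True)
        assert out.loc[0, "t"] == pytest.approx(ref.statistic, abs=1e-10)

    def test_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        fcs, records, values = self._tables(rng, delta=0.04)
        out = region_group_test(fcs, records)
        X = pd.DataFrame(
            {
                "group": (records["group"] == "post").astype(float),
                "age": records["age"],
                "sex": (records["sex"] == "male").astype(float),
                "mean_fd": records["mean_fd"],
            }
        )
        fit = sm.OLS(values, sm.add_constant(X)).fit()
        assert out.loc[0, "t"] == pytest.approx(fit.tvalues["group"], abs=1e-10)
        assert out.loc[0, "p"] == pytest.approx(fit.pvalues["group"], abs=1e-10)
        assert out.loc[0, "beta_group"] == pytest.approx(
            fit.params["group"], abs=1e-12
        )

    def test_group_coding_sign(self, rng):
        # post below pre must give a negative t
        fcs, records, _ = self._tables(rng, delta=0.2)
        out = region_group_test(fcs, records)
        assert out.loc[0, "t"] < 0

    def test_collinear_covariates_fail(self, rng):
        fcs, records, _ = self._tables(rng)
        records["age2"] = records["age"]
        with pytest.raises(ValueError, match="collinear"):
            region_group_test(fcs, records, covariates=("age", "age2"))

    def test_family_size_override_inflates_adjustment(self, rng):
        fcs, records, _ = self._tables(rng, delta=0.08)
        plain = region_group_test(fcs, records)
        inflated = region_group_test(fcs, records, family_sizes={"WW": 50})
        assert inflated.loc[0, "p_fdr"] == pytest.approx(
            min(1.0, plain.loc[0, "p"] * 50), abs=1e-12
        )

    def test_vectorised_path_matches_per_region(self, rng):
        n = 40
        X = np.column_stack(
            [
                np.ones(n),
                rng.integers(0, 2, n).astype(float),
                rng.normal(size=n),
                rng.normal(size=n),
            ]
        )
        Y = rng.normal(size=(n, 7))
        beta, t, p = ols_group_ttests(Y, X)
        for j in range(7):
            b1, t1, p1 = ols_group_ttests(Y[:, [j]], X)
            assert t[j] == pytest.approx(t1[0], abs=1e-12)
            assert p[j] == pytest.approx(p1[0], abs=1e-12)


class TestPower:
    def test_null_effect_gives_alpha(self):
        res = posthoc_power_two_sample(0.3, 0.1, 47, 0.3, 0.1, 64, alpha=0.05)
        assert res.effect_size == 0.0
        assert res.power == pytest.approx(0.05, abs=1e-10)

    def test_published_fcs_row_power(self):
        res = posthoc_power_two_sample(0.25, 0.11, 47, 0.19, 0.10, 64)
        assert res.power == pytest.approx(0.84, abs=0.01)

    def test_monotone_in_sample_size(self):
        p1 = posthoc_power_two_sample(0.25, 0.11, 47, 0.19, 0.10, 64).power
        p2 = posthoc_power_two_sample(0.25, 0.11, 188, 0.19, 0.10, 256).power
        assert 1 > p2 > p1 > 0.05


class TestDemographics:
    def test_published_sex_table(self):
        res = chi2_from_counts([[36, 11], [47, 17]], correction=True)
        assert round(res.p, 2) == 0.87

    def test_published_staging_table(self):
        res = chi2_from_counts([[4, 34], [7, 45]], correction=False)
        assert round(res.p, 3) == 0.675

    def test_table_with_staging_and_missing(self, rng):
        groups = ["pre"] * 47 + ["post"] * 64
        sex = ["male"] * 36 + ["female"] * 11 + ["male"] * 47 + ["female"] * 17
        staging = (
            ["I/II"] * 4 + ["III/IV"] * 34 + [np.nan] * 9
            + ["I/II"] * 7 + ["III/IV"] * 45 + [np.nan] * 12
        )
        records = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(111)],
                "group": groups,
                "age": rng.normal(45, 10, 111),
                "sex": sex,
                "mean_fd": rng.uniform(0.1, 0.2, 111),
                "staging": staging,
            }
        )
        table = demographics_table(records).set_index("parameter")
        assert round(table.loc["sex (male/female)", "p"], 2) == 0.87
        assert round(table.loc["clinical staging", "p"], 3) == 0.675
        assert "21 missing" in table.loc["clinical staging", "note"]

    def test_identical_groups_all_p_one(self):
        base = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(20)],
                "group": ["pre"] * 10 + ["post"] * 10,
                "age": list(range(10)) * 2,
                "sex": (["male"] * 7 + ["female"] * 3) * 2,
                "mean_fd": ([0.1] * 5 + [0.2] * 5) * 2,
            }
        )
        table = demographics_table(base)
        assert np.allclose(table["p"], 1.0)


class TestDoseAssociation:
    def test_dose_subset_and_df(self, rng):
        n_post, n_dose = 64, 37
        records = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n_post)],
                "group": "post",
                "age": rng.normal(45, 10, n_post),
                "sex": rng.choice(["male", "female"], n_post),
                "mean_fd": rng.uniform(0.05, 0.3, n_post),
                "mdrt_brainstem": [62.0 + i for i in range(n_dose)]
                + [np.nan] * (n_post - n_dose),
                "mdrt_left_temporal": np.nan,
            }
        )
        fcs = pd.DataFrame(
            {
                "subject_id": records["subject_id"],
                "region": "ctx_001",
                "family": "GW",
                "value": rng.normal(0.3, 0.1, n_post),
            }
        )
        out = dose_association(fcs, records, ["mdrt_brainstem"], ["ctx_001"])
        assert len(out) == 1
        assert out.loc[0, "n"] == 37
        assert out.loc[0, "df"] == 32
        assert out.loc[0, "n_excluded"] == 27

    def test_shuffled_dose_is_null(self, rng):
        n = 400
        records = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "group": "post",
                "age": rng.normal(45, 10, n),
                "sex": rng.choice(["male", "female"], n),
                "mean_fd": rng.uniform(0.05, 0.3, n),
                "mdrt_brainstem": rng.permutation(rng.normal(62, 6, n)),
            }
        )
        fcs = pd.DataFrame(
            {
                "subject_id": records["subject_id"],
                "region": "ctx_001",
                "family": "GW",
                "value": rng.normal(0.3, 0.1, n),
            }
        )
        out = dose_association(fcs, records, ["mdrt_brainstem"], ["ctx_001"])
        assert abs(out.loc[0, "r"]) < 0.12
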