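"""The marker scan, permutation thresholds, deep permutation and type-I harness."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from admixscan.io import CohortBundle
from admixscan.models import CovariateSet, ModelId, build_design, fit_ols, lrt, wald
from admixscan.scan import (
    CONTRASTS,
    PermutationPlan,
    bonferroni_adjust,
    deep_permutation_p,
    fwer_thresholds,
    heterogeneity_test,
    scan_markers,
    type1_harness,
)
from admixscan.simulate import (
    PhenotypeModelSpec,
    simulate_cohort,
    simulate_null_cohort,
)


def _signal_spec(causal: int, strong: bool = True) -> PhenotypeModelSpec:
    scale = 1.0 if strong else 0.3
    return PhenotypeModelSpec(
        model="heterogeneous",
        intercept=4.1,
        beta_covariates={"med": 0.124},
        beta_dummies={"EN": 0.138 * scale, "EA": -0.053, "NN": 0.45 * scale,
                      "NA": 0.131, "AA": 0.0},
        beta_g_by_category={"EE": 0.4 * scale, "EN": 0.15 * scale, "EA": -0.039,
                           "NN": -0.3 * scale, "NA": -0.122, "AA": 0.0},
        sigma=0.12,
        causal_marker=causal,
    )


class TestScanAgainstExplicitFits:
    def test_kernel_matches_statsmodels_route(self, null_cohort_small):
        """The residualized Gram kernel reproduces explicit per-marker OLS fits
        (statistics, df and p-values) for all four contrasts."""
        cohort = null_cohort_small
        res = scan_markers(cohort, covariates=("sex", "age"))
        y = cohort.log_trait()
        cov = CovariateSet(frame=cohort.phenotypes[["ga_N", "ga_A", "sex", "age"]])
        for marker in cohort.markers[:25]:
            g = cohort.genotypes[marker].to_numpy(float)
            cats = cohort.diplotypes[marker].to_numpy(object)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits = {
                    mid: fit_ols(
                        build_design(
                            mid,
                            g if mid != ModelId.M1_null else None,
                            cats if mid not in (ModelId.M1_null, ModelId.M2_association) else None,
                            cov,
                        )[0],
                        y,
                    )
                    for mid in (ModelId.M1_null, ModelId.M2_association,
                                ModelId.M3_admixture, ModelId.M4_heterogeneous)
                }
            pairs = {
                "admixture": (fits[ModelId.M3_admixture], fits[ModelId.M1_null]),
                "association": (fits[ModelId.M2_association], fits[ModelId.M1_null]),
                "association_adj_admixture": (
                    fits[ModelId.M4_heterogeneous], fits[ModelId.M3_admixture]),
                "combined": (fits[ModelId.M4_heterogeneous], fits[ModelId.M1_null]),
            }
            for name, (full, red) in pairs.items():
                if not np.isfinite(res.loc[marker, f"{name}_lrt_stat"]):
                    continue
                stat, df, p = lrt(full, red)
                assert res.loc[marker, f"{name}_df"] == df
                assert res.loc[marker, f"{name}_lrt_stat"] == pytest.approx(stat, abs=1e-8)
                assert res.loc[marker, f"{name}_lrt_p"] == pytest.approx(p, abs=1e-10)
                tested = [c for c in full.columns if c not in red.columns]
                wstat, wdf, wp = wald(full, tested)
                assert res.loc[marker, f"{name}_wald_stat"] == pytest.approx(wstat, abs=1e-8)
                assert res.loc[marker, f"{name}_wald_p"] == pytest.approx(wp, abs=1e-10)

    def test_monomorphic_marker_keeps_admixture_contrast(self, null_cohort_small):
        cohort = null_cohort_small
        geno = cohort.genotypes.copy()
        geno.iloc[:, 3] = 0.0
        mono = CohortBundle(
            genotypes=geno,
            diplotypes=cohort.diplotypes,
            marker_map=cohort.marker_map,
            phenotypes=cohort.phenotypes,
        )
        res = scan_markers(mono, covariates=("sex", "age"))
        row = res.iloc[3]
        assert np.isnan(row["association_lrt_p"])
        assert np.isnan(row["association_adj_admixture_lrt_p"])
        assert np.isfinite(row["admixture_lrt_p"])
        assert "skip:association" in row["flags"]

    def test_combined_df_is_sum_of_parts(self, null_cohort_small):
        res = scan_markers(null_cohort_small, covariates=("sex", "age"))
        ok = res["flags"] == ""
        assert (
            res.loc[ok, "combined_df"]
            == res.loc[ok, "admixture_df"] + res.loc[ok, "association_adj_admixture_df"]
        ).all()

    def test_power_ordering_at_planted_marker(self):
        """Under strong heterogeneous effects the combined test yields the
        smallest p-value of the four contrasts at the causal marker."""
        cohort = simulate_cohort(_signal_spec(20), n_individuals=132, n_markers=60, seed=42)
        res = scan_markers(cohort, covariates=("med",))
        row = res.iloc[20]
        p_comb = row["combined_lrt_p"]
        for contrast in ("admixture", "association", "association_adj_admixture"):
            assert p_comb <= row[f"{contrast}_lrt_p"]

    def test_wald_and_lrt_rank_markers_identically_on_strong_signal(self):
        cohort = simulate_cohort(_signal_spec(10), n_individuals=132, n_markers=40, seed=43)
        res = scan_markers(cohort, covariates=("med",))
        p_w = res["combined_wald_p"].fillna(1.0)
        p_l = res["combined_lrt_p"].fillna(1.0)
        assert p_w.idxmin() == p_l.idxmin() == res.index[10]


class TestHeterogeneity:
    def test_opposite_sign_slopes_detected(self):
        cohort = simulate_cohort(_signal_spec(5), n_individuals=600, n_markers=20, seed=8)
        stat, df, p = heterogeneity_test(cohort, "trait", cohort.markers[5],
                                         covariates=("med",))
        assert df >= 2
        assert p < 1e-6

    def test_shared_slope_gives_null_pvalues(self):
        """Under a homogeneous generating slope the heterogeneity p-values are
        not systematically small."""
        pvals = []
        for k in range(30):
            spec = PhenotypeModelSpec(
                model="homogeneous", intercept=4.1,
                beta_dummies={"EN": 0.1, "NN": 0.12}, beta_g=0.1,
                sigma=0.12, causal_marker=2,
            )
            cohort = simulate_cohort(spec, n_individuals=150, n_markers=8, seed=900 + k)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, df, p = heterogeneity_test(cohort, "trait", cohort.markers[2])
            if df > 0 and np.isfinite(p):
                pvals.append(p)
        assert 0.25 < np.mean(pvals) < 0.75
        assert min(pvals) > 1e-4

    def test_single_stratum_is_explicit_skip(self):
        cohort = simulate_null_cohort(40, 6, seed=12)
        dips = pd.DataFrame("EE", index=cohort.diplotypes.index,
                            columns=cohort.diplotypes.columns)
        pheno = cohort.phenotypes.copy()
        pheno[["ga_E", "ga_N", "ga_A"]] = [1.0, 0.0, 0.0]
        # make the global-ancestry covariates non-constant so M1 remains full rank
        rng = np.random.default_rng(0)
        pheno["ga_N"] = rng.uniform(0, 0.1, len(pheno))
        pheno["ga_A"] = rng.uniform(0, 0.1, len(pheno))
        single = CohortBundle(
            genotypes=cohort.genotypes, diplotypes=dips,
            marker_map=cohort.marker_map, phenotypes=pheno,
        )
        stat, df, p = heterogeneity_test(single, "trait", cohort.markers[0])
        assert df == 0 and np.isnan(p)


class TestPermutationThresholds:
    def test_single_marker_threshold_near_alpha(self):
        """With one marker there is no multiplicity: the min-p threshold is
        close to the per-test level."""
        cohort = simulate_null_cohort(120, 1, seed=33)
        thr = fwer_thresholds(
            cohort, covariates=("sex", "age"), plan=PermutationPlan(2000, 0.05, 3)
        )
        val = thr.thresholds.loc["combined", "wald"]
        assert 0.02 < val < 0.09

    def test_minp_stochastically_smaller_than_uniform(self, null_cohort_small):
        thr = fwer_thresholds(
            null_cohort_small, covariates=("sex", "age"),
            plan=PermutationPlan(150, 0.05, 4),
        )
        minp = thr.min_p["wald"]["combined"]
        assert minp.mean() < 0.40  # 100 markers' minimum is far below U(0,1)'s 0.5
        assert (minp >= 0).all() and (minp <= 1).all()

    def test_higher_df_contrasts_get_larger_thresholds(self):
        """df-4+ admixture thresholds exceed the df-1 association threshold,
        the ordering seen in the published per-contrast thresholds."""
        cohort = simulate_null_cohort(132, 400, seed=44)
        thr = fwer_thresholds(
            cohort, covariates=("sex", "age"), plan=PermutationPlan(400, 0.05, 5)
        )
        for statistic in ("lrt", "wald"):
            assert (
                thr.thresholds.loc["admixture", statistic]
                > thr.thresholds.loc["association", statistic]
            )

    def test_bit_reproducible_under_seed(self):
        cohort = simulate_null_cohort(60, 40, seed=21)
        a = fwer_thresholds(cohort, covariates=("sex",), plan=PermutationPlan(120, 0.05, 9))
        b = fwer_thresholds(cohort, covariates=("sex",), plan=PermutationPlan(120, 0.05, 9))
        assert a.thresholds.equals(b.thresholds)
        assert a.min_p["lrt"].equals(b.min_p["lrt"])

    def test_plan_validation(self):
        with pytest.raises(ValueError):
            PermutationPlan(0)
        with pytest.raises(ValueError):
            PermutationPlan(100, fwer=1.5)


class TestDeepPermutation:
    def test_boundary_p_is_one_over_nplus1(self):
        """An observed statistic above every permuted one gives p = 1/(n+1)."""
        cohort = simulate_cohort(_signal_spec(0), n_individuals=132, n_markers=1, seed=3)
        p = deep_permutation_p(
            cohort, "trait", cohort.markers[0], n_perm=999, seed=17, covariates=("med",)
        )
        assert p == pytest.approx(1 / 1000)

    def test_consistent_with_analytic_chi2_under_null(self, null_cohort_small):
        """Permutation p-hat agrees with the analytic chi-squared p within
        Monte-Carlo error on a genotype-independent trait."""
        cohort = null_cohort_small
        res = scan_markers(cohort, covariates=("sex", "age"))
        marker = res["combined_wald_p"].fillna(1.0).idxmin()  # smallest p, still null
        analytic = res.loc[marker, "combined_wald_p"]
        n_perm = 3000
        p_hat = deep_permutation_p(
            cohort, "trait", marker, statistic="wald", n_perm=n_perm, seed=2,
            covariates=("sex", "age"),
        )
        se = np.sqrt(max(p_hat * (1 - p_hat), 1e-9) / n_perm)
        assert abs(p_hat - analytic) < 3 * se + 0.01

    def test_invalid_n_perm_rejected(self, null_cohort_small):
        with pytest.raises(ValueError, match="positive"):
            deep_permutation_p(null_cohort_small, "trait",
                               null_cohort_small.markers[0], n_perm=0)


class TestBonferroni:
    def test_published_adjustment(self):
        assert round(bonferroni_adjust(8.068e-7, 40098), 3) == 0.032

    @given(p=st.floats(0, 1), n=st.integers(1, 10**6))
    def test_capped_and_monotone(self, p, n):
        adj = bonferroni_adjust(p, n)
        assert 0 <= adj <= 1
        assert adj >= min(p, 1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(1.5, 10)
        with pytest.raises(ValueError):
            bonferroni_adjust(0.5, 0)


class TestType1Harness:
    def test_degenerate_thresholds(self, null_cohort_small):
        zero = pd.DataFrame(
            {"lrt": [0.0] * 4, "wald": [0.0] * 4}, index=pd.Index(CONTRASTS)
        )
        one = pd.DataFrame(
            {"lrt": [1.0] * 4, "wald": [1.0] * 4}, index=pd.Index(CONTRASTS)
        )
        rep0 = type1_harness(null_cohort_small, zero, n_datasets=10, seed=1)
        rep1 = type1_harness(null_cohort_small, one, n_datasets=10, seed=1)
        assert (rep0["empirical_fwer"] == 0.0).all()
        assert (rep1["empirical_fwer"] == 1.0).all()

    def test_requires_null_generating_model(self):
        cohort = simulate_cohort(_signal_spec(0), n_individuals=40, n_markers=4, seed=2)
        thr = pd.DataFrame({"lrt": [0.05] * 4, "wald": [0.05] * 4}, index=pd.Index(CONTRASTS))
        with pytest.raises(ValueError, match="null trait model"):
            type1_harness(cohort, thr, n_datasets=5, seed=0)
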