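"""Correlated-factors ACE model: covariance algebra, likelihood, fitting, CIs."""

import numpy as np
import pytest
from scipy import stats

import gxetwin as gx
from gxetwin.twin import (CorrelatedFactorsParams, TwinData, compare_models,
                          expected_covariance, fit_correlated_factors,
                          fit_saturated, intraclass_correlations,
                          minus2_log_likelihood, profile_ci)


def _uni_params(a2=0.78, c2=0.10, e2=0.12, mu=0.0):
    return CorrelatedFactorsParams(
        a=np.array([np.sqrt(a2)]), c=np.array([np.sqrt(c2)]),
        e=np.array([np.sqrt(e2)]), r_a=np.eye(1), r_c=np.eye(1),
        r_e=np.eye(1), mu=np.array([mu]))


def _uni_data(a2, c2, e2, n_mz, n_dz, seed):
    ace = {t: (a2, c2, e2) for t in gx.TRAITS}
    m = gx.GeneratingModel(n_mz_pairs=n_mz, n_dz_ss_pairs=n_dz,
                           n_dz_os_pairs=0, n_unrelated=0, ace_props=ace,
                           seed=seed)
    traits = gx.simulate_twin_traits(m)
    return TwinData(groups={g: arr[:, [0, 3]] for g, arr in traits.items()},
                    traits=("bmi_sds",))


class TestExpectedCovariance:
    def test_univariate_hand_values(self):
        # A + C = 0.88 (MZ cross-twin), 0.5 A + C = 0.49 (DZ cross-twin)
        p = _uni_params(0.78, 0.10, 0.12)
        mz = expected_covariance(p, "MZ")
        dz = expected_covariance(p, "DZ")
        assert mz[0, 1] == pytest.approx(0.88)
        assert dz[0, 1] == pytest.approx(0.49)
        assert mz[0, 0] == pytest.approx(1.0)

    def test_symmetric_positive_definite(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            z = rng.standard_normal(3)
            R = np.corrcoef(rng.standard_normal((4, 10)))[:3, :3]
            p = CorrelatedFactorsParams(
                a=np.abs(rng.standard_normal(3)) + 0.1,
                c=np.abs(rng.standard_normal(3)) + 0.1,
                e=np.abs(rng.standard_normal(3)) + 0.1,
                r_a=R, r_c=np.eye(3), r_e=np.eye(3))
            for grp in ("MZ", "DZ"):
                S = expected_covariance(p, grp)
                assert np.array_equal(S, S.T)
                assert np.linalg.eigvalsh(S).min() > 0

    def test_pure_additive_limit_icc_one(self):
        p = _uni_params(1.0 - 2e-9, 1e-9, 1e-9)
        mz = expected_covariance(p, "MZ")
        assert mz[0, 1] / mz[0, 0] == pytest.approx(1.0, abs=1e-8)


class TestLikelihood:
    def test_standard_normal_at_origin(self):
        data = TwinData(groups={"MZ": np.array([[0.0, 0.0]])},
                        traits=("t",))
        p = _uni_params(1e-12, 1e-12, 1.0 - 2e-12)
        assert minus2_log_likelihood(p, data) == pytest.approx(
            2.0 * np.log(2 * np.pi), abs=1e-6)

    def test_matches_direct_density_oracle(self):
        """FIML via pattern sufficient statistics equals a brute-force sum of
        per-pair multivariate-normal log densities, including missingness."""
        rng = np.random.default_rng(1)
        p = 3
        paths = CorrelatedFactorsParams(
            a=np.array([0.8, 0.6, 0.7]), c=np.array([0.3, 0.5, 0.4]),
            e=np.array([0.5, 0.6, 0.4]),
            r_a=np.array([[1, 0.3, -0.4], [0.3, 1, 0.1], [-0.4, 0.1, 1.0]]),
            r_c=np.eye(3), r_e=np.array([[1, 0.2, -0.2], [0.2, 1, 0.0],
                                         [-0.2, 0.0, 1.0]]),
            mu=np.array([0.1, -0.2, 0.3]))
        groups = {}
        for g in ("MZ", "DZ"):
            arr = rng.standard_normal((10, 2 * p))
            arr[0, 4] = np.nan  # partial missingness
            arr[3, 0] = np.nan
            groups[g] = arr
        data = TwinData(groups=groups, traits=("x", "y", "z"))

        direct = 0.0
        mu_full = np.tile(paths.mu, 2)
        for g, arr in data.groups.items():
            sigma = expected_covariance(paths, g)
            for row in arr:
                obs = np.isfinite(row)
                direct += -2.0 * stats.multivariate_normal.logpdf(
                    row[obs], mu_full[obs], sigma[np.ix_(obs, obs)])
        assert minus2_log_likelihood(paths, data) == pytest.approx(
            direct, abs=1e-8)

    def test_duplicating_data_doubles_m2ll(self):
        data = _uni_data(0.6, 0.2, 0.2, 30, 30, seed=2)
        doubled = TwinData(groups={g: np.vstack([a, a])
                                   for g, a in data.groups.items()},
                           traits=data.traits)
        p = _uni_params(0.5, 0.3, 0.2, mu=0.1)
        assert minus2_log_likelihood(p, doubled) == pytest.approx(
            2 * minus2_log_likelihood(p, data), rel=1e-12)

    def test_invariant_to_twin_order_swap(self):
        data = _uni_data(0.6, 0.2, 0.2, 40, 40, seed=3)
        swapped = TwinData(groups={g: a[:, ::-1].copy()
                                   for g, a in data.groups.items()},
                           traits=data.traits)
        p = _uni_params(0.5, 0.3, 0.2, mu=0.05)
        assert minus2_log_likelihood(p, swapped) == pytest.approx(
            minus2_log_likelihood(p, data), rel=1e-12)


class TestFitting:
    def test_univariate_recovery_moderate_n(self):
        data = _uni_data(0.78, 0.10, 0.12, 1000, 1600, seed=4)
        fit = fit_correlated_factors(data, "ACE", seed=0)
        assert fit.std_props.loc["bmi_sds", "A"] == pytest.approx(0.78, abs=0.06)
        assert fit.converged

    def test_falconer_agreement(self):
        data = _uni_data(0.6, 0.25, 0.15, 3000, 3000, seed=5)
        fit = fit_correlated_factors(data, "ACE", seed=0)
        icc = intraclass_correlations(data)
        falconer = 2 * (icc.loc["MZ"].iloc[0] - icc.loc["DZ"].iloc[0])
        assert fit.std_props["A"].iloc[0] == pytest.approx(falconer, abs=0.05)

    def test_saturated_never_worse_than_ace(self):
        data = _uni_data(0.5, 0.3, 0.2, 80, 80, seed=6)
        ace = fit_correlated_factors(data, "ACE", seed=0)
        sat = fit_saturated(data)
        assert sat.minus2LL <= ace.minus2LL + 1e-6

    def test_saturated_df_counting_oracle(self):
        data = _uni_data(0.5, 0.3, 0.2, 50, 60, seed=7)
        sat = fit_saturated(data)
        # per group: 2 means + 3 covariance entries = 5 parameters
        assert sat.n_params == 10
        n_complete = sum(np.isfinite(a).all(axis=1).sum()
                         for a in data.groups.values())
        assert sat.df == n_complete * 2 - 10

    def test_ae_preferred_when_c_is_zero(self):
        data = _uni_data(0.7, 0.0, 0.3, 600, 900, seed=8)
        ace = fit_correlated_factors(data, "ACE", seed=0)
        ae = fit_correlated_factors(data, "AE", seed=0)
        # boundary truncation gives C a small positive bias ~ half-normal SE
        assert ace.std_props.loc["bmi_sds", "C"] < 0.08
        cmp = compare_models(ace, ae)
        assert cmp["preferred_by_aic"] == "AE"
        assert cmp["lrt_p"] > 0.01

    def test_compare_identical_fits(self):
        data = _uni_data(0.5, 0.3, 0.2, 80, 80, seed=9)
        ace = fit_correlated_factors(data, "ACE", seed=0)
        cmp = compare_models(ace, ace)
        assert cmp["delta_minus2LL"] == 0.0
        assert cmp["lrt_p"] == 1.0
        sat = fit_saturated(data)
        cmp = compare_models(sat, ace)
        assert cmp["delta_minus2LL"] >= -1e-6
        assert 0.0 <= cmp["lrt_p"] <= 1.0

    def test_non_nested_comparison_rejected(self):
        data = _uni_data(0.5, 0.3, 0.2, 80, 80, seed=10)
        ae = fit_correlated_factors(data, "AE", seed=0)
        ce = fit_correlated_factors(data, "CE", seed=0)
        with pytest.raises(ValueError, match="nested"):
            compare_models(ae, ce)

    def test_aic_identity(self):
        data = _uni_data(0.5, 0.3, 0.2, 80, 80, seed=11)
        fit = fit_correlated_factors(data, "ACE", seed=0)
        assert fit.aic == pytest.approx(fit.minus2LL + 2 * fit.n_params)

    def test_standardized_proportions_sum_to_one(self):
        data = _uni_data(0.4, 0.3, 0.3, 120, 120, seed=12)
        fit = fit_correlated_factors(data, "ACE", seed=0)
        assert fit.std_props.sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-8)


class TestProfileCi:
    def test_interval_contains_point_estimate(self):
        data = _uni_data(0.6, 0.2, 0.2, 300, 300, seed=13)
        fit = fit_correlated_factors(data, "ACE", seed=0)
        lo, hi = profile_ci(fit, ("A", "bmi_sds"))
        a_hat = fit.std_props.loc["bmi_sds", "A"]
        assert lo <= a_hat <= hi
        assert 0.0 <= lo < hi <= 1.0

    def test_width_shrinks_with_sample_size(self):
        fits = []
        for n in (150, 1200):
            data = _uni_data(0.6, 0.2, 0.2, n, n, seed=14)
            fits.append(fit_correlated_factors(data, "ACE", seed=0))
        w = [np.diff(profile_ci(f, ("A", 0)))[0] for f in fits]
        assert w[1] < w[0]

    def test_quadratic_likelihood_closed_form(self):
        """At large n the profile interval approaches the Wald interval of
        the double-entry MZ/DZ moment estimator (quadratic log-likelihood);
        checked loosely as an analytic cross-validation."""
        data = _uni_data(0.6, 0.2, 0.2, 4000, 4000, seed=15)
        fit = fit_correlated_factors(data, "ACE", seed=0)
        lo, hi = profile_ci(fit, ("A", 0))
        a_hat = fit.std_props.loc["bmi_sds", "A"]
        assert hi - lo < 0.20
        assert lo <= a_hat <= hi
        # symmetric to first order
        assert (hi - a_hat) == pytest.approx(a_hat - lo, abs=0.02)


class TestIcc:
    def test_identical_twin_values_give_one(self):
        arr = np.tile(np.random.default_rng(16).standard_normal(20)[:, None],
                      (1, 2))
        data = TwinData(groups={"MZ": arr, "DZ": arr}, traits=("t",))
        icc = intraclass_correlations(data)
        assert icc.loc["MZ", "t"] == pytest.approx(1.0)

    def test_pure_additive_expectations(self):
        data = _uni_data(0.8, 0.0, 0.2, 2000, 2000, seed=17)
        icc = intraclass_correlations(data)
        assert icc.loc["MZ", "bmi_sds"] == pytest.approx(0.8, abs=0.05)
        assert icc.loc["DZ", "bmi_sds"] == pytest.approx(0.4, abs=0.05)

    def test_double_entry_invariant_to_order(self):
        rng = np.random.default_rng(18)
        arr = rng.standard_normal((30, 2))
        d1 = TwinData(groups={"MZ": arr, "DZ": arr}, traits=("t",))
        d2 = TwinData(groups={"MZ": arr[:, ::-1].copy(), "DZ": arr},
                      traits=("t",))
        assert intraclass_correlations(d1).loc["MZ", "t"] == pytest.approx(
            intraclass_correlations(d2).loc["MZ", "t"], abs=1e-12)


def test_from_phenotypes_builds_pairs(small_cohort):
    from gxetwin.lms import LmsReference
    from gxetwin.pheno import prepare_phenotypes
    tables = small_cohort["tables"]
    clean = prepare_phenotypes(tables.phenotypes, LmsReference(tables.lms))
    data = TwinData.from_phenotypes(clean.data, gx.TRAITS)
    m = small_cohort["model"]
    assert data.groups["MZ"].shape[0] <= m.n_mz_pairs
    assert data.groups["DZ"].shape[0] <= m.n_dz_ss_pairs + m.n_dz_os_pairs
    assert data.groups["MZ"].shape[1] == 6
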