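import math

import numpy as np
import pytest

from augseq import (
    EndpointModel,
    InsufficientDataError,
    LookCounts,
    ModelError,
    TrialDataset,
    estimate_nuisance,
    expected_information,
    final_information,
    fixed_design_sample_size,
    generalized_effect,
    generalized_variance,
    information_fraction,
    summarize,
    treatment_effect,
    treatment_effect_variance,
)
from augseq.model import NuisanceEstimate

from conftest import make_monotone_dataset


def naive_augmented_effect(data: TrialDataset, nuisance) -> float:
    """Loop-by-loop transcription of the paired-difference form of the
    estimator for equal arms with a monotone pattern; independent of the
    vectorized implementation."""
    sig = np.asarray(nuisance.sigmas, dtype=float)
    corr = np.asarray(nuisance.corr, dtype=float)
    K = data.K
    arm1 = data.values[data.arms == 1]
    arm0 = data.values[data.arms == 0]
    assert arm1.shape == arm0.shape
    counts = [int(np.sum(~np.isnan(arm1[:, k]))) for k in range(K)]
    nK = counts[K - 1]
    total = 0.0
    for i in range(nK):
        total += arm1[i, K - 1] - arm0[i, K - 1]
    for k in range(K - 1):
        nk = counts[k]
        dbar = sum(arm1[m, k] - arm0[m, k] for m in range(nk)) / nk
        correction = 0.0
        for i in range(nK, nk):
            correction += arm1[i, k] - arm0[i, k] - dbar
        total += corr[k, K - 1] * sig[K - 1] / sig[k] * correction
    return total / nK


class TestTreatmentEffect:
    def test_zero_correlations_give_plain_mean_difference(self, rng, uniform_model):
        data = make_monotone_dataset(uniform_model, [30, 20, 12], rng, delta=4.0)
        independent = EndpointModel.uniform(K=3, sigma=20.0, rho=0.0)
        b = treatment_effect(data, independent)
        final1 = data.values[(data.arms == 1) & ~np.isnan(data.values[:, 2]), 2]
        final0 = data.values[(data.arms == 0) & ~np.isnan(data.values[:, 2]), 2]
        assert b == pytest.approx(final1.mean() - final0.mean(), abs=1e-12)

    def test_complete_data_gives_plain_mean_difference(self, rng, uniform_model):
        data = make_monotone_dataset(uniform_model, [25, 25, 25], rng, delta=-3.0)
        b = treatment_effect(data, uniform_model)
        diff = data.values[data.arms == 1, 2].mean() - data.values[data.arms == 0, 2].mean()
        assert b == pytest.approx(diff, abs=1e-12)

    def test_matches_naive_loop_oracle(self, rng, demo_model):
        data = make_monotone_dataset(demo_model, [20, 15, 10], rng, delta=5.0)
        b = treatment_effect(data, demo_model)
        assert b == pytest.approx(naive_augmented_effect(data, demo_model), abs=1e-10)

    @pytest.mark.parametrize("counts", [[40, 28, 15], [12, 9, 5], [50, 50, 8]])
    def test_oracle_agreement_across_patterns(self, rng, uniform_model, counts):
        data = make_monotone_dataset(uniform_model, counts, rng, delta=2.0)
        assert treatment_effect(data, uniform_model) == pytest.approx(
            naive_augmented_effect(data, uniform_model), abs=1e-10
        )

    def test_no_final_data_in_an_arm_fails(self, rng, uniform_model):
        data = make_monotone_dataset(uniform_model, [10, 8, 4], rng)
        vals = data.values.copy()
        vals[data.arms == 1, 2] = np.nan
        broken = TrialDataset(vals, data.arms, data.entries, data.lags)
        with pytest.raises(InsufficientDataError):
            treatment_effect(broken, uniform_model)

    def test_unequal_arms_reduces_to_mean_difference_when_complete(self, rng, uniform_model):
        data = make_monotone_dataset(uniform_model, [[30, 30, 30], [22, 22, 22]], rng)
        b = treatment_effect(data, uniform_model)
        diff = data.values[data.arms == 1, 2].mean() - data.values[data.arms == 0, 2].mean()
        assert b == pytest.approx(diff, abs=1e-12)


class TestVariance:
    def test_worked_example_first_look_information(self, demo_model):
        info = expected_information(LookCounts.equal_arms([20, 15, 10]), demo_model)
        assert round(info, 3) == 0.019

    def test_worked_example_second_look_information(self, demo_model):
        info = expected_information(LookCounts.equal_arms([25, 20, 15]), demo_model)
        assert round(info, 3) == 0.028

    def test_zero_correlations_closed_form(self):
        model = EndpointModel.uniform(K=3, sigma=18.0, rho=0.0)
        var = treatment_effect_variance(LookCounts.equal_arms([20, 15, 10]), model)
        assert var == pytest.approx(2 * 18.0**2 / 10, rel=1e-12)

    def test_information_fraction_start_look(self):
        model = EndpointModel.uniform(K=3, sigma=20.0, rho=0.5)
        info = expected_information(LookCounts.equal_arms([50, 35, 15]), model)
        frac = information_fraction(info, final_information(85, 20.0), as_percent=True)
        assert round(frac, 1) == 21.4

    def test_information_fraction_zero_correlation(self):
        model = EndpointModel.uniform(K=3, sigma=20.0, rho=0.0)
        info = expected_information(LookCounts.equal_arms([50, 35, 15]), model)
        assert info == pytest.approx(15 / 800, rel=1e-12)
        frac = information_fraction(info, 85 / 800, as_percent=True)
        assert round(frac, 1) == 17.6

    def test_monte_carlo_variance_oracle(self, rng, demo_model):
        # empirical variance of B over 1e5 simulated datasets at fixed counts
        n1, n2, n3 = 20, 15, 10
        reps = 100_000
        chol = np.linalg.cholesky(demo_model.covariance())
        d = (
            rng.standard_normal((reps, n1, 3)) @ chol.T
            - rng.standard_normal((reps, n1, 3)) @ chol.T
        )
        b = (
            d[:, :n3, 2].mean(axis=1)
            + 0.5 * (d[:, n3:n1, 0] - d[:, :n1, 0].mean(axis=1, keepdims=True)).sum(axis=1) / n3
            + 0.5 * (d[:, n3:n2, 1] - d[:, :n2, 1].mean(axis=1, keepdims=True)).sum(axis=1) / n3
        )
        expected = treatment_effect_variance(LookCounts.equal_arms([n1, n2, n3]), demo_model)
        assert b.var() == pytest.approx(expected, rel=0.02)

    def test_augmentation_never_loses_information(self, rng):
        # var(B) <= 2 sigma^2 / N3 for random PSD correlation matrices
        for _ in range(200):
            a = rng.standard_normal((3, 3))
            cov = a @ a.T + 1e-6 * np.eye(3)
            d = np.sqrt(np.diag(cov))
            corr = cov / np.outer(d, d)
            np.fill_diagonal(corr, 1.0)
            model = EndpointModel(
                sigmas=[20.0] * 3, corr=corr, means_control=[0.0] * 3, means_active=[0.0] * 3
            )
            var = treatment_effect_variance(LookCounts.equal_arms([40, 25, 12]), model)
            assert var <= 2 * 400 / 12 + 1e-9

    def test_equality_when_counts_equal_or_uncorrelated(self):
        model = EndpointModel.uniform(K=3, sigma=20.0, rho=0.5)
        var = treatment_effect_variance(LookCounts.equal_arms([15, 15, 15]), model)
        assert var == pytest.approx(2 * 400 / 15, rel=1e-12)

    def test_variance_nonincreasing_in_rho13_when_rho12_zero(self):
        counts = LookCounts.equal_arms([40, 30, 20])
        last = np.inf
        for r in np.linspace(0.0, 0.9, 10):
            corr = np.array([[1, 0, r], [0, 1, 0.3], [r, 0.3, 1]])
            model = EndpointModel(
                sigmas=[20.0] * 3, corr=corr, means_control=[0.0] * 3, means_active=[0.0] * 3
            )
            var = treatment_effect_variance(counts, model)
            assert var <= last + 1e-12
            last = var

    def test_zero_final_count_fails(self, uniform_model):
        counts = LookCounts(np.array([[5, 5], [3, 3], [0, 0]]))
        with pytest.raises(InsufficientDataError):
            treatment_effect_variance(counts, uniform_model)

    def test_non_psd_correlation_rejected(self):
        corr = np.array([[1.0, 0.95, -0.95], [0.95, 1.0, 0.95], [-0.95, 0.95, 1.0]])
        with pytest.raises(ModelError):
            EndpointModel(sigmas=[1.0] * 3, corr=corr, means_control=[0.0] * 3, means_active=[0.0] * 3)


class TestGeneralized:
    def test_k3_specialization_is_identical(self, rng, demo_model):
        data = make_monotone_dataset(demo_model, [22, 16, 9], rng, delta=3.0)
        full = generalized_effect(data, demo_model)
        b = treatment_effect(data, demo_model)
        var = treatment_effect_variance(data.counts(), demo_model)
        assert full.B == pytest.approx(b, abs=1e-12)
        assert full.varB == pytest.approx(var, abs=1e-12)
        assert full.S == pytest.approx(b / math.sqrt(var), abs=1e-12)
        assert full.info == pytest.approx(1 / var, abs=1e-12)

    def test_k2_complete_reduces_to_plain_difference(self, rng):
        model = EndpointModel.uniform(K=2, sigma=15.0, rho=0.6)
        data = make_monotone_dataset(model, [18, 18], rng, delta=1.5)
        summary = generalized_effect(data, model)
        diff = data.values[data.arms == 1, 1].mean() - data.values[data.arms == 0, 1].mean()
        assert summary.B == pytest.approx(diff, abs=1e-12)
        assert summary.varB == pytest.approx(2 * 15.0**2 / 18, rel=1e-12)

    def test_k4_monte_carlo_oracle(self, rng):
        model = EndpointModel.uniform(K=4, sigma=10.0, rho=0.4, delta=2.0)
        counts = [16, 12, 9, 6]
        n1 = counts[0]
        reps = 100_000
        chol = np.linalg.cholesky(model.covariance())
        d = (
            rng.standard_normal((reps, n1, 4)) @ chol.T + model.means_active
            - (rng.standard_normal((reps, n1, 4)) @ chol.T + model.means_control)
        )
        nK = counts[-1]
        b = d[:, :nK, 3].mean(axis=1)
        for k in range(3):
            nk = counts[k]
            b += 0.4 * (d[:, nK:nk, k] - d[:, :nk, k].mean(axis=1, keepdims=True)).sum(axis=1) / nK
        expected_var = generalized_variance(LookCounts.equal_arms(counts), model)
        assert b.mean() == pytest.approx(2.0, abs=3 * b.std() / math.sqrt(reps))
        assert b.var() == pytest.approx(expected_var, rel=0.02)

    def test_k_below_two_rejected(self, rng):
        with pytest.raises(ModelError):
            EndpointModel.uniform(K=1, sigma=10.0, rho=0.0)


class TestUnbiasedness:
    def test_unbiased_under_nonzero_early_effects(self, rng):
        # early-endpoint treatment effects must not bias B (centred corrections)
        model = EndpointModel.uniform(K=3, sigma=20.0, rho=0.5, delta=[8.0, 6.0, 3.0])
        n1, n2, n3 = 30, 20, 10
        reps = 100_000
        chol = np.linalg.cholesky(model.covariance())
        d = (
            rng.standard_normal((reps, n1, 3)) @ chol.T + model.means_active
            - (rng.standard_normal((reps, n1, 3)) @ chol.T + model.means_control)
        )
        b = (
            d[:, :n3, 2].mean(axis=1)
            + 0.5 * (d[:, n3:n1, 0] - d[:, :n1, 0].mean(axis=1, keepdims=True)).sum(axis=1) / n3
            + 0.5 * (d[:, n3:n2, 1] - d[:, :n2, 1].mean(axis=1, keepdims=True)).sum(axis=1) / n3
        )
        mc_se = b.std() / math.sqrt(reps)
        assert abs(b.mean() - 3.0) < 3 * mc_se


class TestInformation:
    def test_final_information_worked_example(self):
        assert final_information(30, 18.0) == pytest.approx(30 / 648, rel=1e-12)
        assert round(final_information(30, 18.0), 3) == 0.046

    def test_fraction_endpoints(self, demo_model):
        i1 = expected_information(LookCounts.equal_arms([20, 15, 10]), demo_model)
        i2 = expected_information(LookCounts.equal_arms([25, 20, 15]), demo_model)
        fin = final_information(30, 18.0)
        assert round(information_fraction(i1, fin, as_percent=True)) == 42
        assert round(information_fraction(i2, fin, as_percent=True)) == 60
        assert information_fraction(fin, fin) == 1.0

    def test_overshoot_warns_not_fails(self):
        with pytest.warns(RuntimeWarning):
            frac = information_fraction(1.2, 1.0)
        assert frac == pytest.approx(1.2)

    def test_information_nondecreasing_as_counts_accrue(self, uniform_model):
        infos = [
            expected_information(LookCounts.equal_arms(c), uniform_model)
            for c in ([20, 12, 5], [25, 18, 9], [30, 24, 14], [40, 33, 21])
        ]
        assert all(b > a for a, b in zip(infos, infos[1:]))


class TestNuisance:
    def test_duplicate_endpoint_clamps_correlation(self, rng, uniform_model):
        data = make_monotone_dataset(uniform_model, [25, 25, 25], rng)
        vals = data.values.copy()
        vals[:, 1] = vals[:, 2]  # 6m identical to 12m
        dup = TrialDataset(vals, data.arms, data.entries, data.lags)
        est = estimate_nuisance(dup)
        assert est.corr_hat[1, 2] == pytest.approx(0.99, abs=5e-3)

    def test_consistency_on_large_sample(self, rng):
        model = EndpointModel.uniform(K=3, sigma=20.0, rho=0.5, delta=5.0)
        data = make_monotone_dataset(model, [10_000, 10_000, 10_000], rng)
        est = estimate_nuisance(data)
        assert np.allclose(est.sigma_hats, 20.0, atol=0.5)
        off = est.corr_hat[np.triu_indices(3, k=1)]
        assert np.allclose(off, 0.5, atol=0.03)

    def test_arm_means_do_not_leak_into_estimates(self, rng):
        base = EndpointModel.uniform(K=3, sigma=20.0, rho=0.5)
        shifted = EndpointModel(
            sigmas=base.sigmas,
            corr=base.corr,
            means_control=[0.0, 0.0, 0.0],
            means_active=[30.0, 25.0, 40.0],
        )
        state = rng.bit_generator.state
        d0 = make_monotone_dataset(base, [200, 150, 100], rng)
        rng.bit_generator.state = state
        d1 = make_monotone_dataset(shifted, [200, 150, 100], rng)
        e0, e1 = estimate_nuisance(d0), estimate_nuisance(d1)
        assert np.allclose(e0.sigma_hats, e1.sigma_hats, atol=1e-8)
        assert np.allclose(e0.corr_hat, e1.corr_hat, atol=1e-8)

    def test_fallback_when_pairs_inestimable(self, rng, uniform_model):
        # nobody has both 3m and 12m observed -> rho_13 falls back to assumed
        data = make_monotone_dataset(uniform_model, [30, 20, 10], rng)
        vals = data.values.copy()
        vals[~np.isnan(vals[:, 2]), 0] = np.nan
        sparse = TrialDataset(vals, data.arms, data.entries, data.lags)
        est = estimate_nuisance(sparse, fallback=uniform_model)
        assert est.corr_hat[0, 2] == pytest.approx(0.5, abs=0.35)  # PSD repair may nudge it
        assert est.n_pairs[0, 2] == 0

    def test_too_few_observations_fails(self, rng, uniform_model):
        data = make_monotone_dataset(uniform_model, [5, 3, 1], rng)
        with pytest.raises(InsufficientDataError):
            estimate_nuisance(data)

    def test_estimates_feed_summary(self, rng, uniform_model):
        data = make_monotone_dataset(uniform_model, [40, 30, 20], rng, delta=6.0)
        est = estimate_nuisance(data, fallback=uniform_model)
        summary = summarize(data, est)
        assert summary.varB > 0
        assert summary.S == pytest.approx(summary.B / math.sqrt(summary.varB))


class TestSampleSize:
    def test_start_reference_design(self):
        per_group, total = fixed_design_sample_size(10.0, 20.0, power=0.9, alpha_two_sided=0.05)
        assert per_group == 85
        assert total == 170

    def test_doubling_delta_quarters_n(self):
        n1, _ = fixed_design_sample_size(5.0, 20.0)
        n2, _ = fixed_design_sample_size(10.0, 20.0)
        assert n1 == pytest.approx(4 * n2, abs=4)  # before-ceiling scaling, allow rounding

    def test_grid_search_oracle(self):
        from scipy.stats import norm

        delta, sigma, alpha, power = 10.0, 20.0, 0.05, 0.9
        z_a = norm.ppf(1 - alpha / 2)
        n = 1
        while True:
            achieved = norm.cdf(delta / (sigma * math.sqrt(2.0 / n)) - z_a)
            if achieved >= power:
                break
            n += 1
        assert fixed_design_sample_size(delta, sigma, power, alpha)[0] == n

    def test_zero_delta_rejected(self):
        with pytest.raises(ModelError):
            fixed_design_sample_size(0.0, 20.0)
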