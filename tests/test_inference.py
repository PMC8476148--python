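"""Composite likelihood, fitting, and significance utilities."""

import numpy as np
import pytest
from scipy.stats import poisson

from jointdfe.demography import DemographicModel, SelectionRegime
from jointdfe.diffusion import EngineConfig, expected_joint_afs
from jointdfe.inference import (
    FitError,
    FitOptions,
    MutationClassTable,
    fit_demography,
    fit_dfe,
    fitted_model,
    partition_theta,
    poisson_loglik,
    w_significance,
)
from jointdfe.integrate_dfe import ThetaConfig, expected_selected_afs
from jointdfe.dfe import LognormalMixtureDFE
from jointdfe.spectrum import JointSpectrum, SampleConfig, SpectrumError


def _spec(vals):
    vals = np.asarray(vals, dtype=float)
    n1, n2 = vals.shape[0] - 1, vals.shape[1] - 1
    return JointSpectrum(vals, SampleConfig(n1, n2))


class TestPoissonLoglik:
    def test_unit_rates_and_counts_closed_form(self):
        # every unmasked lambda = S = 1: each term is -1 + 1*ln 1 - ln 1!
        model = _spec(np.ones((4, 4)))
        data = _spec(np.ones((4, 4)))
        n_unmasked = 16 - 2
        assert poisson_loglik(model, data) == pytest.approx(-n_unmasked)

    def test_matches_scipy_pmf_oracle(self, rng):
        lam = rng.gamma(2.0, 3.0, size=(5, 5))
        counts = rng.poisson(5.0, size=(5, 5)).astype(float)
        model, data = _spec(lam), _spec(counts)
        mask = model.mask
        oracle = poisson.logpmf(counts[~mask], lam[~mask]).sum()
        assert poisson_loglik(model, data) == pytest.approx(oracle, abs=1e-10)

    def test_additive_over_disjoint_entry_subsets(self, rng):
        lam = rng.gamma(2.0, 3.0, size=(5, 5))
        counts = rng.poisson(5.0, size=(5, 5)).astype(float)
        full = poisson_loglik(_spec(lam), _spec(counts))
        # split the unmasked entries via complementary extra masks
        extra = np.zeros((5, 5), dtype=bool)
        extra[:, :3] = True
        m1 = JointSpectrum(lam, SampleConfig(4, 4), mask=extra)
        m2 = JointSpectrum(lam, SampleConfig(4, 4), mask=~extra)
        d1 = JointSpectrum(counts, SampleConfig(4, 4), mask=extra)
        d2 = JointSpectrum(counts, SampleConfig(4, 4), mask=~extra)
        assert poisson_loglik(m1, d1) + poisson_loglik(m2, d2) == pytest.approx(
            full, abs=1e-10)

    def test_zero_expectation_with_observation_is_minus_inf(self):
        lam = np.ones((4, 4))
        lam[1, 1] = 0.0
        counts = np.ones((4, 4))
        with pytest.warns(RuntimeWarning):
            assert poisson_loglik(_spec(lam), _spec(counts)) == -np.inf

    def test_shape_mismatch_rejected(self):
        with pytest.raises(SpectrumError):
            poisson_loglik(_spec(np.ones((4, 4))), _spec(np.ones((5, 4))))


class TestFitDemography:
    def test_recovers_truth_from_expected_data(self):
        truth = DemographicModel("split_mig", nu1=2.0, nu2=0.8, T=0.2,
                                 m12=1.0, m21=0.5)
        sample = SampleConfig(10, 10)
        data = expected_joint_afs(truth, SelectionRegime(0.0, 0.0),
                                  sample) * 5000.0
        start = DemographicModel("split_mig", nu1=1.5, nu2=1.0, T=0.15,
                                 m12=0.8, m21=0.8)
        res = fit_demography(data, start, FitOptions(starts=2),
                             fit_misid=False)
        assert res.converged
        for name, true_val in truth.param_dict().items():
            assert res.params[name] == pytest.approx(true_val, rel=1e-2)
        assert res.params["theta_neu"] == pytest.approx(5000.0, rel=1e-3)
        refit = fitted_model(res, start)
        assert refit.id == "split_mig"

    def test_theta_profile_is_exact_ratio_of_sums(self):
        # for any fixed shape, profiled theta equals sum(data)/sum(model)
        truth = DemographicModel("split_no_mig", nu1=1.0, nu2=1.0, T=0.1)
        sample = SampleConfig(6, 6)
        F = expected_joint_afs(truth, SelectionRegime(0.0, 0.0), sample)
        data = F * 1234.5
        res = fit_demography(data, truth, FitOptions(starts=1, maxiter=0),
                             fit_misid=False, fixed={"nu2": 1.0, "T": 0.1})
        assert res.params["theta_neu"] == pytest.approx(1234.5, rel=1e-9)


class TestFitDFE:
    def test_recovers_truth_from_expected_data(self, truth_cache, theta_ns):
        truth = LognormalMixtureDFE(3.6, 5.1, 0.9)
        data = expected_selected_afs(truth_cache, truth, theta_ns)
        res = fit_dfe(data, truth_cache,
                      LognormalMixtureDFE(3.0, 4.0, 0.7), theta_ns,
                      FitOptions(starts=2), fit_misid=False)
        assert res.converged
        assert res.params["mu"] == pytest.approx(3.6, rel=1e-2)
        assert res.params["sigma"] == pytest.approx(5.1, rel=1e-2)
        assert res.params["w"] == pytest.approx(0.9, abs=0.01)

    def test_fitted_loglik_not_below_truth_loglik(self, truth_cache, theta_ns):
        truth = LognormalMixtureDFE(3.6, 5.1, 0.9)
        data = expected_selected_afs(truth_cache, truth, theta_ns)
        res = fit_dfe(data, truth_cache, LognormalMixtureDFE(3.0, 4.0, 0.7),
                      theta_ns, FitOptions(starts=2), fit_misid=False)
        ll_truth = poisson_loglik(data, data)
        assert res.loglik >= ll_truth - 1e-6

    def test_misid_parameter_recovered(self, truth_cache, theta_ns):
        from jointdfe.integrate_dfe import misid_transform
        truth = LognormalMixtureDFE(3.6, 5.1, 0.9)
        data = misid_transform(
            expected_selected_afs(truth_cache, truth, theta_ns), 0.05)
        res = fit_dfe(data, truth_cache, LognormalMixtureDFE(3.0, 4.0, 0.7),
                      theta_ns, FitOptions(starts=2), fit_misid=True)
        assert res.params["p_misid"] == pytest.approx(0.05, abs=5e-3)
        assert res.params["w"] == pytest.approx(0.9, abs=0.02)

    def test_sample_size_mismatch_rejected(self, truth_cache, theta_ns):
        bad = JointSpectrum(np.ones((5, 5)), SampleConfig(4, 4))
        with pytest.raises(FitError):
            fit_dfe(bad, truth_cache, LognormalMixtureDFE(3.0, 4.0, 0.7),
                    theta_ns)


class TestWSignificance:
    def test_w_equal_to_null_gives_p_one(self):
        out = w_significance([(1.0, 0.05)])
        assert out["p"][0] == pytest.approx(1.0)

    def test_two_sigma_below_null(self):
        out = w_significance([(0.9, 0.05)])
        assert out["z"][0] == pytest.approx(-2.0)
        assert out["p"][0] == pytest.approx(0.0455, abs=2e-4)

    def test_benjamini_hochberg_adjustment(self):
        out = w_significance([(1 - 2.576 * 0.01, 0.01),
                              (1 - 2.326 * 0.01, 0.01),
                              (1 - 2.054 * 0.01, 0.01)])
        np.testing.assert_allclose(out["p"], [0.01, 0.02, 0.04], atol=2e-4)
        np.testing.assert_allclose(out["p_fdr"], [0.03, 0.03, 0.04], atol=6e-4)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(FitError):
            w_significance([(0.9, 0.0)])


class TestPartitionTheta:
    def test_equal_rates_and_counts_split_evenly(self):
        table = MutationClassTable(u=np.ones(12), d=np.full(12, 7.0),
                                   t=np.full(12, 7.0))
        assert partition_theta(100.0, table) == pytest.approx((50.0, 50.0))

    def test_single_type_ratio(self):
        table = MutationClassTable(u=[1.0], d=[3.0], t=[1.0])
        assert partition_theta(1.0, table) == pytest.approx((0.75, 0.25))

    def test_rate_weighted_proportions(self):
        table = MutationClassTable(u=[1.0, 2.0], d=[10.0, 0.0], t=[0.0, 10.0])
        p_del, p_tol = partition_theta(1.0, table)
        assert p_del == pytest.approx(1.0 / 3.0)
        assert p_tol == pytest.approx(2.0 / 3.0)
        assert p_del + p_tol == pytest.approx(1.0)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(FitError):
            MutationClassTable(u=[1.0], d=[0.0], t=[0.0])
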