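"""Joint-DFE densities, sampling, and correlation semantics."""

import numpy as np
import pytest
from scipy import integrate, stats

from jointdfe.dfe import (
    BivariateLognormalDFE,
    DFEError,
    GammaMixtureDFE,
    LognormalMixtureDFE,
    dfe_correlation,
    joint_pdf,
    make_dfe,
    marginal_pdf,
    sample_pairs,
)


class TestMarginalDensities:
    def test_lognormal_scalar_value(self):
        # direct evaluation of the lognormal density at gamma = -1:
        # 1/(1 * 5.1 * sqrt(2 pi)) * exp(-(0 - 3.6)^2 / (2 * 5.1^2)) ~ 0.0610
        dfe = LognormalMixtureDFE(mu=3.6, sigma=5.1, w=0.9)
        assert marginal_pdf(dfe, -1.0) == pytest.approx(0.0610, abs=5e-4)

    @pytest.mark.parametrize("dfe", [
        LognormalMixtureDFE(mu=3.6, sigma=5.1, w=0.5),
        GammaMixtureDFE(alpha=0.4, beta=1400.0, w=0.5),
    ])
    def test_marginal_normalizes_to_one(self, dfe):
        total, _ = integrate.quad(lambda g: float(dfe.marginal_pdf(-g)),
                                  0.0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_gamma_family_mean_is_alpha_beta(self):
        dfe = GammaMixtureDFE(alpha=0.4, beta=1400.0, w=0.9)
        mean, _ = integrate.quad(lambda g: g * float(dfe.marginal_pdf(-g)),
                                 0.0, np.inf, limit=400)
        assert mean == pytest.approx(0.4 * 1400.0, rel=1e-6)  # = 560

    def test_nonnegative_gamma_rejected(self):
        dfe = LognormalMixtureDFE(mu=3.6, sigma=5.1, w=0.9)
        with pytest.raises(DFEError):
            marginal_pdf(dfe, 0.5)

    @pytest.mark.parametrize("kw", [
        dict(mu=1.0, sigma=0.0, w=0.5), dict(mu=1.0, sigma=1.0, w=1.5),
    ])
    def test_invalid_lognormal_parameters(self, kw):
        with pytest.raises(DFEError):
            LognormalMixtureDFE(**kw)


class TestBivariateLognormal:
    dfe = BivariateLognormalDFE(mu1=1.0, sigma1=0.8, mu2=1.5, sigma2=1.2,
                                rho=0.6)

    def test_rho_zero_factorizes_into_marginals(self):
        d0 = BivariateLognormalDFE(mu1=1.0, sigma1=0.8, mu2=1.5, sigma2=1.2,
                                   rho=0.0)
        g = -np.array([0.5, 1.0, 3.0, 10.0])
        for g1 in g:
            for g2 in g:
                prod = (d0.marginal_pdf(g1, pop=1) * d0.marginal_pdf(g2, pop=2))
                assert joint_pdf(d0, g1, g2) == pytest.approx(float(prod),
                                                              rel=1e-12)

    def test_exchange_symmetry_with_symmetric_parameters(self):
        d = BivariateLognormalDFE(mu1=1.0, sigma1=0.8, mu2=1.0, sigma2=0.8,
                                  rho=0.5)
        assert joint_pdf(d, -0.5, -4.0) == pytest.approx(
            float(joint_pdf(d, -4.0, -0.5)), rel=1e-12)

    def test_joint_density_normalizes_over_negative_quadrant(self):
        total, _ = integrate.dblquad(
            lambda y, x: float(self.dfe.joint_pdf(-np.exp(x), -np.exp(y)))
            * np.exp(x) * np.exp(y),
            -8, 10, lambda x: -8, lambda x: 10)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_rect_prob_consistent_with_sampling(self, rng):
        pairs = -self.dfe.sample_pairs(200_000, rng)
        p_emp = np.mean((pairs[:, 0] > 1.0) & (pairs[:, 0] <= 10.0)
                        & (pairs[:, 1] > 2.0) & (pairs[:, 1] <= 20.0))
        p = self.dfe.rect_prob_mag(1.0, 10.0, 2.0, 20.0)
        assert p == pytest.approx(p_emp, abs=3e-3)

    def test_mixture_joint_pdf_refused(self):
        with pytest.raises(DFEError):
            joint_pdf(LognormalMixtureDFE(1.0, 1.0, 0.5), -1.0, -1.0)


class TestMixtureSemantics:
    def test_w_one_gives_identical_pairs(self):
        pairs = sample_pairs(LognormalMixtureDFE(3.6, 5.1, 1.0), 1000, seed=1)
        np.testing.assert_array_equal(pairs[:, 0], pairs[:, 1])

    @pytest.mark.parametrize("w", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_log_scale_correlation_equals_mixture_weight(self, w):
        pairs = sample_pairs(LognormalMixtureDFE(3.6, 5.1, w), 100_000, seed=7)
        logs = np.log(-pairs)
        r = np.corrcoef(logs[:, 0], logs[:, 1])[0, 1]
        assert r == pytest.approx(w, abs=0.02)

    def test_gamma_mixture_correlation_matches_weight(self):
        pairs = sample_pairs(GammaMixtureDFE(0.4, 1400.0, 0.6), 100_000, seed=3)
        r = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert r == pytest.approx(0.6, abs=0.02)

    def test_marginals_of_mixture_match_g1d(self):
        # two-sample KS between the pop-2 marginal of sampled pairs and
        # direct draws from the marginal must not reject at alpha = 0.01
        dfe = LognormalMixtureDFE(3.6, 5.1, 0.5)
        pairs = sample_pairs(dfe, 10_000, seed=11)
        direct = dfe._marginal().rvs(size=10_000,
                                     random_state=np.random.default_rng(13))
        ks = stats.ks_2samp(-pairs[:, 1], direct)
        assert ks.pvalue > 0.01

    def test_sampling_reproducible_given_seed(self):
        a = sample_pairs(LognormalMixtureDFE(3.6, 5.1, 0.9), 100, seed=5)
        b = sample_pairs(LognormalMixtureDFE(3.6, 5.1, 0.9), 100, seed=5)
        np.testing.assert_array_equal(a, b)


class TestCorrelationStatistic:
    def test_mixture_reports_weight(self):
        assert dfe_correlation(LognormalMixtureDFE(3.6, 5.1, 0.9)) == 0.9
        assert dfe_correlation(GammaMixtureDFE(0.4, 1400.0, 0.35)) == 0.35

    def test_bivariate_reports_log_scale_rho(self):
        d = BivariateLognormalDFE(1.0, 1.0, 1.0, 1.0, rho=0.0)
        assert dfe_correlation(d) == 0.0

    def test_factory_by_family_name(self):
        d = make_dfe("lognormal_mixture", mu=1.0, sigma=2.0, w=0.5)
        assert isinstance(d, LognormalMixtureDFE)
        with pytest.raises(DFEError):
            make_dfe("uniform")
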