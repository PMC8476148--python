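"""DFE integration over the cache: misidentification, tails, expectations."""

import numpy as np
import pytest

from jointdfe.dfe import BivariateLognormalDFE, LognormalMixtureDFE
from jointdfe.integrate_dfe import (
    IntegrationError,
    MisidParam,
    ThetaConfig,
    _trapz_weights,
    expected_selected_afs,
    misid_transform,
    tail_weights,
)
from jointdfe.cache import build_gamma_grid
from jointdfe.spectrum import JointSpectrum, SampleConfig


class TestMisidTransform:
    def _spec(self, rng):
        vals = rng.gamma(2.0, 5.0, size=(6, 5))
        return JointSpectrum(vals, SampleConfig(5, 4))

    def test_p_zero_is_identity(self, rng):
        s = self._spec(rng)
        np.testing.assert_array_equal(misid_transform(s, 0.0).values, s.values)

    def test_p_one_reverses_both_axes(self, rng):
        s = self._spec(rng)
        np.testing.assert_array_equal(misid_transform(s, 1.0).values,
                                      s.values[::-1, ::-1])

    @pytest.mark.parametrize("p", [0.0, 0.1, 0.5, 0.9, 1.0])
    def test_unmasked_mass_conserved(self, rng, p):
        s = self._spec(rng)
        out = misid_transform(s, MisidParam(p))
        assert out.total() == pytest.approx(s.total(), rel=1e-12)

    def test_probability_outside_unit_interval_rejected(self, rng):
        with pytest.raises(IntegrationError):
            misid_transform(self._spec(rng), 1.5)


class TestThetaConfig:
    def test_theta_sel_is_ratio_times_theta_neu(self):
        th = ThetaConfig(theta_neu=6000.0, ratio_NS=2.31)
        assert th.theta_sel == pytest.approx(6000.0 * 2.31)

    def test_from_theta_sel_inverts(self):
        th = ThetaConfig.from_theta_sel(13842.5, ratio_NS=2.5)
        assert th.theta_sel == pytest.approx(13842.5)

    def test_positive_rates_required(self):
        with pytest.raises(IntegrationError):
            ThetaConfig(theta_neu=-1.0)


class TestTailWeights:
    dfe = LognormalMixtureDFE(mu=3.6, sigma=5.1, w=0.9)

    def test_three_way_split_sums_to_one(self):
        t = tail_weights(self.dfe, (1e-4, 2000.0))
        assert t["below"] + t["within"] + t["above"] == pytest.approx(1.0,
                                                                      abs=1e-6)

    def test_mass_beyond_strongest_cached_selection(self):
        # Phi((ln 2000 - 3.6) / 5.1) upper tail ~ 0.216
        t = tail_weights(self.dfe, (1e-4, 2000.0))
        assert t["above"] == pytest.approx(0.216, abs=2e-3)

    def test_mass_below_weakest_cached_selection(self):
        # Phi((ln 1e-4 - 3.6) / 5.1) ~ 0.006
        t = tail_weights(self.dfe, (1e-4, 2000.0))
        assert t["below"] == pytest.approx(0.006, abs=1e-3)

    def test_bivariate_blocks_sum_to_one(self):
        d = BivariateLognormalDFE(3.6, 5.1, 3.6, 5.1, rho=0.8)
        t = tail_weights(d, (1e-4, 2000.0))
        assert t["joint"].sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(t["joint"] >= 0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(IntegrationError):
            tail_weights(self.dfe, (2000.0, 1e-4))


class TestQuadratureAccounting:
    def test_trapezoid_plus_tails_approach_unity_under_refinement(self):
        # the full weight bookkeeping (trapezoid node masses + exact tail
        # mass) converges to 1; at 400 points it is within 1e-3
        dfe = LognormalMixtureDFE(mu=3.6, sigma=5.1, w=0.9)
        totals = {}
        for n in (50, 400):
            g = build_gamma_grid(n, (1e-4, 2000.0))
            node_mass = _trapz_weights(g) * dfe._marginal().pdf(g)
            t = tail_weights(dfe, (g[0], g[-1]))
            totals[n] = node_mass.sum() + t["below"] + t["above"]
        assert abs(totals[400] - 1.0) < 1e-3
        assert abs(totals[400] - 1.0) < abs(totals[50] - 1.0)


class TestExpectedSelectedAFS:
    theta = ThetaConfig.from_theta_sel(1000.0)

    def test_w_one_uses_only_the_diagonal_cache(self, small_cache):
        dfe = LognormalMixtureDFE(2.0, 1.0, 1.0)
        full = expected_selected_afs(small_cache, dfe, self.theta)
        # rebuilding the 1D integral by hand from the diagonal + tails
        g = small_cache.grid
        node_mass = _trapz_weights(g) * dfe._marginal().pdf(g)
        t = tail_weights(dfe, (g[0], g[-1]))
        by_hand = np.tensordot(node_mass, small_cache.diagonal(), axes=(0, 0))
        by_hand += t["below"] * small_cache.neutral.values
        by_hand += t["above"] * small_cache.diagonal()[-1]
        np.testing.assert_allclose(full.values,
                                   np.clip(by_hand, 0, None) * 1000.0,
                                   rtol=1e-12)

    def test_theta_sel_scales_every_entry(self, small_cache):
        dfe = LognormalMixtureDFE(3.6, 5.1, 0.9)
        e1 = expected_selected_afs(small_cache, dfe, self.theta)
        e2 = expected_selected_afs(small_cache, dfe,
                                   ThetaConfig.from_theta_sel(2000.0))
        np.testing.assert_allclose(e2.values, 2.0 * e1.values, rtol=1e-12)

    def test_narrow_dfe_at_grid_node_recovers_cached_spectrum(self, truth_demo):
        # a narrow lognormal centred on a grid node collapses onto that
        # node's cached spectrum; sigma must stay resolved by the grid
        # (a sub-cell spike cannot be normalized by the trapezoid rule)
        from jointdfe.cache import build_cache, build_gamma_grid
        from jointdfe.spectrum import SampleConfig

        grid = build_gamma_grid(24, (0.3, 5.0))
        cache = build_cache(truth_demo, SampleConfig(6, 6), grid)
        k = 12
        dfe = LognormalMixtureDFE(mu=float(np.log(grid[k])), sigma=0.15, w=1.0)
        E = expected_selected_afs(cache, dfe, self.theta)
        m = ~cache.mask
        np.testing.assert_allclose(E.values[m],
                                   1000.0 * cache.spectra[k, k][m],
                                   rtol=2e-2)

    def test_higher_correlation_increases_top_shared_cell(self, small_cache):
        vals = []
        for w in (0.0, 0.25, 0.5, 0.75, 1.0):
            E = expected_selected_afs(
                small_cache, LognormalMixtureDFE(3.6, 5.1, w), self.theta)
            vals.append(E.values[-2, -2])
        assert np.all(np.diff(vals) > 0)

    def test_misid_applied_after_scaling(self, small_cache):
        dfe = LognormalMixtureDFE(3.6, 5.1, 0.9)
        plain = expected_selected_afs(small_cache, dfe, self.theta)
        flipped = expected_selected_afs(small_cache, dfe, self.theta,
                                        misid=1.0)
        np.testing.assert_allclose(flipped.values, plain.values[::-1, ::-1],
                                   rtol=1e-12)

    def test_bivariate_rho_zero_matches_independent_mixture(self, small_cache):
        # at rho = 0 the bivariate density factorizes, so it must agree
        # with the w = 0 mixture that shares its marginal
        biv = BivariateLognormalDFE(2.0, 1.2, 2.0, 1.2, rho=0.0)
        mix = LognormalMixtureDFE(2.0, 1.2, 0.0)
        Eb = expected_selected_afs(small_cache, biv, self.theta)
        Em = expected_selected_afs(small_cache, mix, self.theta)
        m = ~small_cache.mask
        np.testing.assert_allclose(Eb.values[m], Em.values[m], rtol=2e-2)
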