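"""Diffusion engine: analytic limits, invariances, and the WF oracle."""

import numpy as np
import pytest
from scipy.stats import binom

from jointdfe.demography import DemographicModel, DemographyError, SelectionRegime
from jointdfe.diffusion import (
    EngineConfig,
    equilibrium_spectrum_1d,
    expected_joint_afs,
)
from jointdfe.spectrum import SampleConfig
from jointdfe.wf import _equilibrium_counts

NEUTRAL = SelectionRegime(0.0, 0.0, 0.5)


def _wf_equilibrium_sample(gamma, h, n, twoN):
    """Sample AFS from the discrete WF sojourn-time (transition-matrix) chain."""
    e = _equilibrium_counts(twoN, gamma, h, 1.0, twoN)
    x = np.arange(twoN + 1) / twoN
    D = binom.pmf(np.arange(n + 1)[None, :], n, x[:, None])
    return (D.T @ e)[1:-1]


def _wf_equilibrium_extrap(gamma, h, n, sizes=(400, 800, 1600)):
    """Richardson extrapolation of the WF chain to 1/N -> 0."""
    deltas = [1.0 / s for s in sizes]
    out = np.zeros(n - 1)
    for k, (s, d) in enumerate(zip(sizes, deltas)):
        coef = 1.0
        for l, dl in enumerate(deltas):
            if l != k:
                coef *= (0.0 - dl) / (d - dl)
        out += coef * _wf_equilibrium_sample(gamma, h, n, s)
    return out


class TestEquilibrium1D:
    @pytest.mark.parametrize("n", [2, 4, 10, 20])
    def test_neutral_equilibrium_is_theta_over_i(self, n):
        f = equilibrium_spectrum_1d(0.0, 0.5, n)
        expected = 1.0 / np.arange(1, n)
        np.testing.assert_allclose(f, expected, rtol=2e-3)

    def test_theta_scales_linearly(self):
        f1 = equilibrium_spectrum_1d(-3.0, 0.5, 8, theta=1.0)
        f2 = equilibrium_spectrum_1d(-3.0, 0.5, 8, theta=7.5)
        np.testing.assert_allclose(f2, 7.5 * f1, rtol=1e-12)

    @pytest.mark.parametrize("gamma,h", [
        (-2.0, 0.5), (-50.0, 0.5), (-5.0, 0.25), (-5.0, 0.75),
    ])
    def test_matches_wright_fisher_sojourn_oracle(self, gamma, h):
        # WF chain extrapolated in 1/N (raw 2N=400 keeps O(1/N) bias)
        f = equilibrium_spectrum_1d(gamma, h, 10)
        oracle = _wf_equilibrium_extrap(gamma, h, 10)
        np.testing.assert_allclose(f, oracle, rtol=2e-2)

    def test_sample_size_below_two_rejected(self):
        with pytest.raises(DemographyError):
            equilibrium_spectrum_1d(0.0, 0.5, 1)

    def test_nonfinite_gamma_rejected(self):
        with pytest.raises(DemographyError):
            equilibrium_spectrum_1d(np.nan, 0.5, 6)


class TestExpectedJointAFS:
    def test_symmetric_model_gives_symmetric_spectrum(self):
        demo = DemographicModel("split_mig", nu1=1.0, nu2=1.0, T=0.05,
                                m12=1.0, m21=1.0)
        F = expected_joint_afs(demo, NEUTRAL, SampleConfig(6, 6))
        vals = np.where(F.mask, 0.0, F.values)
        np.testing.assert_allclose(vals, vals.T, rtol=5e-3, atol=1e-8)

    def test_long_isolation_approaches_independent_equilibria(self):
        # deep no-migration split: shared polymorphism dies out and each
        # marginal returns to the single-population equilibrium
        demo = DemographicModel("split_no_mig", nu1=1.0, nu2=1.0, T=4.0)
        n = 6
        F = expected_joint_afs(demo, NEUTRAL, SampleConfig(n, n))
        interior = F.values[1:-1, 1:-1]
        assert interior.max() < 5e-3  # off-axis (shared) mass is gone
        marg1 = F.values[1:-1, :].sum(axis=1)
        np.testing.assert_allclose(marg1, 1.0 / np.arange(1, n), rtol=2e-2)

    def test_weak_selection_converges_to_neutral(self):
        demo = DemographicModel("split_mig", nu1=1.0, nu2=1.0, T=0.1,
                                m12=1.0, m21=1.0)
        F0 = expected_joint_afs(demo, NEUTRAL, SampleConfig(6, 6))
        Fw = expected_joint_afs(demo, SelectionRegime(-1e-4, -1e-4),
                                SampleConfig(6, 6))
        m = ~F0.mask
        np.testing.assert_allclose(Fw.values[m], F0.values[m], rtol=1e-2)

    def test_stronger_selection_reduces_shared_high_frequency_mass(self):
        demo = DemographicModel("split_mig", nu1=1.0, nu2=1.0, T=0.1,
                                m12=1.0, m21=1.0)
        top = []
        for g in (0.0, -1.0, -5.0, -20.0, -100.0):
            F = expected_joint_afs(demo, SelectionRegime(g, g), SampleConfig(6, 6))
            top.append(F.values[-2, -2])
        assert np.all(np.diff(top) < 0)

    def test_unsupported_model_payload_rejected(self):
        with pytest.raises(DemographyError):
            expected_joint_afs("IM", NEUTRAL, SampleConfig(4, 4))

    def test_deterministic_given_inputs(self):
        demo = DemographicModel("IM", s_frac=0.6, nu1=2.0, nu2=1.5, T=0.1,
                                m12=1.0, m21=0.5)
        F1 = expected_joint_afs(demo, SelectionRegime(-2.0, -3.0), SampleConfig(5, 5))
        F2 = expected_joint_afs(demo, SelectionRegime(-2.0, -3.0), SampleConfig(5, 5))
        np.testing.assert_array_equal(F1.values, F2.values)
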