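"""Admittance factors, trigger-point PSD and quadrature statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurice.closed import one_dendrite_stats, two_dendrite_stats
from neurice.exceptions import ConvergenceError, UnsupportedMorphologyError
from neurice.params import build_morphology
from neurice.spectral import (SpectrumGrid, gamma_factor, mean_at_trigger,
                              rel_admittance, sealed_end_psd, spectrum_table,
                              stats_from_psd, trigger_psd)

EPS5 = 70.0 / 65.0
OMEGAS = np.geomspace(1e-3, 1e3, 40)


class TestGammaFactor:
    def test_dc_value_is_unity(self):
        assert gamma_factor(0.0, 10.0) == 1.0 + 0.0j

    @given(st.floats(1e-4, 1e4), st.floats(0.1, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_modulus_and_real_part_identities(self, om, tau):
        g = gamma_factor(om, tau)
        mod2 = math.sqrt(1.0 + (om * tau) ** 2)
        assert abs(g) ** 2 == pytest.approx(mod2, rel=1e-12)
        assert g.real == pytest.approx(math.sqrt((mod2 + 1.0) / 2.0), rel=1e-12)
        assert g.real >= 1.0

    def test_conjugate_symmetry(self):
        g = gamma_factor(3.0, 10.0)
        assert gamma_factor(-3.0, 10.0) == pytest.approx(np.conj(g))


class TestRelAdmittance:
    def test_single_neurite_is_unity_at_all_frequencies(self, one_dendrite):
        m, _ = one_dendrite
        assert np.allclose(rel_admittance(m, OMEGAS), 1.0)

    def test_identical_passive_twin_gives_half(self):
        """With no mean drive (epsilon = 1) an axon with the dendrite's
        geometry has equal admittance, so each carries half."""
        m, _ = build_morphology(mu=0.0, sigma_s=1.0, a_ratio=1.0)
        assert m.axon.lam == pytest.approx(m.dendrite.lam)
        assert np.allclose(rel_admittance(m, OMEGAS), 0.5)

    def test_dc_value_dendrite_plus_axon(self):
        m, _ = build_morphology(mu=5.0, sigma_s=1.0, lambda_alpha=100.0)
        f0 = rel_admittance(m, 0.0)
        expected = 1.0 / (1.0 + 100.0 ** 3 / (EPS5 ** 2 * 200.0 ** 3))
        assert f0.real == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.9027, abs=5e-5)

    def test_admittance_fractions_sum_to_one(self, dendrite_axon):
        m, _ = dendrite_axon
        f = rel_admittance(m, OMEGAS)
        g1 = gamma_factor(OMEGAS, m.dendrite.tau)
        ga = gamma_factor(OMEGAS, m.axon.tau)
        w1, wa = m.dendrite.admittance_weight, m.axon.admittance_weight
        axon_frac = wa * ga / (w1 * g1 + wa * ga)
        assert np.allclose(f + axon_frac, 1.0, atol=1e-12)

    def test_soma_fractions_sum_to_one(self, soma_model):
        m, _ = soma_model
        f = rel_admittance(m, OMEGAS)
        g1 = gamma_factor(OMEGAS, m.dendrite.tau)
        ga = gamma_factor(OMEGAS, m.axon.tau)
        g0sq = 1.0 + 1j * OMEGAS * m.soma.tau_0
        denom = g0sq + m.soma.rho_1 * g1 + m.soma.rho_alpha * ga
        total = f + m.soma.rho_alpha * ga / denom + g0sq / denom
        assert np.allclose(total, 1.0, atol=1e-12)

    @given(st.floats(0.0, 12.0), st.floats(0.05, 1.0), st.integers(1, 16))
    @settings(max_examples=60, deadline=None)
    def test_bounded_and_conjugate_symmetric(self, mu, a_ratio, n):
        m, _ = build_morphology(mu=mu, sigma_s=1.0, a_ratio=a_ratio, n=n)
        f_pos = rel_admittance(m, OMEGAS)
        f_neg = rel_admittance(m, -OMEGAS)
        assert np.all(np.abs(f_pos) <= 1.0 + 1e-12)
        assert np.allclose(f_neg, np.conj(f_pos), atol=1e-12)
        f0 = rel_admittance(m, 0.0)
        assert f0.imag == 0.0 and 0.0 < f0.real <= 1.0

    def test_large_soma_dominance_recovers_nominal_soma(self, dendrite_axon):
        """rho_1 -> inf at fixed rho_alpha/rho_1: the somatic admittance
        becomes negligible and the nominal-soma factor is recovered."""
        m, d = dendrite_axon
        m_soma, _ = build_morphology(mu=5.0, sigma_s=3.0, a_ratio=0.25,
                                     rho_1=1e8, x_th=30.0)
        f_nom = rel_admittance(m, OMEGAS)
        f_big = rel_admittance(m_soma, OMEGAS)
        assert np.allclose(f_big, f_nom, rtol=1e-6)


class TestSealedEndPsd:
    def test_dc_value(self, drive):
        assert sealed_end_psd(0.0, drive, 10.0) == pytest.approx(
            2.0 * drive.sigma_s ** 2 * drive.tau_s)

    def test_integrals_reproduce_closed_forms(self, drive):
        grid = SpectrumGrid.build()
        S = sealed_end_psd(grid.omega, drive, 10.0)
        cf = one_dendrite_stats(drive, 10.0)
        assert grid.integrate(S) / math.pi == pytest.approx(cf.variance, rel=1e-10)
        assert grid.integrate(grid.omega ** 2 * S) / math.pi == pytest.approx(
            cf.dvariance, rel=1e-10)

    def test_high_frequency_decay_exponent(self, drive):
        # S ~ omega^(-7/2): guarantees a finite sigma_vdot
        s1 = sealed_end_psd(1.0e3, drive, 10.0)
        s2 = sealed_end_psd(2.0e3, drive, 10.0)
        assert s2 / s1 == pytest.approx(2.0 ** -3.5, rel=2e-3)


class TestTriggerPsd:
    def test_bare_dendrite_reduces_to_sealed_end(self, one_dendrite):
        m, d = one_dendrite
        assert np.allclose(trigger_psd(m, d, OMEGAS),
                           sealed_end_psd(OMEGAS, d, 10.0), rtol=1e-12)

    def test_two_identical_dendrites_halve_the_psd(self, two_dendrite):
        m, d = two_dendrite
        assert np.allclose(trigger_psd(m, d, OMEGAS),
                           sealed_end_psd(OMEGAS, d, 10.0) / 2.0, rtol=1e-12)

    def test_trigger_on_dendrite_interior_unsupported(self):
        m, d = build_morphology(mu=5.0, sigma_s=1.0)
        m = type(m)(n_dendrites=1, dendrite=m.dendrite,
                    threshold=type(m.threshold)(x_th=30.0,
                                                trigger_neurite="dendrite"))
        with pytest.raises(UnsupportedMorphologyError):
            trigger_psd(m, d, OMEGAS)


class TestMeanAtTrigger:
    def test_bare_dendrite_mean_is_mu(self, one_dendrite, two_dendrite):
        for m, d in (one_dendrite, two_dendrite):
            assert mean_at_trigger(m, d) == pytest.approx(d.mu)

    def test_attenuated_transfer_down_the_axon(self):
        m, d = build_morphology(mu=5.0, sigma_s=1.0, lambda_alpha=100.0,
                                x_th=30.0)
        f0 = 1.0 / (1.0 + 100.0 ** 3 / (EPS5 ** 2 * 200.0 ** 3))
        assert mean_at_trigger(m, d) == pytest.approx(
            5.0 * f0 * math.exp(-0.3), rel=1e-12)
        assert 5.0 * f0 * math.exp(-0.3) == pytest.approx(3.344, abs=1e-3)

    def test_many_dendrites_saturate_the_mean(self):
        m, d = build_morphology(mu=5.0, sigma_s=1.0, lambda_alpha=100.0,
                                x_th=30.0, n=4096)
        assert mean_at_trigger(m, d) == pytest.approx(
            5.0 * math.exp(-0.3), rel=1e-3)


class TestStatsFromPsd:
    def test_reproduces_one_dendrite_closed_form(self, one_dendrite):
        m, d = one_dendrite
        st_ = stats_from_psd(m, d)
        cf = one_dendrite_stats(d, 10.0)
        assert st_.variance == pytest.approx(cf.variance, rel=1e-8)
        assert st_.dvariance == pytest.approx(cf.dvariance, rel=1e-8)

    def test_reproduces_two_dendrite_closed_form(self, two_dendrite):
        m, d = two_dendrite
        st_ = stats_from_psd(m, d)
        cf = two_dendrite_stats(d, 10.0)
        assert st_.variance == pytest.approx(cf.variance, rel=1e-8)
        assert st_.dvariance == pytest.approx(cf.dvariance, rel=1e-8)

    def test_vanishing_axon_recovers_one_dendrite_stats(self):
        m, d = build_morphology(mu=5.0, sigma_s=1.0, a_ratio=1e-12, x_th=0.0)
        st_ = stats_from_psd(m, d)
        cf = one_dendrite_stats(d, 10.0)
        assert st_.variance == pytest.approx(cf.variance, rel=1e-6)
        assert st_.dvariance == pytest.approx(cf.dvariance, rel=1e-6)

    def test_variance_decreases_along_the_axon(self):
        prev = np.inf
        for x_th in (0.0, 10.0, 30.0, 60.0):
            m, d = build_morphology(mu=5.0, sigma_s=1.0, a_ratio=0.25,
                                    x_th=x_th)
            v = stats_from_psd(m, d).variance
            assert v < prev
            prev = v

    def test_variance_scales_as_inverse_n_for_many_dendrites(self):
        vals = {}
        for n in (32, 64):
            m, d = build_morphology(mu=5.0, sigma_s=1.0, a_ratio=0.25,
                                    x_th=30.0, n=n)
            vals[n] = n * stats_from_psd(m, d).variance
        assert vals[64] == pytest.approx(vals[32], rel=0.05)

    def test_coarse_grid_signals_non_convergence(self, dendrite_axon):
        m, d = dendrite_axon
        coarse = SpectrumGrid.build(omega_max=10.0, n_panels=3, n_nodes=4)
        with pytest.raises(ConvergenceError):
            stats_from_psd(m, d, grid=coarse)

    def test_spectrum_table_is_sorted_and_positive(self, dendrite_axon):
        m, d = dendrite_axon
        tab = spectrum_table(m, d)
        assert (np.diff(tab["omega"]) > 0).all()
        # the axonal attenuation underflows to exactly 0 at extreme omega
        assert (tab["S"] >= 0).all()
        assert tab["S"].iloc[0] > 0
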