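"""Forward-physics unit and property tests for exchange_core."""

import dataclasses

import numpy as np
import pytest

from betazip.exchange_core import (
    DEFAULT_NCYC,
    CestExperiment,
    CpmgExperiment,
    ExchangeModel,
    asymptotic_r2eff,
    carver_richards_r2eff,
    ppm_to_hz,
    ppm_to_rads,
    r2eff_from_intensities,
    simulate_cest_profile,
    simulate_cpmg_numeric,
)


class TestExchangeModel:
    def test_populations_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ExchangeModel((0.8, 0.3), kex_ab=100.0, dw_ab_ppm=1.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            ExchangeModel((0.9, 0.1), kex_ab=-5.0, dw_ab_ppm=1.0)

    def test_two_state_cannot_carry_ac_parameters(self):
        with pytest.raises(ValueError):
            ExchangeModel((0.9, 0.1), kex_ab=100.0, dw_ab_ppm=1.0,
                          kex_ac=500.0)

    def test_exchange_matrix_columns_sum_to_zero(self, three_state_model):
        K = three_state_model.exchange_matrix()
        assert np.allclose(K.sum(axis=0), 0.0, atol=1e-12)

    def test_detailed_balance(self, two_state_model):
        m = two_state_model
        assert m.k_ab * m.p_a == pytest.approx(m.k_ba * m.p_b)
        assert m.k_ab + m.k_ba == pytest.approx(m.kex_ab)


class TestUnits:
    def test_ppm_to_hz(self):
        assert ppm_to_hz(2.0, 60.83) == pytest.approx(121.66)

    def test_ppm_to_rads(self):
        assert ppm_to_rads(2.0, 60.83) == pytest.approx(
            2 * np.pi * 121.66)


class TestCestProfile:
    def test_ratio_bounded(self, two_state_model, cest_experiment):
        ratio = simulate_cest_profile(two_state_model, cest_experiment)
        # Mz can be driven slightly negative by on-resonance nutation, so
        # the physical bound is [-1, 1], not [0, 1]
        assert np.all(ratio >= -1.0 - 1e-9)
        assert np.all(ratio <= 1.0 + 1e-9)

    def test_main_dip_at_zero_offset(self, two_state_model, cest_experiment):
        ratio = simulate_cest_profile(two_state_model, cest_experiment)
        off = np.asarray(cest_experiment.offsets_hz)
        assert abs(off[np.argmin(ratio)]) <= 20.0

    def test_minor_dip_at_dw(self, two_state_model, cest_experiment):
        ratio = simulate_cest_profile(two_state_model, cest_experiment)
        off = np.asarray(cest_experiment.offsets_hz)
        # expected near +2 ppm = 121.66 Hz
        mask = off > 60.0
        dip = off[mask][np.argmin(ratio[mask])]
        assert dip == pytest.approx(ppm_to_hz(2.0, 60.83), abs=20.0)

    def test_no_exchange_is_symmetric_single_dip(self, cest_experiment):
        m = ExchangeModel((1.0, 0.0), kex_ab=0.0, dw_ab_ppm=0.0,
                          r1=1.2, r2=10.0)
        ratio = simulate_cest_profile(m, cest_experiment)
        assert np.allclose(ratio, ratio[::-1], atol=1e-8)

    def test_mirror_symmetry_under_dw_sign_flip(self, cest_experiment):
        # property: flipping the sign of dw mirrors the profile because the
        # default offset grid is symmetric about the major resonance
        for dw in (1.0, 2.5, 3.7):
            plus = simulate_cest_profile(
                ExchangeModel((0.9, 0.1), kex_ab=80.0, dw_ab_ppm=dw),
                cest_experiment)
            minus = simulate_cest_profile(
                ExchangeModel((0.9, 0.1), kex_ab=80.0, dw_ab_ppm=-dw),
                cest_experiment)
            assert np.allclose(plus, minus[::-1], atol=1e-8)

    def test_three_state_shows_both_dips(self, cest_experiment):
        m = ExchangeModel((0.84, 0.11, 0.05), kex_ab=104.0, dw_ab_ppm=3.0,
                          kex_ac=500.0, dw_ac_ppm=-3.0)
        ratio = simulate_cest_profile(m, cest_experiment)
        off = np.asarray(cest_experiment.offsets_hz)
        base = np.median(ratio[np.abs(off) > 60])
        hz = ppm_to_hz(3.0, 60.83)
        near_b = np.abs(off - hz) < 30
        near_c = np.abs(off + hz) < 30
        assert base - ratio[near_b].min() > 0.01
        assert base - ratio[near_c].min() > 0.01


class TestCpmg:
    def test_round_trip_intensities(self, two_state_model, cpmg_experiment):
        r2eff = simulate_cpmg_numeric(two_state_model, cpmg_experiment)
        T = cpmg_experiment.t_cpmg_s
        intensities = np.exp(-r2eff * T)
        back = r2eff_from_intensities(intensities, 1.0, T)
        assert np.allclose(back, r2eff, atol=1e-10)

    def test_dispersion_decreases_with_frequency(self, cpmg_experiment):
        m = ExchangeModel((0.95, 0.05), kex_ab=1740.0, dw_ab_ppm=2.0)
        r2eff = simulate_cpmg_numeric(m, cpmg_experiment)
        assert r2eff[0] > r2eff[-1] + 1.0
        # high-frequency limit approaches the baseline R2
        assert r2eff[-1] == pytest.approx(m.r2, abs=2.0)

    def test_no_exchange_is_flat(self, cpmg_experiment):
        m = ExchangeModel((0.95, 0.05), kex_ab=1740.0, dw_ab_ppm=0.0)
        r2eff = simulate_cpmg_numeric(m, cpmg_experiment)
        assert np.allclose(r2eff, m.r2, atol=1e-6)

    def test_three_state_adds_low_frequency_contribution(
            self, two_state_model, three_state_model, cpmg_experiment):
        r2 = simulate_cpmg_numeric(two_state_model, cpmg_experiment)
        r3 = simulate_cpmg_numeric(three_state_model, cpmg_experiment)
        assert r3[0] > r2[0] + 1.0


class TestCarverRichards:
    def test_rejects_three_state(self, three_state_model, cpmg_experiment):
        with pytest.raises(ValueError):
            carver_richards_r2eff(three_state_model,
                                  cpmg_experiment.nu_cpmg)

    def test_no_exchange_returns_baseline(self, cpmg_experiment):
        m = ExchangeModel((1.0, 0.0), kex_ab=0.0, dw_ab_ppm=0.0, r2=9.0)
        out = carver_richards_r2eff(m, cpmg_experiment.nu_cpmg)
        assert np.allclose(out, 9.0)

    def test_matches_asymptotic_rate_exactly(self, cpmg_experiment):
        # CR is the closed form of the dominant decay rate of the cycle
        # propagator; compare against that rate over a wide regime range
        rng = np.random.default_rng(2024)
        for _ in range(25):
            pb = rng.uniform(0.01, 0.2)
            kex = 10 ** rng.uniform(1.8, 3.8)
            dw = rng.uniform(0.5, 5.0)
            m = ExchangeModel((1 - pb, pb), kex_ab=kex, dw_ab_ppm=dw)
            nu = cpmg_experiment.nu_cpmg
            cr = carver_richards_r2eff(m, nu)
            asym = asymptotic_r2eff(m, nu)
            assert np.allclose(cr, asym, rtol=2e-3), (pb, kex, dw)


class TestExperimentValidation:
    def test_offsets_must_increase(self):
        with pytest.raises(ValueError):
            CestExperiment(b1_hz=10.0, t_relax_s=0.5,
                           offsets_hz=(0.0, -10.0, 10.0))

    def test_default_grid_spacing(self):
        exp = CestExperiment.default_grid()
        off = np.asarray(exp.offsets_hz)
        assert np.allclose(np.diff(off), 20.0)
        assert off.max() <= 6.0 * 60.83

    def test_ncyc_positive(self):
        with pytest.raises(ValueError):
            CpmgExperiment(ncyc_values=(0, 2))

    def test_default_ncyc_is_methods_schedule(self):
        assert CpmgExperiment().ncyc_values == DEFAULT_NCYC
        assert len(DEFAULT_NCYC) == 14

    def test_nu_cpmg(self):
        exp = CpmgExperiment(t_cpmg_s=0.04, ncyc_values=(1, 2, 4))
        assert np.allclose(exp.nu_cpmg, [25.0, 50.0, 100.0])
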