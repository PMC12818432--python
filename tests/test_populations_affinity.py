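"""Populations, free energies, K_D fits and regime classification tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betazip.populations_affinity import (
    PeakVolumePair,
    SaturationCurve,
    TitrationSeries,
    bound_fraction,
    classify_exchange_regime,
    combined_csp,
    delta_delta_g,
    fit_hyperbolic_saturation,
    fit_kd_fast_exchange,
    k_ratio,
    open_population_from_volumes,
)
from betazip.synthetic_data import GeneratorSpec, gen_titration


class TestPopulations:
    def test_volume_fraction(self):
        pair = PeakVolumePair("r1", v_open=15.0, v_closed=85.0)
        assert pair.p_open == pytest.approx(0.15)

    def test_mean_and_sd(self):
        pairs = [PeakVolumePair(f"r{i}", v, 100.0 - v)
                 for i, v in enumerate([10.0, 15.0, 20.0])]
        est = open_population_from_volumes(pairs)
        assert est.mean_pct == pytest.approx(15.0)
        assert est.sd_pct == pytest.approx(5.0)
        assert not est.flagged

    def test_single_reporter_flagged(self):
        est = open_population_from_volumes(
            [PeakVolumePair("r1", 15.0, 85.0)])
        assert est.flagged
        assert est.sd_pct is None

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            PeakVolumePair("r1", 0.0, 5.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=0.01, max_value=1e4))
    def test_scale_invariance(self, scale):
        # property: scaling all volumes leaves the population unchanged
        base = PeakVolumePair("r", 12.0, 88.0).p_open
        scaled = PeakVolumePair("r", 12.0 * scale, 88.0 * scale).p_open
        assert scaled == pytest.approx(base)


class TestDeltaDeltaG:
    def test_twofold_at_298(self):
        assert delta_delta_g(2.0) == pytest.approx(-0.41, abs=0.005)

    def test_pair_input(self):
        assert delta_delta_g((0.15, 0.30)) == pytest.approx(
            delta_delta_g(2.0))

    def test_unity_ratio_is_zero(self):
        assert delta_delta_g(1.0) == pytest.approx(0.0, abs=1e-12)

    def test_invalid(self):
        with pytest.raises(ValueError):
            delta_delta_g(-1.0)
        with pytest.raises(ValueError):
            delta_delta_g(2.0, temperature=0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(r=st.floats(min_value=0.01, max_value=100.0))
    def test_antisymmetry(self, r):
        # property: ddG(r) = -ddG(1/r)
        assert delta_delta_g(r) == pytest.approx(-delta_delta_g(1.0 / r),
                                                 abs=1e-9)


class TestIsotherm:
    def test_csp_combination(self):
        assert combined_csp(0.03, 0.2) == pytest.approx(
            np.sqrt(0.03**2 + (0.154 * 0.2) ** 2))

    def test_bound_fraction_limits(self):
        # saturating ligand drives the fraction to 1
        assert bound_fraction(100e-6, 1.0, 400e-6) == pytest.approx(1.0,
                                                                    abs=1e-3)
        assert bound_fraction(100e-6, 0.0, 400e-6) == pytest.approx(0.0)

    def test_depletion_matters(self):
        # at comparable protein and ligand concentrations the depletion
        # isotherm gives less binding than the free-ligand hyperbola
        p, l, kd = 100e-6, 200e-6, 400e-6
        naive = l / (kd + l)
        assert bound_fraction(p, l, kd) < naive

    def test_monotone_in_ligand(self):
        l = np.linspace(0.0, 4e-3, 40)
        fb = bound_fraction(np.full_like(l, 100e-6), l, 400e-6)
        assert np.all(np.diff(fb) > 0)


def _make_titration(seed, kd, noise_ppm=0.01, ligand_max=4e-3):
    spec = GeneratorSpec(seed=seed, shift_noise_ppm=noise_ppm)
    sched = np.concatenate([[0.0], np.geomspace(ligand_max / 50, ligand_max,
                                                9)])
    return gen_titration(spec, kd=kd, protein_total=100e-6,
                         ligand_schedule=sched, n_residues=6)


class TestKdFit:
    def test_zero_noise_exact(self):
        bundle = _make_titration(3, 400e-6, noise_ppm=0.0)
        fit = fit_kd_fast_exchange(bundle.datasets[0])
        assert fit.kd == pytest.approx(400e-6, rel=1e-3)
        assert not fit.flagged

    def test_noisy_recovery(self):
        bundle = _make_titration(4, 400e-6)
        fit = fit_kd_fast_exchange(bundle.datasets[0])
        assert fit.kd == pytest.approx(400e-6, abs=3 * fit.kd_stderr)

    def test_weak_binding_recovery(self):
        bundle = _make_titration(5, 2.3e-3, ligand_max=20e-3)
        fit = fit_kd_fast_exchange(bundle.datasets[0])
        assert fit.kd == pytest.approx(2.3e-3, abs=3 * fit.kd_stderr)

    def test_flat_titration_flagged(self):
        sched = np.concatenate([[0.0], np.geomspace(1e-5, 4e-3, 9)])
        series = TitrationSeries(
            protein_total=np.full(10, 100e-6), ligand_total=sched,
            shifts={"r1": (np.zeros(10), np.zeros(10))}, sigma=0.01)
        fit = fit_kd_fast_exchange(series)
        assert fit.flagged
        assert np.isnan(fit.kd)

    def test_non_saturating_is_lower_bound(self):
        # K_D far above the ligand range: only a lower bound is recoverable
        bundle = _make_titration(6, 50e-3, noise_ppm=0.01, ligand_max=1e-3)
        fit = fit_kd_fast_exchange(bundle.datasets[0])
        assert fit.flagged

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            TitrationSeries(protein_total=[1e-4] * 3,
                            ligand_total=[0, 1e-4, 2e-4],
                            shifts={}, sigma=0.01)


class TestRegime:
    def test_slow(self):
        assert classify_exchange_regime(100.0, 1000.0) == "slow"

    def test_fast(self):
        assert classify_exchange_regime(10000.0, 1000.0) == "fast"

    def test_intermediate(self):
        assert classify_exchange_regime(1000.0, 1000.0) == "intermediate"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_exchange_regime(-1.0, 100.0)


class TestHyperbolic:
    def _curve(self, k, ymax=10.0, noise=0.0, seed=0):
        x = np.array([0.0, 0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0]) * k * 4
        y = ymax * x / (k + x)
        if noise:
            y = y + np.random.default_rng(seed).normal(0, noise, y.size)
        return SaturationCurve(x, y, sigma=max(noise, 1e-3))

    def test_exact_recovery(self):
        fit = fit_hyperbolic_saturation(self._curve(0.3))
        assert fit.k_half == pytest.approx(0.3, rel=1e-4)
        assert fit.ymax == pytest.approx(10.0, rel=1e-4)
        assert not fit.flagged_k

    def test_k_ratio(self):
        a = fit_hyperbolic_saturation(self._curve(0.48))
        b = fit_hyperbolic_saturation(self._curve(0.3))
        assert k_ratio(a, b) == pytest.approx(1.6, rel=1e-3)

    def test_constant_curve_flags_k(self):
        x = np.array([0.0, 0.1, 0.5, 1.0, 2.0, 5.0])
        curve = SaturationCurve(x, np.full(x.size, 5.0), sigma=0.05)
        fit = fit_hyperbolic_saturation(curve)
        assert fit.flagged_k

    def test_requires_baseline_point(self):
        with pytest.raises(ValueError):
            SaturationCurve([1.0, 2.0, 3.0, 4.0, 5.0],
                            [1, 2, 3, 4, 5], sigma=0.1)
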