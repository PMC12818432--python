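"""Global-fit, model-selection and grouping tests for fitting."""

import numpy as np
import pytest

from betazip.exchange_core import (
    CestExperiment,
    CpmgExperiment,
    ExchangeModel,
    ppm_to_rads,
)
from betazip.fitting import (
    ZIP_PROBE_SHIFTS_15N,
    CpmgDispersion,
    FixedSlowProcess,
    ResidueDataset,
    compare_minor_shifts,
    detect_minor_dip,
    fit_cest_two_state,
    fit_cpmg_three_state_constrained,
    fit_cpmg_two_state,
    group_residues_by_rate,
    reconstruct_minor_shifts,
    select_exchange_model,
)
from betazip.synthetic_data import (
    GeneratorSpec,
    gen_cest_dataset,
    gen_cpmg_dataset,
)


def _noiseless_spec(seed):
    return GeneratorSpec(seed=seed, cest_noise_frac=0.0, cpmg_noise_frac=0.0)


class TestDipDetection:
    def test_finds_minor_dip(self, two_state_model, cest_experiment):
        from betazip.exchange_core import simulate_cest_profile

        ratio = simulate_cest_profile(two_state_model, cest_experiment)
        dw = detect_minor_dip(cest_experiment.offsets_hz, ratio,
                              cest_experiment.freq_15n_mhz)
        assert dw == pytest.approx(2.0, abs=0.35)

    def test_none_without_exchange(self, cest_experiment):
        from betazip.exchange_core import simulate_cest_profile

        m = ExchangeModel((1.0, 0.0), kex_ab=0.0, dw_ab_ppm=0.0)
        ratio = simulate_cest_profile(m, cest_experiment)
        sigma = np.full(ratio.size, 0.005)
        assert detect_minor_dip(cest_experiment.offsets_hz, ratio,
                                cest_experiment.freq_15n_mhz,
                                sigma=sigma) is None


class TestCestFit:
    def test_zero_noise_round_trip(self, cest_experiment):
        model = ExchangeModel((0.89, 0.11), kex_ab=104.0, dw_ab_ppm=2.0)
        bundle = gen_cest_dataset(_noiseless_spec(5), model,
                                  cest_experiment, 3)
        fit = fit_cest_two_state(bundle.datasets, cest_experiment)
        assert fit.shared["kex"].value == pytest.approx(104.0, rel=1e-3)
        assert fit.shared["pb"].value == pytest.approx(0.11, rel=1e-3)
        for rid, truth_dw in bundle.truth["dw_ppm"].items():
            assert fit.per_residue[rid]["dw"].value == pytest.approx(
                truth_dw, rel=1e-2)

    def test_recovers_signed_dw(self, cest_experiment):
        model = ExchangeModel((0.89, 0.11), kex_ab=104.0, dw_ab_ppm=2.0)
        bundle = gen_cest_dataset(_noiseless_spec(8), model, cest_experiment,
                                  2, dw_ppm=[2.5, -2.5])
        fit = fit_cest_two_state(bundle.datasets, cest_experiment)
        dws = [fit.per_residue[r]["dw"].value for r in ("res01", "res02")]
        assert dws[0] == pytest.approx(2.5, abs=0.05)
        assert dws[1] == pytest.approx(-2.5, abs=0.05)

    def test_no_cest_data_raises(self, cpmg_experiment, cest_experiment):
        model = ExchangeModel((0.95, 0.05), kex_ab=1740.0, dw_ab_ppm=2.0)
        bundle = gen_cpmg_dataset(_noiseless_spec(2), model,
                                  cpmg_experiment, 2)
        with pytest.raises(ValueError):
            fit_cest_two_state(bundle.datasets, cest_experiment)


class TestCpmgFit:
    def test_zero_noise_round_trip(self, cpmg_experiment):
        model = ExchangeModel((0.95, 0.05), kex_ab=1740.0, dw_ab_ppm=2.0)
        bundle = gen_cpmg_dataset(_noiseless_spec(4), model, cpmg_experiment,
                                  3, dw_ab_range=(1.5, 3.0))
        fit = fit_cpmg_two_state(bundle.datasets, cpmg_experiment)
        assert fit.exchange_detected
        assert fit.shared["kex"].value == pytest.approx(1740.0, rel=0.02)

    def test_flat_dispersions_reported_not_raised(self, cpmg_experiment):
        model = ExchangeModel((0.95, 0.05), kex_ab=1740.0, dw_ab_ppm=2.0)
        bundle = gen_cpmg_dataset(_noiseless_spec(4), model, cpmg_experiment,
                                  2, dw_ab_ppm=[0.0, 0.0])
        fit = fit_cpmg_two_state(bundle.datasets, cpmg_experiment)
        assert not fit.exchange_detected
        assert fit.shared["kex"].flagged
        assert np.isnan(fit.shared["kex"].value)

    def test_reference_row_required(self):
        with pytest.raises(ValueError):
            CpmgDispersion(ncyc=[1, 2, 4], intensity=[0.9, 0.92, 0.95],
                           sigma=0.005)

    def test_phi_attached_per_residue(self, cpmg_experiment):
        model = ExchangeModel((0.95, 0.05), kex_ab=1740.0, dw_ab_ppm=2.0)
        bundle = gen_cpmg_dataset(_noiseless_spec(9), model, cpmg_experiment,
                                  2, dw_ab_range=(1.5, 3.0))
        fit = fit_cpmg_two_state(bundle.datasets, cpmg_experiment)
        for rid, truth_dw in bundle.truth["dw_ab_ppm"].items():
            dw_rad = ppm_to_rads(abs(truth_dw), cpmg_experiment.freq_15n_mhz)
            phi_truth = 0.95 * 0.05 * dw_rad**2
            assert fit.per_residue[rid]["phi"].value == pytest.approx(
                phi_truth, rel=0.1)


@pytest.fixture(scope="module")
def three_state_bundle():
    exp = CpmgExperiment()
    model = ExchangeModel((0.84, 0.11, 0.05), kex_ab=104.0,
                          dw_ab_ppm=2.0, kex_ac=2600.0, dw_ac_ppm=2.0)
    return gen_cpmg_dataset(_noiseless_spec(6), model, exp, 3), exp


class TestThreeStateFit:

    def test_zero_noise_recovers_kex_ac(self, three_state_bundle):
        bundle, exp = three_state_bundle
        fixed = FixedSlowProcess(kex_ab=104.0,
                                 dw_ab_ppm=bundle.truth["dw_ab_ppm"],
                                 p_b=0.11)
        fit = fit_cpmg_three_state_constrained(bundle.datasets, fixed, exp)
        assert fit.shared["kex_ac"].value == pytest.approx(2600.0, rel=0.05)
        assert fit.shared["pc"].flagged
        assert fit.shared["pb"].flagged

    def test_missing_dw_ab_raises(self, three_state_bundle):
        bundle, exp = three_state_bundle
        fixed = FixedSlowProcess(kex_ab=104.0, dw_ab_ppm={"res01": 2.0},
                                 p_b=0.11)
        with pytest.raises(ValueError, match="res0"):
            fit_cpmg_three_state_constrained(bundle.datasets, fixed, exp)

    def test_invalid_fixed_process(self):
        with pytest.raises(ValueError):
            FixedSlowProcess(kex_ab=-10.0, dw_ab_ppm={})
        with pytest.raises(ValueError):
            FixedSlowProcess(kex_ab=100.0, dw_ab_ppm={}, p_b=0.9)

    def test_model_selection_prefers_three_state(self, three_state_bundle):
        bundle, exp = three_state_bundle
        two = fit_cpmg_two_state(bundle.datasets, exp, rex_threshold=0.0)
        fixed = FixedSlowProcess(kex_ab=104.0,
                                 dw_ab_ppm=bundle.truth["dw_ab_ppm"],
                                 p_b=0.11)
        three = fit_cpmg_three_state_constrained(bundle.datasets, fixed, exp)
        sel = select_exchange_model(two, three)
        assert sel.chosen == "three_state"
        # the unmodeled slow process biases the low-frequency residuals of
        # the two-state fit systematically
        assert abs(sel.low_freq_bias["two_state"]) > \
            abs(sel.low_freq_bias["three_state"])

    def test_selection_requires_identical_data(self, three_state_bundle,
                                               cpmg_experiment):
        bundle, exp = three_state_bundle
        two = fit_cpmg_two_state(bundle.datasets, exp, rex_threshold=0.0)
        model = ExchangeModel((0.95, 0.05), kex_ab=1740.0, dw_ab_ppm=2.0)
        other = gen_cpmg_dataset(_noiseless_spec(3), model, cpmg_experiment,
                                 2, dw_ab_range=(1.5, 3.0))
        other_fit = fit_cpmg_two_state(other.datasets, cpmg_experiment)
        with pytest.raises(ValueError):
            select_exchange_model(two, other_fit)


class TestRateGrouping:
    def test_two_clear_groups(self):
        rates = {"a": 100.0, "b": 110.0, "c": 95.0, "d": 1700.0, "e": 1800.0}
        groups = group_residues_by_rate(rates)
        assert len(groups) == 2
        sizes = sorted(len(g.members) for g in groups)
        assert sizes == [2, 3]

    def test_singleton_marks_outlier(self):
        rates = {"a": 100.0, "b": 105.0, "c": 5000.0}
        groups = group_residues_by_rate(rates)
        assert any(g.is_singleton and g.members == ("c",) for g in groups)

    def test_single_group_within_threshold(self):
        rates = {"a": 100.0, "b": 150.0, "c": 120.0}
        assert len(group_residues_by_rate(rates)) == 1


class TestMinorShifts:
    def test_reconstruction_additive(self):
        assert reconstruct_minor_shifts(118.0, -1.5) == pytest.approx(116.5)
        out = reconstruct_minor_shifts([118.0, 120.0], [1.0, -1.0])
        assert np.allclose(out, [119.0, 119.0])

    def test_probe_table_differences(self):
        diffs = compare_minor_shifts(ZIP_PROBE_SHIFTS_15N)
        assert diffs["F41"] == pytest.approx(0.1)
        assert diffs["I56"] == pytest.approx(0.3)
        assert diffs["D40"] == pytest.approx(0.2)
        assert diffs["Q57"] == pytest.approx(0.1)

    def test_sequence_input(self):
        out = compare_minor_shifts([(1.0, 1.2), (3.0, 2.5)])
        assert np.allclose(out, [0.2, 0.5])
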