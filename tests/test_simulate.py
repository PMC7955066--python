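"""Charging, resolution law, peak rendering and baseline correction."""

import dataclasses

import numpy as np
import pytest

from aavsim import (
    AssemblyModel,
    ChargingModel,
    InstrumentModel,
    IonList,
    VPRatio,
    baseline_correct,
    build_ensemble,
    calibrate_charge_offset,
    charge_envelope,
    detect_centroids,
    ensemble_ions,
    fwhm_at,
    mean_charge,
    render_spectrum,
    simulate_ensemble_spectrum,
)
from aavsim.simulate import FWHM_SIGMA, PROTON_MASS
from aavsim.spectrum import Spectrum


class TestMeanCharge:
    def test_vp3_only_capsid(self):
        z = mean_charge(3_571_000.0, ChargingModel())
        assert z == pytest.approx(1.638 * 3571.0**0.5497, rel=1e-12)
        assert z == pytest.approx(147.0, abs=0.5)

    def test_offset_is_additive(self):
        base = mean_charge(1e6, ChargingModel())
        assert mean_charge(1e6, ChargingModel(offset_b=10.0)) == pytest.approx(base + 10.0)

    def test_power_law_scaling(self):
        z1 = mean_charge(1e6, ChargingModel())
        z2 = mean_charge(2e6, ChargingModel())
        assert z2 / z1 == pytest.approx(2**0.5497, rel=1e-12)

    def test_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError):
            mean_charge(0.0, ChargingModel())


class TestChargeEnvelope:
    def test_aav_ion_species_count(self, aav_model, aav9_ratio, wide_instrument):
        ens = build_ensemble(aav9_ratio, aav_model)
        ions = ensemble_ions(ens, wide_instrument)
        assert len(ions) == 1891 * 37 == 69_967

    def test_intensities_sum_to_probability(self, wide_instrument):
        ions = charge_envelope(3.571e6, 0.37, wide_instrument)
        assert ions.intensity.sum() == pytest.approx(0.37, abs=1e-9)

    def test_symmetry_about_center(self, wide_instrument):
        mass = 3.571e6
        z0 = round(mean_charge(mass, wide_instrument.charging))
        ions = charge_envelope(mass, 1.0, wide_instrument)
        w = {int(z): i for z, i in zip(ions.charge, ions.intensity)}
        # symmetric only when the mean charge is exactly the rounded center
        sym_instrument = wide_instrument.with_offset(z0 - mean_charge(mass, ChargingModel()))
        ions = charge_envelope(mass, 1.0, sym_instrument)
        w = ions.intensity
        assert w == pytest.approx(w[::-1], rel=1e-9)

    def test_mz_convention_includes_proton(self, wide_instrument):
        ions = charge_envelope(3.571e6, 1.0, wide_instrument)
        expected = (ions.mass + ions.charge * PROTON_MASS) / ions.charge
        assert ions.mz == pytest.approx(expected, rel=1e-12)

    def test_truncation_below_charge_one(self):
        inst = InstrumentModel(grid_min=1.0, grid_max=10000.0, grid_step=1.0,
                               n_charge_states=37)
        ions = charge_envelope(1000.0, 1.0, inst)  # mean charge ~2.4
        assert ions.charge.min() >= 1
        assert len(ions) < 37
        assert ions.intensity.sum() == pytest.approx(1.0, abs=1e-9)

    def test_sigma_zero_collapses_to_single_state(self, wide_instrument):
        inst = dataclasses.replace(wide_instrument, charge_sigma=0.0)
        ions = charge_envelope(3.571e6, 1.0, inst)
        assert (ions.intensity > 0).sum() == 1


class TestResolutionLaw:
    def test_reference_point(self):
        inst = InstrumentModel()
        assert fwhm_at(400.0, inst) == pytest.approx(400.0 / 6250.0, rel=1e-12)

    def test_value_at_21000(self):
        inst = InstrumentModel()
        r = 6250.0 * np.sqrt(400.0 / 21000.0)
        assert r == pytest.approx(863, abs=1.0)
        assert fwhm_at(21000.0, inst) == pytest.approx(21000.0 / r, rel=1e-12)
        assert fwhm_at(21000.0, inst) == pytest.approx(24.3, abs=0.1)

    def test_mz_three_halves_power(self):
        inst = InstrumentModel()
        assert fwhm_at(4 * 21000.0, InstrumentModel(grid_max=100000.0)) == pytest.approx(
            8 * fwhm_at(21000.0, inst), rel=1e-12
        )

    def test_transient_scaling(self):
        i32 = InstrumentModel(transient_ms=32.0)
        i128 = InstrumentModel(transient_ms=128.0)
        assert fwhm_at(21000.0, i128) == pytest.approx(fwhm_at(21000.0, i32) / 4.0, rel=1e-12)


def _single_ion(mz: float, intensity: float = 1.0) -> IonList:
    return IonList(
        mass=np.array([mz * 150.0]),
        charge=np.array([150]),
        mz=np.array([mz]),
        intensity=np.array([intensity]),
    )


class TestRenderSpectrum:
    def test_apex_at_ion_position(self, narrow_instrument):
        spec = render_spectrum(_single_ion(21500.0), narrow_instrument)
        apex = spec.mz[np.argmax(spec.intensity)]
        assert abs(apex - 21500.0) <= narrow_instrument.grid_step

    def test_windowed_matches_dense_oracle(self, narrow_instrument):
        rng = np.random.default_rng(42)
        mzs = rng.uniform(20500, 22500, size=25)
        amps = rng.uniform(0.1, 1.0, size=25)
        ions = IonList(mzs * 150, np.full(25, 150), mzs, amps)
        windowed = render_spectrum(ions, narrow_instrument)

        # dense oracle: every ion evaluated at every bin, no window
        grid = narrow_instrument.mz_grid()
        dense = np.zeros(grid.size)
        for mz, amp in zip(mzs, amps):
            fwhm = fwhm_at(mz, narrow_instrument)
            sigma = fwhm / FWHM_SIGMA
            dense += (
                amp * narrow_instrument.grid_step / (sigma * np.sqrt(2 * np.pi))
            ) * np.exp(-0.5 * ((grid - mz) / sigma) ** 2)

        err = np.abs(windowed.intensity - dense).sum()
        assert err <= 0.002 * dense.sum()

    def test_total_intensity_conserved(self, narrow_instrument):
        ions = _single_ion(21500.0, 0.73)
        spec = render_spectrum(ions, narrow_instrument)
        assert spec.intensity.sum() == pytest.approx(0.73, rel=5e-3)

    def test_rendered_fwhm_matches_resolution_law(self, narrow_instrument):
        mz0 = 21500.0
        spec = render_spectrum(_single_ion(mz0), narrow_instrument)
        half = spec.intensity.max() / 2
        above = spec.mz[spec.intensity >= half]
        measured = above[-1] - above[0]
        assert abs(measured - fwhm_at(mz0, narrow_instrument)) <= narrow_instrument.grid_step

    def test_two_distant_ions_baseline_separated(self, narrow_instrument):
        fwhm = fwhm_at(21000.0, narrow_instrument)
        ions = IonList.concat([_single_ion(21000.0), _single_ion(21000.0 + 10 * fwhm)])
        spec = render_spectrum(ions, narrow_instrument)
        mid = np.searchsorted(spec.mz, 21000.0 + 5 * fwhm)
        assert spec.intensity[mid] < 1e-6 * spec.intensity.max()

    def test_out_of_grid_ions_dropped_with_count(self, narrow_instrument):
        ions = IonList.concat([_single_ion(21000.0), _single_ion(50000.0)])
        spec = render_spectrum(ions, narrow_instrument)
        assert spec.metadata["n_dropped_ions"] == 1

    def test_empty_ion_list(self, narrow_instrument):
        spec = render_spectrum(IonList.concat([]), narrow_instrument)
        assert not spec.intensity.any()


class TestBaselineCorrect:
    def test_all_zero(self, narrow_instrument):
        grid = narrow_instrument.mz_grid()
        spec = Spectrum(grid, np.zeros(grid.size))
        assert not baseline_correct(spec, narrow_instrument).intensity.any()

    def test_constant_offset_removed(self, narrow_instrument):
        grid = narrow_instrument.mz_grid()
        spec = Spectrum(grid, np.full(grid.size, 0.3))
        out = baseline_correct(spec, narrow_instrument)
        assert out.intensity == pytest.approx(np.zeros(grid.size), abs=1e-12)

    def test_output_below_input(self, narrow_instrument):
        rng = np.random.default_rng(0)
        grid = narrow_instrument.mz_grid()
        spec = Spectrum(grid, rng.uniform(0, 1, grid.size))
        out = baseline_correct(spec, narrow_instrument)
        assert np.all(out.intensity <= spec.intensity + 1e-12)
        assert np.all(out.intensity >= 0)

    def test_peak_apex_preserved_on_slope(self, narrow_instrument):
        grid = narrow_instrument.mz_grid()
        mz0 = 21500.0
        peak = render_spectrum(_single_ion(mz0), narrow_instrument).intensity
        hump = 0.5 * peak.max() * np.exp(-0.5 * ((grid - 21000.0) / 800.0) ** 2)
        spec = Spectrum(grid, peak + hump)
        out = baseline_correct(spec, narrow_instrument)
        apex_before = grid[np.argmax(peak)]
        apex_after = grid[np.argmax(out.intensity)]
        assert abs(apex_after - apex_before) < 2 * narrow_instrument.grid_step


class TestSimulateEnsemble:
    def test_vp3_only_series_spacing(self, aav_model, wide_instrument):
        ens = build_ensemble(VPRatio(0, 0, 1), aav_model)
        spec = simulate_ensemble_spectrum(ens, wide_instrument)
        cen = detect_centroids(spec)
        spacings = np.diff(cen.mz)
        mass = 3_571_000.0
        # spacing between charge z and z+1 is ~ M / (z (z+1))
        z_center = round(mean_charge(mass, wide_instrument.charging))
        expected = mass / (z_center * (z_center + 1))
        assert np.median(spacings) == pytest.approx(expected, rel=0.05)

    def test_entry_order_invariance(self, aav_model, aav9_ratio, wide_instrument):
        from aavsim.stoichiometry import CapsidEnsemble

        ens = build_ensemble(aav9_ratio, aav_model).truncate(1e-4)
        perm = np.random.default_rng(3).permutation(len(ens))
        shuffled = CapsidEnsemble(
            ens.counts[perm], ens.masses[perm], ens.probabilities[perm], ens.model, ens.ratio
        )
        a = simulate_ensemble_spectrum(ens, wide_instrument)
        b = simulate_ensemble_spectrum(shuffled, wide_instrument)
        assert np.array_equal(a.intensity, b.intensity)

    def test_max_normalized(self, aav_model, aav9_ratio, wide_instrument):
        ens = build_ensemble(aav9_ratio, aav_model).truncate(1e-4)
        spec = simulate_ensemble_spectrum(ens, wide_instrument)
        assert spec.intensity.max() == pytest.approx(1.0)

    def test_longer_transient_resolves_doublet(self):
        inst32 = InstrumentModel(grid_min=20000, grid_max=23000, grid_step=0.25,
                                 transient_ms=32.0)
        inst128 = dataclasses.replace(inst32, transient_ms=128.0)
        mz0 = 21500.0
        # spacing between the 128 ms FWHM (~6 Th) and the 32 ms FWHM (~25 Th)
        delta = 12.0
        ions = IonList.concat([_single_ion(mz0), _single_ion(mz0 + delta)])
        n32 = len(detect_centroids(render_spectrum(ions, inst32)))
        n128 = len(detect_centroids(render_spectrum(ions, inst128)))
        assert n32 == 1
        assert n128 == 2

    def test_substitution_and_charge_state_coincidence(self, aav_model, wide_instrument):
        """Three VP3->VP2 swaps nearly coincide with the next charge state."""
        mass = 3_571_000.0
        # calibrated so the envelope sits near the experimentally observed
        # 21,000 Th region (z ~ 170)
        b = calibrate_charge_offset(mass, 21000.0, ChargingModel())
        z = round(mean_charge(mass, ChargingModel(offset_b=b)))
        substitution_shift = 3 * 6500.0 / z
        charge_state_spacing = mass / (z * (z + 1))
        fwhm = fwhm_at(mass / z, InstrumentModel(transient_ms=32.0))
        assert abs(substitution_shift - charge_state_spacing) < fwhm


class TestCalibrateOffset:
    def test_direct_evaluation(self):
        b = calibrate_charge_offset(3_571_000.0, 21000.0, ChargingModel())
        assert b == pytest.approx(3_571_000.0 / 21000.0 - 1.638 * 3571.0**0.5497, rel=1e-12)
        assert b == pytest.approx(23.0, abs=1.0)

    def test_self_consistency_single_mass(self, aav_model, wide_instrument):
        ens = build_ensemble(VPRatio(0, 0, 1), aav_model)
        spec = simulate_ensemble_spectrum(ens, wide_instrument, apply_baseline=False)
        b = calibrate_charge_offset(ens.mean_mass, spec.mean_mz(), wide_instrument.charging)
        assert abs(b) < 0.5

    def test_monotone_in_mean_mz(self):
        b1 = calibrate_charge_offset(3.571e6, 20000.0, ChargingModel())
        b2 = calibrate_charge_offset(3.571e6, 22000.0, ChargingModel())
        assert b1 > b2

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            calibrate_charge_offset(3.571e6, 0.0, ChargingModel())
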