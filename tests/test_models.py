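import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placenta_dwi import io, models
from placenta_dwi.models import (
    VMREConfig,
    biexp_signal,
    compute_vmre,
    fit_adc,
    fit_ivim_full,
    fit_ivim_segmented,
    fit_stretched,
    fit_volume,
    mono_signal,
    stretched_signal,
)


class TestForwardModels:
    def test_biexp_collapses_to_mono_when_perfusion_free(self, bvalues):
        np.testing.assert_allclose(
            biexp_signal(0.0, 1.5e-3, 0.1, 50.0, bvalues),
            mono_signal(1.5e-3, 50.0, bvalues))

    def test_signal_at_b0_is_s0(self, bvalues):
        assert biexp_signal(0.3, 2e-3, 0.05, 123.0, [0])[0] == 123.0
        assert stretched_signal(2e-3, 0.7, 123.0, [0])[0] == 123.0

    def test_biexp_adverse_group_means_frozen_values(self, adverse_params):
        # independent arithmetic: 0.7644*e^{-0.31} = 0.56065,
        # 0.7644*e^{-1.24} = 0.22120 (fast pool fully attenuated)
        p = adverse_params
        s = biexp_signal(p["f"], p["D"], p["Dstar"], 1.0, [200, 800])
        np.testing.assert_allclose(s, [0.56065, 0.22121], atol=1e-5)
        # exact: ln(S_200/S_800) = (1.24 - 0.31) = 0.93 once the fast pool
        # has fully decayed (its b=200 remnant is ~1e-14)
        assert np.log(s[0] / s[1]) == pytest.approx(0.93, abs=1e-9)

    def test_mono_non_adverse_adc_attenuation(self):
        # e^{-800 * 2.75e-3} = e^{-2.2}
        s = mono_signal(2.75e-3, 1.0, [800])
        assert s[0] == pytest.approx(np.exp(-2.2), rel=1e-12)

    def test_stretched_with_unit_alpha_is_mono(self, bvalues):
        np.testing.assert_allclose(
            stretched_signal(2.4e-3, 1.0, 7.0, bvalues),
            mono_signal(2.4e-3, 7.0, bvalues), rtol=1e-12)

    def test_stretched_strictly_decreasing_over_protocol(self, bvalues):
        s = stretched_signal(2.4e-3, 0.7, 1.0, bvalues)
        assert np.all(np.diff(s) < 0)

    def test_out_of_bound_parameters_rejected(self, bvalues):
        with pytest.raises(ValueError):
            biexp_signal(1.2, 1e-3, 0.05, 1.0, bvalues)
        with pytest.raises(ValueError):
            stretched_signal(2e-3, 1.5, 1.0, bvalues)


class TestNoiseFreeRecovery:
    """Forward/inverse consistency at the 7 protocol b-values."""

    def test_adc_recovery(self, bvalues, non_adverse_params):
        fit = fit_adc(mono_signal(non_adverse_params["ADC"], 1.0, bvalues), bvalues)
        assert fit.ADC == pytest.approx(non_adverse_params["ADC"], rel=1e-6)
        assert fit.converged

    @pytest.mark.parametrize("fitter", [fit_ivim_segmented, fit_ivim_full])
    def test_ivim_recovery_adverse_means(self, bvalues, adverse_params, fitter):
        p = adverse_params
        sig = biexp_signal(p["f"], p["D"], p["Dstar"], 1.0, bvalues)
        fit = fitter(sig, bvalues)
        assert fit.f == pytest.approx(p["f"], rel=1e-3)
        assert fit.D == pytest.approx(p["D"], rel=1e-3)
        assert fit.Dstar == pytest.approx(p["Dstar"], rel=1e-2)
        assert fit.converged

    def test_ivim_full_recovers_non_adverse_D(self, bvalues, non_adverse_params):
        p = non_adverse_params
        sig = biexp_signal(p["f"], p["D"], p["Dstar"], 1.0, bvalues)
        assert fit_ivim_full(sig, bvalues).D == pytest.approx(p["D"], rel=1e-3)

    def test_stretched_recovery_non_adverse_means(self, bvalues, non_adverse_params):
        p = non_adverse_params
        sig = stretched_signal(p["DDC"], p["Alpha"], 1.0, bvalues)
        fit = fit_stretched(sig, bvalues)
        assert fit.DDC == pytest.approx(p["DDC"], rel=1e-3)
        assert fit.Alpha == pytest.approx(p["Alpha"], rel=1e-3)

    def test_full_fit_is_fixed_point_at_truth(self, bvalues, adverse_params):
        p = adverse_params
        sig = biexp_signal(p["f"], p["D"], p["Dstar"], 1.0, bvalues)
        init = models.IVIMFit(f=p["f"], D=p["D"], Dstar=p["Dstar"], S0=1.0)
        fit = fit_ivim_full(sig, bvalues, init=init)
        assert fit.f == pytest.approx(p["f"], abs=1e-9)
        assert fit.Dstar == pytest.approx(p["Dstar"], rel=1e-6)


class TestFitBehaviour:
    def test_adc_of_biexp_lies_between_D_and_fast_rate(self, bvalues, adverse_params):
        p = adverse_params
        sig = biexp_signal(p["f"], p["D"], p["Dstar"], 1.0, bvalues)
        adc = fit_adc(sig, bvalues).ADC
        assert p["D"] < adc < p["D"] + p["Dstar"]

    def test_constant_signal_gives_zero_adc(self, bvalues):
        fit = fit_adc(np.full(bvalues.size, 5.0), bvalues)
        assert fit.ADC == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_signal_flags_voxel_unfit(self, bvalues):
        sig = mono_signal(1e-3, 1.0, bvalues)
        sig[3] = 0.0
        fit = fit_adc(sig, bvalues)
        assert not fit.converged and np.isnan(fit.ADC)

    def test_perfusion_free_signal(self, bvalues):
        sig = mono_signal(1.5e-3, 1.0, bvalues)
        fit = fit_ivim_segmented(sig, bvalues)
        assert fit.f == pytest.approx(0.0, abs=1e-6)
        assert fit.D == pytest.approx(1.5e-3, rel=1e-4)

    def test_insufficient_bvalues_rejected(self):
        with pytest.raises(ValueError):
            fit_adc([1.0], [0.0])
        with pytest.raises(ValueError):
            fit_ivim_segmented([1, 0.9, 0.5], [0, 200, 800])
        with pytest.raises(ValueError):
            fit_stretched([1.0, 0.5], [0, 800])

    def test_stretched_fit_of_biexp_is_sub_monoexponential(self, bvalues, adverse_params):
        p = adverse_params
        sig = biexp_signal(p["f"], p["D"], p["Dstar"], 1.0, bvalues)
        assert fit_stretched(sig, bvalues).Alpha < 1.0

    def test_stretched_fit_of_mono_hits_alpha_boundary(self, bvalues):
        fit = fit_stretched(mono_signal(2e-3, 1.0, bvalues), bvalues)
        assert fit.Alpha == pytest.approx(1.0, abs=1e-4)
        assert fit.DDC == pytest.approx(2e-3, rel=1e-3)

    def test_monte_carlo_f_bias_small_at_low_noise(self, bvalues, adverse_params):
        # 1,000 replicate voxels, Gaussian sigma = 0.5% of S0: the median
        # fitted f stays within 2 percentage points of truth
        p = adverse_params
        rng = np.random.default_rng(2024)
        clean = biexp_signal(p["f"], p["D"], p["Dstar"], 1.0, bvalues)
        fs = []
        for _ in range(1000):
            noisy = np.clip(clean + rng.normal(0, 0.005, clean.size), 1e-6, None)
            fs.append(fit_ivim_full(noisy, bvalues).f)
        assert abs(np.median(fs) - p["f"]) < 0.02


class TestInvariances:
    @given(scale=st.floats(min_value=0.1, max_value=1e4))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance_of_all_fitters(self, scale):
        b = np.array(models.PROTOCOL_BVALUES)
        sig = biexp_signal(0.25, 1.6e-3, 0.12, 1.0, b)
        base_ivim = fit_ivim_full(sig, b)
        scaled_ivim = fit_ivim_full(sig * scale, b)
        assert scaled_ivim.f == pytest.approx(base_ivim.f, rel=1e-5, abs=1e-7)
        assert scaled_ivim.D == pytest.approx(base_ivim.D, rel=1e-5)
        assert scaled_ivim.S0 == pytest.approx(base_ivim.S0 * scale, rel=1e-5)
        assert fit_adc(sig * scale, b).ADC == pytest.approx(
            fit_adc(sig, b).ADC, rel=1e-9)
        st_base, st_scaled = fit_stretched(sig, b), fit_stretched(sig * scale, b)
        assert st_scaled.Alpha == pytest.approx(st_base.Alpha, rel=1e-4)
        assert compute_vmre(sig * scale, b) == pytest.approx(
            compute_vmre(sig, b), rel=1e-12)

    @given(perm=st.permutations(range(7)))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_permutation_invariance(self, perm):
        b = np.array(models.PROTOCOL_BVALUES)
        sig = biexp_signal(0.25, 1.6e-3, 0.12, 1.0, b)
        perm = np.array(perm)
        base = fit_ivim_segmented(sig, b)
        shuf = fit_ivim_segmented(sig[perm], b[perm])
        assert shuf.f == pytest.approx(base.f, rel=1e-9)
        assert shuf.D == pytest.approx(base.D, rel=1e-9)
        assert fit_adc(sig[perm], b[perm]).ADC == pytest.approx(
            fit_adc(sig, b).ADC, rel=1e-9)
        assert compute_vmre(sig[perm], b[perm]) == pytest.approx(
            compute_vmre(sig, b), rel=1e-12)


class TestVMRE:
    def test_equal_signals_give_shift_factor(self, bvalues):
        assert compute_vmre(np.ones(7), bvalues) == 14.0

    def test_mono_voxel_worked_example(self, bvalues):
        # ADC = 1e-3: ln ratio over (200, 800) = 0.6; 14 - 9.8*0.6 = 8.12
        mu = compute_vmre(mono_signal(1e-3, 1.0, bvalues), bvalues)
        assert mu == pytest.approx(8.12, abs=1e-9)

    def test_biexp_adverse_group_stiffness(self, bvalues, adverse_params):
        p = adverse_params
        sig = biexp_signal(p["f"], p["D"], p["Dstar"], 1.0, bvalues)
        assert compute_vmre(sig, bvalues) == pytest.approx(4.885, abs=5e-3)

    def test_stiffness_decreases_with_attenuation_ratio(self, bvalues):
        mus = [compute_vmre(mono_signal(adc, 1.0, bvalues), bvalues)
               for adc in (0.5e-3, 1e-3, 2e-3, 3e-3)]
        assert np.all(np.diff(mus) < 0)

    def test_missing_key_bvalue_rejected(self):
        with pytest.raises(ValueError, match="must both be acquired"):
            compute_vmre([1.0, 0.5], [0, 500], VMREConfig())

    def test_zero_high_b_signal_gives_nan(self, bvalues):
        sig = mono_signal(1e-3, 1.0, bvalues)
        sig[-1] = 0.0
        assert np.isnan(compute_vmre(sig, bvalues))


class TestFitVolume:
    def test_constant_phantom_matches_scalar_fit(self, small_series):
        mask = io.ROIMask(np.ones((3, 3, 2), dtype=bool))
        maps = fit_volume(small_series, mask, "adc")
        scalar = fit_adc(small_series.signal[0, 0, 0], small_series.bvalues)
        np.testing.assert_allclose(maps["ADC"].values, scalar.ADC, rtol=1e-12)

    def test_masked_out_voxels_are_nan(self, small_series):
        m = np.zeros((3, 3, 2), dtype=bool)
        m[0, 0, 0] = True
        maps = fit_volume(small_series, io.ROIMask(m), "adc")
        assert np.isfinite(maps["ADC"].values[0, 0, 0])
        assert np.isnan(maps["ADC"].values[1, 1, 1])

    def test_bad_voxel_isolated_in_vmre_map(self, small_series):
        series = io.DWISeries(small_series.signal.copy(), small_series.bvalues)
        series.signal[1, 1, 1, -1] = 0.0  # kill the b=800 volume of one voxel
        mask = io.ROIMask(np.ones((3, 3, 2), dtype=bool))
        maps = fit_volume(series, mask, "vmre")
        assert np.isnan(maps["mu_diff"].values[1, 1, 1])
        assert np.isfinite(maps["mu_diff"].values[0, 1, 1])

    def test_volume_fit_equals_per_voxel_full_fit(self, bvalues):
        rng = np.random.default_rng(5)
        vol = np.empty((2, 2, 1, bvalues.size))
        for idx in np.ndindex(2, 2, 1):
            f, d, ds = rng.uniform(0.1, 0.3), rng.uniform(1e-3, 2e-3), rng.uniform(0.05, 0.2)
            vol[idx] = biexp_signal(f, d, ds, 1.0, bvalues)
        series = io.DWISeries(vol, bvalues)
        mask = io.ROIMask(np.ones((2, 2, 1), dtype=bool))
        maps = fit_volume(series, mask, "ivim_full")
        for idx in np.ndindex(2, 2, 1):
            ref = fit_ivim_full(vol[idx], bvalues)
            assert maps["f"].values[idx] == pytest.approx(ref.f, rel=1e-9, abs=1e-12)
            assert maps["Dstar"].values[idx] == pytest.approx(ref.Dstar, rel=1e-9)

    def test_grid_mismatch_rejected(self, small_series):
        with pytest.raises(ValueError, match="grid"):
            fit_volume(small_series, io.ROIMask(np.ones((4, 4, 4), dtype=bool)), "adc")
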