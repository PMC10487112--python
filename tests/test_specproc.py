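"""Processing-chain contracts: each correction is verified by
inject-then-recover constructions and against brute-force oracles."""

import numpy as np
import pytest

from hgmrs import specproc, synthspec
from hgmrs.containers import FID, AcquisitionParams, Spectrum
from hgmrs.specproc import (apodize, baseline_correct, eddy_correct,
                            frequency_align, phase_correct, process,
                            to_spectrum, zero_fill)
from hgmrs.synthspec import VoxelTruth, simulate_fid, tissue_concentrations


def naive_dft(x: np.ndarray) -> np.ndarray:
    """O(N^2) reference DFT (unscaled forward transform)."""
    n = len(x)
    k = np.arange(n)
    return np.array([np.sum(x * np.exp(-2j * np.pi * kk * k / n)) for kk in range(n)])


@pytest.fixture()
def gray_fid(acq):
    return simulate_fid(
        VoxelTruth(concentrations=tissue_concentrations("gray")), acq, seed=1)


class TestApodize:
    def test_hanning_window_values(self, acq):
        # w(0) = 1, w(256 ms) = 0.5, w(512 ms) = 0
        fid = FID(np.ones(1024, complex), acq)
        out = apodize(fid)
        assert out.samples[0] == pytest.approx(1.0)
        i256 = int(256.0 / acq.dwell_ms)
        assert out.samples[i256].real == pytest.approx(0.5)
        t_ms = acq.time_axis_s() * 1e3
        edge = np.flatnonzero(t_ms >= 512.0 - acq.dwell_ms / 2)
        if edge.size:
            assert abs(out.samples[edge[0]]) == pytest.approx(0.0, abs=1e-4)

    def test_window_zero_beyond_width(self):
        acq = AcquisitionParams(n_points=2048, dwell_ms=0.5)  # spans 1024 ms
        out = apodize(FID(np.ones(2048, complex), acq))
        t_ms = acq.time_axis_s() * 1e3
        assert np.all(out.samples[t_ms > 512.0] == 0)

    def test_length_unchanged(self, gray_fid):
        assert len(apodize(gray_fid)) == len(gray_fid)


class TestZeroFill:
    def test_default_doubles_1024_to_2048(self, gray_fid):
        out = zero_fill(gray_fid)
        assert len(out) == 2048
        np.testing.assert_array_equal(out.samples[:1024], gray_fid.samples)
        assert np.all(out.samples[1024:] == 0)

    def test_identity_when_target_equals_length(self, gray_fid):
        out = zero_fill(gray_fid, target=1024)
        np.testing.assert_array_equal(out.samples, gray_fid.samples)

    def test_energy_preserved(self, gray_fid):
        out = zero_fill(gray_fid)
        assert np.sum(np.abs(out.samples) ** 2) == pytest.approx(
            np.sum(np.abs(gray_fid.samples) ** 2))

    def test_shrinking_rejected(self, gray_fid):
        with pytest.raises(ValueError, match="target"):
            zero_fill(gray_fid, target=512)


class TestToSpectrum:
    @pytest.mark.parametrize("n", [8, 64, 256])
    def test_matches_bruteforce_dft(self, n):
        rng = np.random.default_rng(n)
        acq = AcquisitionParams(n_points=n)
        fid = FID(rng.standard_normal(n) + 1j * rng.standard_normal(n), acq)
        spec = to_spectrum(fid)
        oracle = np.fft.fftshift(naive_dft(fid.samples))
        np.testing.assert_allclose(spec.values, oracle,
                                   rtol=1e-9, atol=1e-9 * np.abs(oracle).max())

    def test_single_resonance_lands_on_its_shift(self, acq):
        fid = simulate_fid(VoxelTruth(concentrations={"NAA": 5.0}), acq, seed=0)
        spec = to_spectrum(fid)
        peak = spec.ppm_axis[np.argmax(np.abs(spec.values))]
        assert abs(peak - 2.008) <= abs(spec.dppm)

    def test_zero_in_zero_out(self, acq):
        spec = to_spectrum(FID(np.zeros(1024, complex), acq))
        assert np.all(spec.values == 0)

    def test_parseval_with_unscaled_forward(self, gray_fid):
        spec = to_spectrum(gray_fid)
        n = len(gray_fid)
        assert np.sum(np.abs(spec.values) ** 2) == pytest.approx(
            n * np.sum(np.abs(gray_fid.samples) ** 2))

    def test_rejects_non_fid(self, healthy_spec):
        with pytest.raises(TypeError):
            to_spectrum(healthy_spec)


class TestEddyCorrect:
    def test_zero_phase_water_is_identity(self, gray_fid, acq):
        water = FID(np.full(1024, 2.0 + 0j), acq)
        out = eddy_correct(gray_fid, water)
        np.testing.assert_allclose(out.samples, gray_fid.samples, atol=1e-12)

    def test_known_smooth_phase_recovered(self, gray_fid, acq):
        t = acq.time_axis_s()
        phase = 0.4 * np.sin(2 * np.pi * 3.0 * t) + 0.2
        distorted = gray_fid.copy_with(gray_fid.samples * np.exp(1j * phase))
        water = FID(np.exp(1j * phase), acq)
        out = eddy_correct(distorted, water)
        np.testing.assert_allclose(out.samples, gray_fid.samples, atol=1e-6)

    def test_magnitudes_untouched(self, gray_fid, acq):
        rng = np.random.default_rng(0)
        water = FID(np.exp(1j * rng.uniform(-np.pi, np.pi, 1024)), acq)
        out = eddy_correct(gray_fid, water)
        np.testing.assert_allclose(np.abs(out.samples), np.abs(gray_fid.samples),
                                   atol=1e-12)

    def test_length_mismatch_rejected(self, gray_fid, acq):
        with pytest.raises(ValueError, match="mismatch"):
            eddy_correct(gray_fid, FID(np.ones(512, complex), acq))


class TestFrequencyAlign:
    def test_aligned_spectrum_barely_moves(self, gray_fid):
        spec = to_spectrum(zero_fill(apodize(gray_fid)), halve_first_point=True)
        out = frequency_align(spec)
        rec = out.provenance[-1]
        assert rec["aligned"]
        assert abs(rec["shift_ppm"]) <= abs(spec.dppm)

    def test_injected_shift_recovered(self, acq):
        truth = VoxelTruth(concentrations=tissue_concentrations("gray"),
                           shift_ppm=0.05)
        spec = to_spectrum(zero_fill(apodize(simulate_fid(truth, acq, 0))),
                           halve_first_point=True)
        out = frequency_align(spec)
        rec = out.provenance[-1]
        assert rec["shift_ppm"] == pytest.approx(-0.05, abs=abs(spec.dppm))

    def test_pure_noise_flagged_and_unshifted(self, acq):
        rng = np.random.default_rng(5)
        spec = to_spectrum(FID(rng.standard_normal(1024)
                               + 1j * rng.standard_normal(1024), acq))
        out = frequency_align(spec)
        assert "alignment_failed" in out.flags
        np.testing.assert_array_equal(out.values, spec.values)


class TestBaselineCorrect:
    @staticmethod
    def _poly_on_axis(acq, coeffs, n=2048):
        ppm = acq.ppm_axis(n)
        u = (2 * ppm - (ppm.min() + ppm.max())) / (ppm.max() - ppm.min())
        return ppm, np.polynomial.polynomial.polyval(u, np.asarray(coeffs))

    def test_degree6_baseline_removed_exactly(self, acq):
        ppm, base = self._poly_on_axis(acq, [5, -3, 2, 1, -0.5, 0.25, 1.5])
        spec = Spectrum(values=base.astype(complex), ppm_axis=ppm, acq=acq)
        out = baseline_correct(spec)
        rms = np.sqrt(np.mean(out.values.real ** 2))
        assert rms < 1e-8 * np.max(np.abs(base))

    def test_zero_baseline_leaves_spectrum_alone(self, healthy_spec):
        out = baseline_correct(healthy_spec)
        np.testing.assert_allclose(out.values, healthy_spec.values, atol=1e-6)

    def test_degree_reported_is_six(self, healthy_spec):
        out = baseline_correct(healthy_spec)
        assert out.provenance[-1]["degree"] == 6

    def test_too_few_support_points_rejected(self, acq):
        ppm = np.linspace(2.0, 2.1, 32)   # entirely inside the NAA window
        spec = Spectrum(values=np.zeros(32, complex), ppm_axis=ppm, acq=acq)
        with pytest.raises(ValueError, match="baseline points"):
            baseline_correct(spec)


class TestPhaseCorrect:
    def test_injected_37_degrees_recovered(self, gray_fid):
        ref = phase_correct(to_spectrum(zero_fill(apodize(gray_fid)),
                                        halve_first_point=True))
        rotated = ref.copy_with(ref.values * np.exp(1j * np.deg2rad(37.0)))
        out = phase_correct(rotated)
        np.testing.assert_allclose(out.values, ref.values,
                                   atol=1e-6 * np.abs(ref.values).max())
        assert out.provenance[-1]["phase_deg"] == pytest.approx(37.0, abs=1e-6)

    def test_idempotent_on_phased_spectrum(self, gray_fid):
        once = phase_correct(to_spectrum(zero_fill(apodize(gray_fid)),
                                         halve_first_point=True))
        twice = phase_correct(once)
        assert twice.provenance[-1]["phase_deg"] == pytest.approx(0.0, abs=1e-9)

    def test_magnitude_preserving(self, healthy_spec):
        rotated = healthy_spec.copy_with(healthy_spec.values * np.exp(0.3j))
        out = phase_correct(rotated)
        np.testing.assert_allclose(np.abs(out.values), np.abs(rotated.values),
                                   atol=1e-9)


class TestProcessChain:
    EXPECTED_ORDER = ["eddy_correct", "apodize", "zero_fill", "to_spectrum",
                      "frequency_align", "baseline_correct", "phase_correct"]

    def test_provenance_lists_all_steps_in_order(self, acq):
        truth = VoxelTruth(concentrations=tissue_concentrations("gray"),
                           phase0_deg=10.0)
        fid = simulate_fid(truth, acq, seed=1)
        water = synthspec.simulate_water_reference(acq, seed=1, phase0_deg=10.0)
        spec = process(fid, water_fid=water)
        assert spec.steps == self.EXPECTED_ORDER

    def test_water_step_skipped_without_reference(self, gray_fid):
        spec = process(gray_fid)
        assert spec.steps == self.EXPECTED_ORDER[1:]

    def test_all_zero_fid_yields_flagged_zero_spectrum(self, acq):
        spec = process(FID(np.zeros(1024, complex), acq))
        assert np.all(spec.values == 0)
        assert "alignment_failed" in spec.flags

    def test_distorted_voxel_recovers_clean_areas(self, acq, healthy_panel):
        from hgmrs import peakfit
        co = (2.0, -1.0, 0.5, 0.3, -0.2, 0.1, 0.05)
        truth = VoxelTruth(concentrations=tissue_concentrations("gray"),
                           phase0_deg=15.0, shift_ppm=0.02, baseline_coeffs=co)
        panel = peakfit.fit_panel(process(simulate_fid(truth, acq, seed=1)))
        # frequency alignment is quantized to the spectral grid, so compare
        # fitted areas (which re-center) rather than pointwise values
        for name, fit in panel.fits.items():
            assert fit.area == pytest.approx(healthy_panel.area(name),
                                             rel=0.05), name
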