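"""31P NMR processing: apodization, FT, baseline, calibration, deconvolution."""

import logging

import numpy as np
import pytest

from evlipid.nmr_quantification import (
    CalibrationError,
    Fid,
    NmrSpectrum,
    apodize_fid,
    assign_and_quantify,
    baseline_correct,
    calibrate,
    deconvolute,
    load_shift_table,
    process_fid,
    transform_and_scale,
)
from evlipid.synthetic_data import generate_lipidome, simulate_nmr

CARRIER = 242.93


def damped_cosinusoid_fid(freqs_hz, amps, rates, n=4096, dwell=1 / 2915.16):
    t = np.arange(n) * dwell
    pts = np.zeros(n, dtype=complex)
    for f, a, r in zip(freqs_hz, amps, rates):
        pts += a * np.exp(2j * np.pi * f * t - r * t)
    return Fid(pts, dwell, CARRIER)


def lorentzian_spectrum(centers, fwhms, amps, lo=-4, hi=4, n=4096):
    ppm = np.linspace(hi, lo, n)
    y = np.zeros(n)
    for c, w, a in zip(centers, fwhms, amps):
        g = w / 2
        y += a * g ** 2 / ((ppm - c) ** 2 + g ** 2)
    return NmrSpectrum(ppm, y)


class TestApodize:
    def test_zero_broadening_is_identity(self):
        fid = damped_cosinusoid_fid([100], [1.0], [20.0])
        out = apodize_fid(fid, 0.0)
        assert np.array_equal(out.points, fid.points)

    def test_exponential_envelope(self):
        n, dwell = 256, 1e-3
        fid = Fid(np.ones(n, dtype=complex), dwell)
        out = apodize_fid(fid, 3.0)
        k = np.arange(n)
        expected = np.exp(-np.pi * 3.0 * k * dwell)
        assert np.allclose(np.abs(out.points), expected)
        assert out.points[0] == 1.0  # first point untouched

    def test_negative_broadening_rejected(self):
        fid = Fid(np.ones(4, dtype=complex), 1e-3)
        with pytest.raises(ValueError):
            apodize_fid(fid, -1.0)

    def test_linewidth_increases_by_lb_over_carrier(self):
        truth = generate_lipidome("paper-like", seed=2)
        fid, _ = simulate_nmr(truth, snr=np.inf, seed=2, fwhm_range=(0.05, 0.05))
        widths = {}
        for lb in (0.0, 3.0):
            spec = calibrate(transform_and_scale(apodize_fid(fid, lb)))
            pc = min(deconvolute(spec), key=lambda f: abs(f.center))
            widths[lb] = pc.fwhm
        assert widths[3.0] - widths[0.0] == pytest.approx(3.0 / CARRIER, rel=0.10)


class TestTransform:
    def test_single_damped_cosinusoid_peaks_at_offset(self):
        f_hz = 0.5 * CARRIER  # 0.5 ppm
        fid = damped_cosinusoid_fid([f_hz], [1.0], [30.0])
        spec = transform_and_scale(fid)
        apex = spec.ppm[np.argmax(spec.intensity)]
        assert apex == pytest.approx(0.5, abs=0.01)

    def test_area_ratio_tracks_amplitude_ratio(self):
        fid = damped_cosinusoid_fid([-1.0 * CARRIER, 1.5 * CARRIER],
                                    [3.0, 1.0], [25.0, 25.0])
        spec = transform_and_scale(fid)
        fits = sorted(deconvolute(spec), key=lambda f: f.center)
        assert len(fits) == 2
        # the amplitude-3 line sits at the lower ppm, so it is fits[0]
        assert fits[0].area / fits[1].area == pytest.approx(3.0, rel=0.01)

    def test_zero_fid_gives_zero_spectrum(self):
        spec = transform_and_scale(Fid(np.zeros(128, dtype=complex), 1e-3))
        assert np.allclose(spec.intensity, 0.0)

    def test_ppm_axis_descending(self):
        spec = transform_and_scale(damped_cosinusoid_fid([100], [1], [30]))
        assert np.all(np.diff(spec.ppm) < 0)


class TestBaseline:
    def test_linear_ramp_removed_areas_preserved(self):
        spec = lorentzian_spectrum([0.0], [0.05], [10.0])
        area0 = deconvolute(spec)[0].area
        ramp = 0.5 + 0.3 * np.linspace(-1, 1, len(spec.ppm))
        tilted = NmrSpectrum(spec.ppm, spec.intensity + ramp)
        fixed = baseline_correct(tilted, polynomial_order=1)
        area1 = deconvolute(fixed)[0].area
        assert area1 == pytest.approx(area0, rel=0.01)

    def test_flat_zero_unchanged(self):
        spec = NmrSpectrum(np.linspace(4, -4, 64), np.zeros(64))
        out = baseline_correct(spec)
        assert np.allclose(out.intensity, 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        spec = lorentzian_spectrum([0.0, -1.0], [0.05, 0.04], [10.0, 2.0])
        noisy = NmrSpectrum(spec.ppm, spec.intensity + rng.normal(0, 0.01, len(spec.ppm)))
        once = baseline_correct(noisy)
        twice = baseline_correct(once)
        scale = np.abs(once.intensity).max()
        assert np.allclose(once.intensity, twice.intensity, atol=1e-6 * scale + 1e-3)

    def test_too_short_spectrum_rejected(self):
        spec = NmrSpectrum(np.array([1.0, 0.0]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            baseline_correct(spec, polynomial_order=3)


class TestCalibrate:
    def test_apex_lands_exactly_at_zero(self):
        spec = lorentzian_spectrum([-0.84], [0.05], [10.0])
        out = calibrate(spec)
        assert out.ppm[np.argmax(out.intensity)] == 0.0

    def test_idempotent(self):
        spec = calibrate(lorentzian_spectrum([-0.84], [0.05], [10.0]))
        again = calibrate(spec)
        assert np.array_equal(spec.ppm, again.ppm)

    def test_tie_uses_leftmost_peak(self, caplog):
        ppm = np.linspace(4, -4, 801)
        y = np.zeros(801)
        y[200] = y[600] = 5.0  # equal maxima at +2 and -2 ppm
        with caplog.at_level(logging.WARNING):
            out = calibrate(NmrSpectrum(ppm, y))
        assert out.ppm[200] == 0.0  # higher-ppm apex chosen
        assert "tie" in caplog.text

    def test_pure_noise_raises(self):
        rng = np.random.default_rng(0)
        spec = NmrSpectrum(np.linspace(4, -4, 512), rng.normal(0, 1.0, 512))
        with pytest.raises(CalibrationError):
            calibrate(spec)


class TestDeconvolute:
    def test_single_lorentzian_recovered(self):
        rng = np.random.default_rng(5)
        spec = lorentzian_spectrum([-0.1], [0.05], [2 / (np.pi * 0.05)])  # area 1
        noisy = NmrSpectrum(spec.ppm, spec.intensity + rng.normal(0, 0.01 * spec.intensity.max(), len(spec.ppm)))
        fits = deconvolute(noisy)
        assert len(fits) == 1
        f = fits[0]
        assert f.center == pytest.approx(-0.1, abs=0.002)
        assert f.fwhm == pytest.approx(0.05, rel=0.02)
        assert f.area == pytest.approx(1.0, rel=0.02)

    def test_two_peaks_separated_by_three_fwhm(self):
        spec = lorentzian_spectrum([0.0, 0.15], [0.05, 0.05], [10.0, 4.0])
        fits = sorted(deconvolute(spec), key=lambda f: f.center)
        assert len(fits) == 2
        assert fits[0].area / fits[1].area == pytest.approx(10.0 / 4.0, rel=0.02)

    def test_zero_spectrum_gives_empty_fit(self):
        spec = NmrSpectrum(np.linspace(4, -4, 256), np.zeros(256))
        assert deconvolute(spec) == []

    def test_area_matches_closed_form(self):
        spec = lorentzian_spectrum([0.0], [0.06], [7.0])
        f = deconvolute(spec)[0]
        assert f.area == pytest.approx(f.amplitude * f.fwhm * np.pi / 2, rel=1e-6)


class TestAssignAndQuantify:
    table = {"PC": (0.0, 0.12), "SM": (-0.40, 0.12), "PE": (0.85, 0.12)}

    def fits(self, centers_areas):
        from evlipid.nmr_quantification import NMRPeakFit
        return [NMRPeakFit(c, 0.05, a / (0.05 * np.pi / 2), a)
                for c, a in centers_areas]

    def test_single_class_is_hundred_percent(self):
        out = assign_and_quantify(self.fits([(0.0, 1.0)]), self.table)
        assert out[0].lipid_class == "PC"
        assert out[0].percent == pytest.approx(100.0)

    def test_percentages_reflect_area_ratios(self):
        out = assign_and_quantify(
            self.fits([(0.0, 0.767), (-0.40, 0.203), (0.85, 0.030)]), self.table)
        by = {a.lipid_class: a for a in out}
        assert by["PC"].percent == pytest.approx(76.7, abs=1e-9)
        assert by["SM"].percent == pytest.approx(20.3, abs=1e-9)
        assert by["PE"].percent == pytest.approx(3.0, abs=1e-9)
        assert by["PC"].quantifiable and by["SM"].quantifiable
        assert by["PE"].quantifiable  # exactly at the 3% limit

    def test_sub_three_percent_flagged(self):
        out = assign_and_quantify(
            self.fits([(0.0, 0.98), (-0.40, 0.02)]), self.table)
        by = {a.lipid_class: a for a in out}
        assert not by["SM"].quantifiable

    def test_far_peak_unassigned_and_excluded(self, caplog):
        with caplog.at_level(logging.WARNING):
            out = assign_and_quantify(
                self.fits([(0.0, 1.0), (10.0, 5.0)]), self.table)
        assert sum(a.percent for a in out) == pytest.approx(100.0)
        assert {a.lipid_class for a in out} == {"PC"}

    def test_nothing_assignable_raises(self):
        with pytest.raises(ValueError):
            assign_and_quantify(self.fits([(10.0, 1.0)]), self.table)

    def test_percentages_sum_to_hundred(self):
        out = assign_and_quantify(
            self.fits([(0.0, 0.61), (-0.41, 0.22), (0.86, 0.09)]), self.table)
        assert sum(a.percent for a in out) == pytest.approx(100.0, abs=1e-6)


class TestFullPipeline:
    def test_recovery_invariant_to_scaling_and_shift(self):
        truth = generate_lipidome("paper-like", seed=9)
        fid, _ = simulate_nmr(truth, snr=200, seed=9)
        base, _, _ = process_fid(fid)
        scaled = Fid(fid.points * 37.5, fid.dwell_time, fid.carrier_frequency)
        out, _, _ = process_fid(scaled)
        a = {x.lipid_class: x.percent for x in base}
        b = {x.lipid_class: x.percent for x in out}
        assert set(a) == set(b)
        for cls in a:
            # identical up to optimizer stopping jitter (absolute step criteria)
            assert a[cls] == pytest.approx(b[cls], abs=1e-3)

    def test_recovers_class_fractions_within_two_points(self):
        truth = generate_lipidome("paper-like", seed=4)
        fid, fractions = simulate_nmr(truth, snr=100, seed=4)
        out, _, _ = process_fid(fid)
        got = {x.lipid_class: x.percent for x in out}
        for cls, frac in fractions.items():
            assert abs(got.get(cls, 0.0) - 100 * frac) < 2.0
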