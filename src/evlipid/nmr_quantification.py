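"""Quantitative 31P NMR processing for phospholipid class composition.

Pipeline: exponential apodization of the FID, Fourier transform with
zero-order phasing, polynomial baseline correction, chemical-shift
calibration (tallest peak, phosphatidylcholine, set to exactly 0 ppm),
Lorentzian deconvolution, chemical-shift class assignment and area
normalization to percentages. Classes below 3% of the total assigned area
are flagged as not reliably quantifiable.

The lineshape is pure Lorentzian (liquid-state 31P); a Lorentzian with
height ``amplitude``, full width at half maximum ``fwhm`` and center ``c``
has closed-form area amplitude * fwhm * pi / 2, which is how peak areas are
computed after fitting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import find_peaks

__all__ = [
    "Fid",
    "NmrSpectrum",
    "NMRPeakFit",
    "ClassAbundance",
    "CalibrationError",
    "DeconvolutionError",
    "apodize_fid",
    "transform_and_scale",
    "baseline_correct",
    "calibrate",
    "deconvolute",
    "assign_and_quantify",
    "process_fid",
    "load_shift_table",
    "read_fid_csv",
    "write_fid_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "abundances_to_frame",
    "DEFAULT_CARRIER_MHZ",
    "QUANTIFIABILITY_LIMIT_PCT",
]

logger = logging.getLogger(__name__)

DEFAULT_CARRIER_MHZ = 242.93     # 31P carrier on a 600 MHz instrument
QUANTIFIABILITY_LIMIT_PCT = 3.0  # classes below this share are flagged
_NOISE_PROMINENCE = 5.0          # peak detection threshold, x robust noise


class CalibrationError(ValueError):
    """No peak rises far enough above the noise to define 0 ppm."""


class DeconvolutionError(RuntimeError):
    """Lorentzian fit failed to converge; carries the best fit so far."""

    def __init__(self, message: str, best_fit: list["NMRPeakFit"]):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass
class Fid:
    """Free-induction decay: complex time-domain points at fixed dwell time."""

    points: np.ndarray
    dwell_time: float                            # seconds per point
    carrier_frequency: float = DEFAULT_CARRIER_MHZ  # MHz

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=complex)
        if self.points.ndim != 1 or len(self.points) < 2:
            raise ValueError("FID needs at least 2 points")
        if self.dwell_time <= 0:
            raise ValueError("dwell time must be positive")


@dataclass
class NmrSpectrum:
    """Real spectrum on a strictly descending ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    carrier_frequency: float = DEFAULT_CARRIER_MHZ

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape:
            raise ValueError("ppm and intensity must have equal length")
        if len(self.ppm) >= 2 and not np.all(np.diff(self.ppm) < 0):
            raise ValueError("ppm axis must be strictly descending")


@dataclass
class NMRPeakFit:
    """One fitted Lorentzian component."""

    center: float      # ppm
    fwhm: float        # ppm
    amplitude: float   # peak height
    area: float        # amplitude * fwhm * pi / 2
    assigned_class: str | None = None


@dataclass
class ClassAbundance:
    lipid_class: str
    percent: float
    quantifiable: bool


def robust_noise(intensity: np.ndarray) -> float:
    """Noise scale as 1.4826 x median absolute deviation (peak-tolerant)."""
    med = np.median(intensity)
    return float(1.4826 * np.median(np.abs(intensity - med)))


# ---------------------------------------------------------------------------
# Processing steps, in acquisition order
# ---------------------------------------------------------------------------

def apodize_fid(fid: Fid, lb_hz: float) -> Fid:
    """Exponential line broadening: point k scaled by exp(-pi*lb*k*dwell).

    Adds exactly ``lb_hz`` Hz (= lb_hz / carrier ppm) to every Lorentzian
    linewidth while leaving peak areas untouched (the first point, which
    fixes the integral, is unchanged).
    """
    if lb_hz < 0:
        raise ValueError("line broadening must be non-negative")
    k = np.arange(len(fid.points))
    window = np.exp(-np.pi * lb_hz * k * fid.dwell_time)
    return replace(fid, points=fid.points * window)


def transform_and_scale(fid: Fid) -> NmrSpectrum:
    """DFT to a ppm axis with zero-order phasing.

    The first FID point is halved (standard DC-offset correction), the
    transform is centered with fftshift, frequency (Hz) is divided by the
    carrier (MHz) to give ppm, and a global phase maximizing the total
    integrated real signal is applied — for all-positive absorption peaks
    this is the phase that maximizes positive area.
    """
    pts = fid.points.copy()
    pts[0] *= 0.5
    spec = np.fft.fftshift(np.fft.fft(pts))
    freq = np.fft.fftshift(np.fft.fftfreq(len(pts), fid.dwell_time))
    total = spec.sum()
    phase = -np.angle(total) if np.abs(total) > 0 else 0.0
    real = np.real(spec * np.exp(1j * phase))
    ppm = freq / fid.carrier_frequency
    order = np.argsort(ppm)[::-1]
    return NmrSpectrum(ppm[order], real[order], fid.carrier_frequency)


def baseline_correct(spectrum: NmrSpectrum, polynomial_order: int = 2,
                     clip_sigma: float = 3.0, max_iter: int = 20) -> NmrSpectrum:
    """Subtract a polynomial fitted to signal-free regions.

    Signal points are excluded by iterative sigma-clipping: fit, drop points
    more than ``clip_sigma`` residual sigmas away, refit until the mask is
    stable. Approximately idempotent.
    """
    if polynomial_order > 5:
        raise ValueError("polynomial order above 5 is not supported")
    n = len(spectrum.ppm)
    if n < polynomial_order + 1:
        raise ValueError("spectrum shorter than polynomial order + 1")
    x = np.linspace(-1.0, 1.0, n)
    y = spectrum.intensity
    mask = np.ones(n, dtype=bool)
    coeffs = np.zeros(polynomial_order + 1)
    for _ in range(max_iter):
        coeffs = np.polyfit(x[mask], y[mask], polynomial_order)
        resid = y - np.polyval(coeffs, x)
        sigma = np.std(resid[mask])
        if sigma == 0:
            break
        new_mask = np.abs(resid) <= clip_sigma * sigma
        if new_mask.sum() < polynomial_order + 1 or np.array_equal(new_mask, mask):
            break
        mask = new_mask
    return replace(spectrum, intensity=y - np.polyval(coeffs, x))


def calibrate(spectrum: NmrSpectrum, min_snr: float = 5.0) -> NmrSpectrum:
    """Shift the ppm axis so the most intense peak apex sits at exactly 0 ppm.

    The tallest signal is the most abundant phospholipid (PC) by
    construction of the assay. Ties go to the higher-ppm (leftmost) apex.
    Raises CalibrationError when no point exceeds ``min_snr`` x robust noise.
    """
    y = spectrum.intensity
    noise = robust_noise(y)
    apex = int(np.argmax(y))  # first index = highest ppm on a descending axis
    if noise > 0 and y[apex] < min_snr * noise:
        raise CalibrationError("no peak above the noise floor; cannot set 0 ppm")
    if noise == 0 and y[apex] <= 0:
        raise CalibrationError("flat spectrum; cannot set 0 ppm")
    ties = np.flatnonzero(y == y[apex])
    if len(ties) > 1:
        logger.warning("calibration tie between %d equal maxima; using the "
                       "highest-ppm apex", len(ties))
    return replace(spectrum, ppm=spectrum.ppm - spectrum.ppm[apex])


def _lorentz(x: np.ndarray, amp: float, center: float, fwhm: float) -> np.ndarray:
    g = fwhm / 2.0
    return amp * g ** 2 / ((x - center) ** 2 + g ** 2)


def _model(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    for amp, c, w in params.reshape(-1, 3):
        out += _lorentz(x, amp, c, w)
    return out


def _jacobian(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    jac = np.empty((len(x), len(params)))
    for i, (amp, c, w) in enumerate(params.reshape(-1, 3)):
        g = w / 2.0
        denom = (x - c) ** 2 + g ** 2
        jac[:, 3 * i] = g ** 2 / denom
        jac[:, 3 * i + 1] = 2.0 * amp * g ** 2 * (x - c) / denom ** 2
        jac[:, 3 * i + 2] = amp * g * (x - c) ** 2 / denom ** 2
    return jac


def _detect_peaks(x: np.ndarray, y: np.ndarray, noise: float) -> list[float]:
    """Local maxima exceeding the noise floor in both height and prominence."""
    floor = max(_NOISE_PROMINENCE * noise, 1e-12 * max(1.0, float(np.abs(y).max())))
    idx, _ = find_peaks(y, prominence=floor, height=floor)
    return list(x[idx])


def deconvolute(
    spectrum: NmrSpectrum,
    init_peaks: Sequence[float] | None = None,
    init_fwhm: float = 0.04,
    max_fwhm: float = 0.3,
    max_center_shift: float = 0.12,
    max_nfev: int = 20000,
    min_amplitude_snr: float = 1.0,
    min_separation: float = 0.06,
) -> list[NMRPeakFit]:
    """Nonlinear least-squares fit of a sum of Lorentzians.

    ``init_peaks`` are initial center positions (ppm); by default they come
    from local-maxima detection at 5 x robust noise prominence. Seeds closer
    than ``min_separation`` are merged (keeping the taller one) so a single
    line is never fitted as two half-amplitude components. Fitted components
    whose amplitude stays below ``min_amplitude_snr`` x noise are discarded
    (they model noise, not peaks). Returns [] for a peakless spectrum.
    Non-convergence raises DeconvolutionError carrying the best fit so far.
    """
    x = spectrum.ppm
    y = spectrum.intensity
    noise = robust_noise(y)
    if init_peaks is None:
        init_peaks = _detect_peaks(x, y, noise)
    init_peaks = sorted(set(float(p) for p in init_peaks), reverse=True)
    if not init_peaks:
        return []

    def height_at(c: float) -> float:
        return float(np.interp(c, x[::-1], y[::-1]))

    merged: list[float] = []
    for c in init_peaks:  # descending ppm
        if merged and abs(merged[-1] - c) < min_separation:
            if height_at(c) > height_at(merged[-1]):
                merged[-1] = c
        else:
            merged.append(c)
    init_peaks = merged

    step = float(np.median(np.abs(np.diff(x))))
    x0, lb, ub = [], [], []
    for c in init_peaks:
        x0 += [max(height_at(c), noise if noise > 0 else 1e-12), c, init_fwhm]
        lb += [0.0, c - max_center_shift, max(step, 1e-4)]
        ub += [np.inf, c + max_center_shift, max_fwhm]
    res = least_squares(
        lambda p: _model(p, x) - y, x0=np.array(x0), jac=lambda p: _jacobian(p, x),
        bounds=(np.array(lb), np.array(ub)), max_nfev=max_nfev, method="trf")
    fits = [
        NMRPeakFit(center=float(c), fwhm=float(w), amplitude=float(a),
                   area=float(a * w * np.pi / 2.0))
        for a, c, w in res.x.reshape(-1, 3)
    ]
    fits = [f for f in fits if f.amplitude >= min_amplitude_snr * noise]
    fits.sort(key=lambda f: -f.center)
    if not res.success:
        raise DeconvolutionError("Lorentzian fit did not converge", fits)
    return fits


def assign_and_quantify(
    peak_fits: Sequence[NMRPeakFit],
    shift_table: Mapping[str, tuple[float, float]],
) -> list[ClassAbundance]:
    """Assign fitted peaks to classes by chemical shift and normalize areas.

    ``shift_table`` maps class -> (center ppm, tolerance ppm) with PC at 0.0
    by construction of the calibration. Peaks outside every tolerance stay
    unassigned and are excluded from the total. Percentages sum to 100;
    classes under the 3% limit are flagged not quantifiable.
    """
    assigned: dict[str, float] = {}
    for fit in peak_fits:
        best_cls, best_d = None, np.inf
        for cls, (center, tol) in shift_table.items():
            d = abs(fit.center - center)
            if d <= tol and d < best_d:
                best_cls, best_d = cls, d
        fit.assigned_class = best_cls
        if best_cls is None:
            logger.warning("peak at %.3f ppm not within tolerance of any class; "
                           "excluded from quantification", fit.center)
            continue
        assigned[best_cls] = assigned.get(best_cls, 0.0) + fit.area
    total = sum(assigned.values())
    if total <= 0:
        raise ValueError("no assignable peaks; nothing to quantify")
    return [
        ClassAbundance(cls, 100.0 * area / total,
                       quantifiable=100.0 * area / total >= QUANTIFIABILITY_LIMIT_PCT)
        for cls, area in sorted(assigned.items(), key=lambda kv: -kv[1])
    ]


def process_fid(
    fid: Fid,
    shift_table: Mapping[str, tuple[float, float]] | None = None,
    lb_hz: float = 3.0,
    baseline_order: int = 2,
    seed_from_table: bool = True,
) -> tuple[list[ClassAbundance], list[NMRPeakFit], NmrSpectrum]:
    """Full pipeline: apodize, transform, baseline, calibrate, fit, quantify.

    When ``seed_from_table`` is set, the Lorentzian fit is seeded with the
    union of detected maxima and the shift-table centers, so classes near
    the quantifiability limit are still fitted rather than silently missed.
    """
    if shift_table is None:
        shift_table = load_shift_table()
    spectrum = transform_and_scale(apodize_fid(fid, lb_hz))
    spectrum = baseline_correct(spectrum, baseline_order)
    spectrum = calibrate(spectrum)
    noise = robust_noise(spectrum.intensity)
    seeds = set(np.round(_detect_peaks(spectrum.ppm, spectrum.intensity, noise), 4))
    if seed_from_table:
        lo, hi = spectrum.ppm.min(), spectrum.ppm.max()
        seeds |= {c for c, _ in shift_table.values() if lo < c < hi}
    fits = deconvolute(spectrum, init_peaks=sorted(seeds, reverse=True))
    return assign_and_quantify(fits, shift_table), fits, spectrum


# ---------------------------------------------------------------------------
# Config and I/O
# ---------------------------------------------------------------------------

def load_shift_table(path: str | Path | None = None) -> dict[str, tuple[float, float]]:
    """Class -> (ppm, tolerance) table, PC = 0 by construction.

    The packaged default (data/cubo_shift_table.json) holds synthetic,
    user-editable positions for the CUBO solvent system; replace it with
    measured shifts for real samples.
    """
    if path is None:
        raw = json.loads(
            resources.files("evlipid.data").joinpath("cubo_shift_table.json").read_text())
    else:
        raw = json.loads(Path(path).read_text())
    return {cls: (float(v[0]), float(v[1])) for cls, v in raw.items()
            if not cls.startswith("_")}


def read_fid_csv(csv_path: str | Path, meta_path: str | Path) -> Fid:
    """FID from CSV (index, real, imag) + JSON metadata (dwell_time, carrier)."""
    df = pd.read_csv(csv_path).sort_values("index")
    meta = json.loads(Path(meta_path).read_text())
    return Fid(df["real"].to_numpy() + 1j * df["imag"].to_numpy(),
               dwell_time=float(meta["dwell_time"]),
               carrier_frequency=float(meta.get("carrier_frequency",
                                                DEFAULT_CARRIER_MHZ)))


def write_fid_csv(fid: Fid, csv_path: str | Path, meta_path: str | Path) -> None:
    pd.DataFrame({
        "index": np.arange(len(fid.points)),
        "real": fid.points.real,
        "imag": fid.points.imag,
    }).to_csv(csv_path, index=False)
    Path(meta_path).write_text(json.dumps({
        "dwell_time": fid.dwell_time,
        "carrier_frequency": fid.carrier_frequency,
    }, indent=1))


def read_spectrum_csv(path: str | Path) -> NmrSpectrum:
    df = pd.read_csv(path).sort_values("ppm", ascending=False)
    return NmrSpectrum(df["ppm"].to_numpy(), df["intensity"].to_numpy())


def write_spectrum_csv(spectrum: NmrSpectrum, path: str | Path) -> None:
    pd.DataFrame({"ppm": spectrum.ppm, "intensity": spectrum.intensity}).to_csv(
        path, index=False)


def abundances_to_frame(per_replicate: Sequence[Sequence[ClassAbundance]]) -> pd.DataFrame:
    """Tidy frame of class percentages, one row per (replicate, class)."""
    rows = [
        {"replicate": i + 1, "lipid_class": ab.lipid_class,
         "percent": ab.percent, "quantifiable": ab.quantifiable}
        for i, abunds in enumerate(per_replicate) for ab in abunds
    ]
    return pd.DataFrame(rows, columns=["replicate", "lipid_class", "percent",
                                       "quantifiable"])
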