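"""Synthetic instrument data with known ground truth.

Every input the analysis consumes — MS1 scan tables, MS2 peak lists with
iterative-exclusion runs, 31P FIDs, transwell fluorescence readings, DLS
intensity distributions — can be generated here with a fixed seed, so each
stage of the pipeline is testable against the truth that produced its input.

Two distinct ground truths are carried side by side: an MS-visible species
profile (within-headgroup relative abundances, ionization-biased, lyso
species folded into their parent headgroup) and 31P-NMR mole fractions per
phospholipid class. Real instruments disagree in exactly this way: MS sees
lyso-PC as a top-3 phosphocholine species while NMR puts all lyso-PC below
its 3% quantifiability limit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .bbb_dls import COMPARTMENTS, CompartmentReading, FluorescenceReadings
from .lipid_library import LipidSpecies, precursor_mz, predict_fragments, preferred_polarity
from .ms2_assignment import Ms2Spectrum, Peak
from .ms1_quantification import Ms1Scan
from .nmr_quantification import DEFAULT_CARRIER_MHZ, Fid, load_shift_table

__all__ = [
    "GroundTruth",
    "load_profile",
    "generate_lipidome",
    "simulate_ms_run",
    "simulate_nmr",
    "simulate_nmr_replicates",
    "simulate_bbb_readings",
    "simulate_dls",
    "GRADIENT_SPAN_MIN",
    "N_EXCLUSION_RUNS",
]

GRADIENT_SPAN_MIN = 17.0  # LC gradient length, minutes
N_EXCLUSION_RUNS = 4      # iterative-exclusion MS2 runs per polarity
RT_SIGMA_MIN = 0.06       # chromatographic peak sigma (same for all species)
MS1_SCAN_STEP_MIN = 0.05
MS1_BASE_INTENSITY = 1.0e6


@dataclass
class GroundTruth:
    """Everything a consuming test needs to score recovery."""

    lipidome: dict[str, float]          # species name -> MS-visible fraction
    class_fractions: dict[str, float]   # NMR class -> mole fraction
    nmr_shift_table: dict[str, tuple[float, float]]
    noise_params: dict[str, float]
    seed: int

    def species(self) -> list[LipidSpecies]:
        return [LipidSpecies.parse(name) for name in self.lipidome]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "lipidome": self.lipidome,
            "class_fractions": self.class_fractions,
            "nmr_shift_table": {k: list(v) for k, v in self.nmr_shift_table.items()},
            "noise_params": self.noise_params,
            "seed": self.seed,
        }, indent=1))


def load_profile(path: str | Path | None = None) -> dict:
    """Load generator setpoints; the packaged default is the paper-like one."""
    if path is None:
        raw = resources.files("evlipid.data").joinpath(
            "paper_like_profile.json").read_text()
    else:
        raw = Path(path).read_text()
    cfg = json.loads(raw)
    return {k: v for k, v in cfg.items() if not k.startswith("_")}


def _normalize(d: Mapping[str, float]) -> dict[str, float]:
    total = sum(d.values())
    return {k: v / total for k, v in d.items()}


def _jitter(rng: np.random.Generator, d: Mapping[str, float], sigma: float) -> dict[str, float]:
    """Multiplicative lognormal jitter followed by renormalization."""
    if sigma <= 0:
        return _normalize(d)
    keys = sorted(d)
    noisy = {k: d[k] * rng.lognormal(0.0, sigma) for k in keys}
    return _normalize(noisy)


def generate_lipidome(profile: str | dict = "paper-like", seed: int = 0) -> GroundTruth:
    """Draw one sample's ground truth around the profile setpoints.

    ``profile`` is "paper-like" (packaged setpoints, lognormal jitter),
    "uniform" (equal fractions, no jitter), or a custom config dict with the
    same structure as the packaged profile.
    """
    if isinstance(profile, str):
        if profile == "paper-like":
            cfg = load_profile()
            jitter = True
        elif profile == "uniform":
            cfg = load_profile()
            jitter = False
        else:
            raise ValueError(f"unknown profile {profile!r}")
        name = profile
    else:
        cfg = profile
        jitter = True
        name = "custom"
    noise = dict(cfg["noise_params"])
    for scope in (cfg["nmr_class_fractions"], cfg["ms_headgroup_weights"],
                  *cfg["ms_species_profiles"].values()):
        if any(v < 0 for v in scope.values()):
            raise ValueError("profile fractions must be non-negative")

    rng = np.random.default_rng(seed)
    sigma = float(noise.get("class_fraction_sigma", 0.0)) if jitter else 0.0

    if name == "uniform":
        all_species = [sp for prof in cfg["ms_species_profiles"].values() for sp in prof]
        lipidome = {sp: 1.0 / len(all_species) for sp in all_species}
        classes = sorted(cfg["nmr_class_fractions"])
        class_fractions = {c: 1.0 / len(classes) for c in classes}
    else:
        weights = _jitter(rng, cfg["ms_headgroup_weights"], sigma)
        lipidome = {}
        for hg in sorted(cfg["ms_species_profiles"]):
            within = _jitter(rng, cfg["ms_species_profiles"][hg], sigma)
            for sp_name, frac in within.items():
                lipidome[sp_name] = weights[hg] * frac
        class_fractions = _jitter(rng, cfg["nmr_class_fractions"], sigma)

    return GroundTruth(
        lipidome=lipidome,
        class_fractions=class_fractions,
        nmr_shift_table=load_shift_table(),
        noise_params=noise,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# LC-MS/MS simulation
# ---------------------------------------------------------------------------

def simulate_ms_run(
    truth: GroundTruth,
    polarity: str,
    n_decoys: int | None = None,
    seed: int | None = None,
    ppm_jitter: float | None = None,
    precursor_ppm_jitter: float | None = None,
    intensity_sigma: float | None = None,
) -> tuple[list[Ms1Scan], list[Ms2Spectrum]]:
    """Simulate one polarity's MS1 scans plus 4 iterative-exclusion MS2 runs.

    Each species detectable in ``polarity`` elutes as a Gaussian at a random
    retention time in [1, 16] min (shared chromatographic width, so XIC
    areas stay proportional to abundances); MS1 intensity is proportional to
    abundance times multiplicative lognormal noise. MS2 spectra are built
    from the predicted fragments with Gaussian ppm jitter plus ``n_decoys``
    uniform decoy peaks, and a precursor triggered in run k never reappears
    in later runs (abundance-ranked quartiles). Precursor m/z values come
    from the survey scan and carry their own, tighter jitter. The MS2 title
    records the true species and run for round-trip scoring.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    noise = truth.noise_params
    if n_decoys is None:
        n_decoys = int(noise.get("decoy_peak_rate", 0))
    if ppm_jitter is None:
        ppm_jitter = float(noise.get("ms_ppm_jitter", 0.0))
        if precursor_ppm_jitter is None:
            precursor_ppm_jitter = float(noise.get("ms_precursor_ppm_jitter",
                                                   ppm_jitter))
    if precursor_ppm_jitter is None:
        precursor_ppm_jitter = ppm_jitter
    if intensity_sigma is None:
        intensity_sigma = float(noise.get("intensity_lognormal_sigma", 0.0))

    species = [(name, frac) for name, frac in sorted(truth.lipidome.items())
               if preferred_polarity(LipidSpecies.parse(name)) == polarity]
    if not species:
        return [], []
    adduct = "[M+H]+" if polarity == "positive" else "[M-H]-"

    rows = []
    for name, frac in species:
        sp = LipidSpecies.parse(name)
        rt = rng.uniform(1.0, GRADIENT_SPAN_MIN - 1.0)
        amp = MS1_BASE_INTENSITY * frac * (
            rng.lognormal(0.0, intensity_sigma) if intensity_sigma > 0 else 1.0)
        mz = precursor_mz(sp, adduct)
        rows.append((sp, name, frac, rt, amp, mz))

    # MS1: one peak per eluting species per scan
    scan_times = np.arange(0.5, GRADIENT_SPAN_MIN - 0.4, MS1_SCAN_STEP_MIN)
    scans = []
    for t in scan_times:
        peaks = []
        for sp, name, frac, rt, amp, mz in rows:
            inten = amp * np.exp(-0.5 * ((t - rt) / RT_SIGMA_MIN) ** 2)
            if inten < amp * 1e-4:
                continue
            obs_mz = mz * (1.0 + (rng.normal(0.0, ppm_jitter) * 1e-6
                                  if ppm_jitter > 0 else 0.0))
            peaks.append(Peak(obs_mz, float(inten)))
        scans.append(Ms1Scan(float(t), peaks))

    # MS2: abundance-ranked quartiles realize iterative exclusion
    ranked = sorted(rows, key=lambda r: -r[2])
    per_run = int(np.ceil(len(ranked) / N_EXCLUSION_RUNS))
    spectra = []
    for i, (sp, name, frac, rt, amp, mz) in enumerate(ranked):
        run = min(i // per_run + 1, N_EXCLUSION_RUNS)
        jit = lambda v, s: v * (1.0 + (rng.normal(0.0, s) * 1e-6 if s > 0 else 0.0))
        peaks = [Peak(jit(f.mz, ppm_jitter), float(rng.uniform(1e3, 1e5)))
                 for f in predict_fragments(sp, polarity, adduct)]
        lo = min(p.mz for p in peaks) - 50.0
        hi = mz + 50.0
        peaks += [Peak(float(rng.uniform(max(lo, 50.0), hi)),
                       float(rng.uniform(1e3, 1e5))) for _ in range(n_decoys)]
        spectra.append(Ms2Spectrum(
            precursor_mz=jit(mz, precursor_ppm_jitter),
            polarity=polarity,
            retention_time=rt,
            peaks=peaks,
            run_id=run,
            title=f"{name}|run{run}",
        ))
    return scans, spectra


# ---------------------------------------------------------------------------
# 31P NMR simulation
# ---------------------------------------------------------------------------

def simulate_nmr(
    truth: GroundTruth,
    snr: float,
    seed: int | None = None,
    n_points: int = 8192,
    sweep_ppm: float = 12.0,
    fwhm_range: tuple[float, float] = (0.02, 0.08),
    global_offset_ppm: float = 0.3,
    carrier_frequency: float = DEFAULT_CARRIER_MHZ,
) -> tuple[Fid, dict[str, float]]:
    """FID as a sum of damped cosinusoids, one per class, plus white noise.

    Component amplitudes equal class mole fractions, so spectral areas are
    proportional to them; linewidths are drawn uniformly from ``fwhm_range``
    (ppm) and a random global shift offset (absorbed later by calibration)
    displaces every line. ``snr`` is the ratio of the tallest noise-free
    spectral peak to the spectral noise standard deviation. Returns the FID
    and the true class fractions it encodes.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    fractions = _normalize({c: f for c, f in truth.class_fractions.items() if f > 0})
    sweep_hz = sweep_ppm * carrier_frequency
    dwell = 1.0 / sweep_hz
    t = np.arange(n_points) * dwell
    offset = rng.uniform(-global_offset_ppm, global_offset_ppm)

    fid = np.zeros(n_points, dtype=complex)
    for cls in sorted(fractions):
        shift_ppm = truth.nmr_shift_table[cls][0] + offset
        fwhm_ppm = rng.uniform(*fwhm_range)
        f_hz = shift_ppm * carrier_frequency
        rate = np.pi * fwhm_ppm * carrier_frequency
        fid += fractions[cls] * np.exp(2j * np.pi * f_hz * t - rate * t)

    if np.isfinite(snr):
        probe = fid.copy()
        probe[0] *= 0.5
        height = float(np.abs(np.fft.fft(probe)).max())
        sigma_t = height / (snr * np.sqrt(n_points))
        fid = fid + sigma_t * (rng.normal(size=n_points)
                               + 1j * rng.normal(size=n_points))
    return Fid(fid, dwell, carrier_frequency), fractions


def simulate_nmr_replicates(
    profile: str | dict,
    n_replicates: int,
    snr: float,
    seed: int,
    **nmr_kwargs,
) -> list[tuple[Fid, dict[str, float]]]:
    """Independent replicate samples: fresh lipidome draw + fresh FID each."""
    children = np.random.SeedSequence(seed).generate_state(n_replicates) % (2 ** 31)
    out = []
    for child in children:
        truth = generate_lipidome(profile, seed=int(child))
        out.append(simulate_nmr(truth, snr=snr, seed=int(child) + 1, **nmr_kwargs))
    return out


# ---------------------------------------------------------------------------
# BBB readings and DLS distributions
# ---------------------------------------------------------------------------

# Volume accounting mirroring the assay: aliquots read from pools, the basal
# pellet resuspended 5x concentrated.
DEFAULT_VOLUMES: dict[str, dict[str, float]] = {
    "apical_supernatant": {"sampled_volume": 200, "total_volume": 650},
    "apical_pellet": {"sampled_volume": 200, "total_volume": 400},
    "basal_supernatant": {"sampled_volume": 200, "total_volume": 1650},
    "basal_pellet": {"sampled_volume": 200, "total_volume": 1400,
                     "concentration_factor": 5},
    "cell_lysate": {"sampled_volume": 250, "total_volume": 250},
    "filter": {"sampled_volume": 250, "total_volume": 500},
}

_APICAL_SPLIT = 0.8   # fraction of the apical compartment in the supernatant
_BASAL_SPLIT = 0.7


def simulate_bbb_readings(
    partition: Sequence[float],
    volumes: Mapping[str, Mapping[str, float]] | None = None,
    seed: int | None = None,
    noise_sigma: float = 0.0,
    grand_total: float = 1000.0,
) -> FluorescenceReadings:
    """Back-compute plate readings from a known percentage partition.

    ``partition`` is (passed_filter, passed_bbb, retained_apical,
    retained_cells) summing to 100. Readings are constructed through the
    volume factors so that ``compartment_totals`` inverts them exactly;
    optional Gaussian read noise (relative sigma) is applied afterwards.
    """
    partition = [float(p) for p in partition]
    if len(partition) != 4 or any(p < 0 for p in partition):
        raise ValueError("partition must be four non-negative percentages")
    if abs(sum(partition) - 100.0) > 1e-6:
        raise ValueError("partition must sum to 100")
    volumes = volumes or DEFAULT_VOLUMES
    p_filter, p_bbb, p_apical, p_cells = partition
    totals = {
        "filter": p_filter,
        "basal_supernatant": p_bbb * _BASAL_SPLIT,
        "basal_pellet": p_bbb * (1 - _BASAL_SPLIT),
        "apical_supernatant": p_apical * _APICAL_SPLIT,
        "apical_pellet": p_apical * (1 - _APICAL_SPLIT),
        "cell_lysate": p_cells,
    }
    rng = np.random.default_rng(seed)
    kwargs = {}
    for name in COMPARTMENTS:
        v = dict(volumes[name])
        cf = float(v.get("concentration_factor", 1.0))
        total = totals[name] / 100.0 * grand_total
        reading = total * float(v["sampled_volume"]) * cf / float(v["total_volume"])
        if noise_sigma > 0:
            reading *= max(0.0, 1.0 + rng.normal(0.0, noise_sigma))
        kwargs[name] = CompartmentReading(
            reading=reading,
            sampled_volume=float(v["sampled_volume"]),
            total_volume=float(v["total_volume"]),
            concentration_factor=cf,
        )
    return FluorescenceReadings(**kwargs)


def simulate_dls(
    mean_hd: float = 68.8,
    pdi: float = 0.21,
    n_points: int = 200,
    diameter_range: tuple[float, float] = (10.0, 400.0),
):
    """Lognormal intensity-weighted size distribution with exact moments.

    The lognormal's relative variance is exp(sigma^2) - 1 = PDI, so the
    requested mean and PDI are recovered up to grid discretization.
    """
    from .bbb_dls import DlsDistribution

    if mean_hd <= 0 or pdi < 0:
        raise ValueError("mean_hd must be positive and pdi non-negative")
    d = np.linspace(*diameter_range, n_points)
    if pdi == 0:
        w = np.zeros_like(d)
        w[int(np.argmin(np.abs(d - mean_hd)))] = 1.0
        return DlsDistribution(d, w)
    sigma2 = np.log1p(pdi)
    mu = np.log(mean_hd) - sigma2 / 2.0
    w = np.exp(-((np.log(d) - mu) ** 2) / (2 * sigma2)) / d
    return DlsDistribution(d, w)
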