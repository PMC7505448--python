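"""MS2 lipid assignment with a hypergeometric match score.

Each candidate species within precursor tolerance is scored by the tail
probability of matching k of its T predicted fragments among the P observed
peaks purely by chance, when the spectrum's m/z span is discretized into N
tolerance-width bins:

    score = -log10 P(X >= k),   X ~ Hypergeometric(N, T, P)

A higher score means the observed co-occurrence of predicted fragments is
less likely under the random-matching null. Intensity is deliberately not
used (count-based formulation); peak intensities only matter for run
merging, where the richer spectrum wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf
from scipy.stats import hypergeom

from .lipid_library import (
    FragmentIon,
    LipidLibrary,
    LipidSpecies,
    adduct_polarity,
    precursor_mz,
    predict_fragments,
)

__all__ = [
    "Peak",
    "Ms2Spectrum",
    "MatchResult",
    "match_fragments",
    "hypergeometric_score",
    "assign_spectrum",
    "assign_spectra",
    "merge_iterative_runs",
    "review_table",
    "read_mgf",
    "write_mgf",
    "results_to_tsv",
    "DEFAULT_ADDUCTS",
]

DEFAULT_ADDUCTS = {
    "positive": ("[M+H]+",),
    "negative": ("[M-H]-", "[M+HCOO]-"),
}


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class Ms2Spectrum:
    """One product-ion spectrum; peaks are kept sorted by m/z."""

    precursor_mz: float
    polarity: str
    retention_time: float  # minutes
    peaks: list[Peak]
    run_id: int = 1
    title: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if not 0.0 <= self.retention_time <= 17.0:  # LC gradient span, minutes
            raise ValueError("retention time outside the 17-min gradient")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])


@dataclass
class MatchResult:
    """One candidate lipid scored against one spectrum."""

    species: LipidSpecies
    adduct: str
    n_theoretical: int
    n_matched: int
    matched_mz: list[float]
    score: float
    precursor_error_ppm: float = float("nan")
    spectrum_title: str = ""


def match_fragments(
    spectrum: Ms2Spectrum,
    fragment_list: Sequence[FragmentIon],
    tol_ppm: float,
) -> tuple[int, list[float]]:
    """Greedy nearest-m/z matching of predicted fragments to observed peaks.

    Each theoretical fragment consumes at most one peak and vice versa;
    fragments are processed in ascending m/z so the result is independent of
    the input ordering. Ties on |dm/z| go to the lower-m/z peak.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if not fragment_list or not spectrum.peaks:
        return 0, []
    peak_mz = spectrum.mz_array
    used = np.zeros(len(peak_mz), dtype=bool)
    matched: list[float] = []
    for frag in sorted(fragment_list, key=lambda f: f.mz):
        tol = frag.mz * tol_ppm * 1e-6
        lo = np.searchsorted(peak_mz, frag.mz - tol, side="left")
        hi = np.searchsorted(peak_mz, frag.mz + tol, side="right")
        best = -1
        best_d = math.inf
        for i in range(lo, hi):
            if used[i]:
                continue
            d = abs(peak_mz[i] - frag.mz)
            if d < best_d - 1e-15:
                best, best_d = i, d
        if best >= 0:
            used[best] = True
            matched.append(float(peak_mz[best]))
    return len(matched), matched


def hypergeometric_score(
    n_bins: int, n_theoretical: int, n_peaks: int, n_matched: int
) -> float:
    """-log10 of the hypergeometric upper tail P(X >= n_matched).

    Population n_bins, n_theoretical marked bins, n_peaks drawn; returns 0
    for n_matched = 0 (the null is certain to do at least that well).
    """
    if n_matched < 0 or n_matched > min(n_theoretical, n_peaks):
        raise ValueError("n_matched must lie in [0, min(n_theoretical, n_peaks)]")
    if n_theoretical > n_bins or n_peaks > n_bins:
        raise ValueError("counts cannot exceed the number of bins")
    if n_matched == 0:
        return 0.0
    tail = float(hypergeom.sf(n_matched - 1, n_bins, n_theoretical, n_peaks))
    if tail <= 0.0:  # beyond double-precision tail: fall back to log of the PMF sum
        logs = [
            hypergeom.logpmf(k, n_bins, n_theoretical, n_peaks)
            for k in range(n_matched, min(n_theoretical, n_peaks) + 1)
        ]
        m = max(logs)
        return float(-(m + math.log(sum(math.exp(v - m) for v in logs))) / math.log(10))
    return -math.log10(tail)


def _n_bins(spectrum: Ms2Spectrum, fragment_tol_ppm: float) -> int:
    """Discretize the spectrum span into 2*tolerance-wide bins at the midpoint."""
    mz = spectrum.mz_array
    span = float(mz.max() - mz.min()) if len(mz) > 1 else 0.0
    mid = float(mz.mean()) if len(mz) else 0.0
    width = 2.0 * mid * fragment_tol_ppm * 1e-6
    return int(span // width) if width > 0 and span > 0 else 1


def assign_spectrum(
    spectrum: Ms2Spectrum,
    library: LipidLibrary,
    precursor_tol_ppm: float = 10.0,
    fragment_tol_ppm: float = 20.0,
    min_score: float = 2.0,
    adducts: Sequence[str] | None = None,
) -> list[MatchResult]:
    """Score every polarity-compatible library candidate against a spectrum.

    Returns matches sorted by descending score (ties: smaller |precursor
    error|), with sub-threshold candidates dropped. An empty list means no
    candidate survived — not an error.
    """
    if len(library) == 0:
        raise ValueError("library is empty")
    if adducts is None:
        adducts = DEFAULT_ADDUCTS[spectrum.polarity]
    results: list[MatchResult] = []
    bins = _n_bins(spectrum, fragment_tol_ppm)
    n_peaks = len(spectrum.peaks)
    for adduct in adducts:
        if adduct_polarity(adduct) != spectrum.polarity:
            raise ValueError(f"adduct {adduct} incompatible with {spectrum.polarity} spectrum")
        for sp in library.candidates(spectrum.precursor_mz, adduct, precursor_tol_ppm):
            frags = predict_fragments(sp, spectrum.polarity, adduct)
            k, matched = match_fragments(spectrum, frags, fragment_tol_ppm)
            eff_bins = max(bins, len(frags), n_peaks, 1)
            score = hypergeometric_score(eff_bins, len(frags), n_peaks, k)
            err = (spectrum.precursor_mz - precursor_mz(sp, adduct)) \
                / precursor_mz(sp, adduct) * 1e6
            results.append(MatchResult(sp, adduct, len(frags), k, matched, score,
                                       err, spectrum.title))
    results = [r for r in results if r.score >= min_score]
    results.sort(key=lambda r: (-r.score, abs(r.precursor_error_ppm), r.species.name))
    return results


def assign_spectra(spectra: Iterable[Ms2Spectrum], library: LipidLibrary,
                   **kwargs) -> dict[str, list[MatchResult]]:
    """Assign a collection of spectra; keys are spectrum titles (or indices)."""
    out: dict[str, list[MatchResult]] = {}
    for i, spec in enumerate(spectra):
        key = spec.title or f"spectrum_{i}"
        out[key] = assign_spectrum(spec, library, **kwargs)
    return out


def merge_iterative_runs(
    runs: Sequence[Sequence[Ms2Spectrum]],
    precursor_tol_ppm: float = 5.0,
    rt_window: float = 0.2,
) -> list[Ms2Spectrum]:
    """Union of iterative-exclusion runs with duplicate precursors collapsed.

    Spectra agreeing in precursor m/z (ppm tolerance) and retention time
    (minutes window) are considered the same precursor; the spectrum with
    more peaks is kept. Idempotent.
    """
    if not runs:
        raise ValueError("at least one run is required")
    pool = [s for run in runs for s in run]
    pool.sort(key=lambda s: (-len(s.peaks), s.precursor_mz, s.retention_time, s.run_id))
    kept: list[Ms2Spectrum] = []
    for s in pool:
        dup = any(
            abs(s.precursor_mz - k.precursor_mz) <= k.precursor_mz * precursor_tol_ppm * 1e-6
            and abs(s.retention_time - k.retention_time) <= rt_window
            for k in kept
        )
        if not dup:
            kept.append(s)
    kept.sort(key=lambda s: (s.retention_time, s.precursor_mz))
    return kept


def review_table(assignments: dict[str, list[MatchResult]], top_n: int = 3) -> pd.DataFrame:
    """Manual-confirmation table: top candidates per spectrum with evidence."""
    rows = []
    for title, results in assignments.items():
        for rank, r in enumerate(results[:top_n], start=1):
            rows.append({
                "spectrum": title,
                "rank": rank,
                "species": r.species.name,
                "adduct": r.adduct,
                "score": r.score,
                "n_matched": r.n_matched,
                "n_theoretical": r.n_theoretical,
                "precursor_error_ppm": r.precursor_error_ppm,
                "matched_mz": ";".join(f"{m:.4f}" for m in r.matched_mz),
            })
    return pd.DataFrame(rows, columns=[
        "spectrum", "rank", "species", "adduct", "score", "n_matched",
        "n_theoretical", "precursor_error_ppm", "matched_mz"])


def results_to_tsv(assignments: dict[str, list[MatchResult]], path: str | Path) -> None:
    review_table(assignments, top_n=10 ** 9).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MGF I/O (pyteomics dialect: PEPMASS, RTINSECONDS, signed CHARGE)
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> list[Ms2Spectrum]:
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = params.get("charge", [1])[0]
            polarity = "negative" if int(charge) < 0 else "positive"
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            peaks = [Peak(float(m), float(i))
                     for m, i in zip(entry["m/z array"], entry["intensity array"])]
            spectra.append(Ms2Spectrum(
                precursor_mz=float(params["pepmass"][0]),
                polarity=polarity,
                retention_time=rt,
                peaks=peaks,
                run_id=int(params.get("run", 1)),
                title=str(params.get("title", "")),
            ))
    return spectra


def write_mgf(spectra: Sequence[Ms2Spectrum], path: str | Path) -> None:
    entries = []
    for i, s in enumerate(spectra):
        entries.append({
            "m/z array": np.array([p.mz for p in s.peaks]),
            "intensity array": np.array([p.intensity for p in s.peaks]),
            "params": {
                "title": s.title or f"spectrum_{i}",
                "pepmass": s.precursor_mz,
                "rtinseconds": s.retention_time * 60.0,
                "charge": 1 if s.polarity == "positive" else -1,
                "run": s.run_id,
            },
        })
    _mgf.write(entries, str(path), file_mode="w")
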