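"""MS1 chromatogram reconstruction and within-headgroup relative abundance.

Species identified at the MS2 level are quantified by reconstructing their
precursor extracted-ion chromatogram (XIC) from the MS1 scans around the
identifying spectrum's retention time and integrating it (trapezoid rule).
Abundances are reported relative to the other species sharing the same
headgroup — never across headgroups, since no internal standards are used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .lipid_library import LipidSpecies, headgroup, precursor_mz
from .ms2_assignment import MatchResult, Peak

__all__ = [
    "Ms1Scan",
    "Xic",
    "reconstruct_xic",
    "quantify_assignments",
    "class_relative_abundance",
    "replicate_summary",
    "read_ms1_csv",
    "write_ms1_csv",
]

logger = logging.getLogger(__name__)

DEFAULT_RT_HALFWIDTH = 0.5  # minutes around the assigning MS2 spectrum


@dataclass
class Ms1Scan:
    """One MS1 scan: retention time (minutes) and its centroided peak list."""

    retention_time: float
    peaks: list[Peak]

    def __post_init__(self) -> None:
        if self.retention_time < 0:
            raise ValueError("retention time must be non-negative")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)


@dataclass
class Xic:
    """Extracted-ion chromatogram for one species/adduct."""

    species: LipidSpecies | None
    adduct: str | None
    points: list[tuple[float, float]]  # (retention time, summed intensity)
    area: float


def reconstruct_xic(
    scans: Sequence[Ms1Scan],
    target_mz: float,
    tol_ppm: float,
    rt_window: tuple[float, float],
    species: LipidSpecies | None = None,
    adduct: str | None = None,
) -> Xic:
    """One XIC point per scan inside the window; area by trapezoid rule.

    A scan contributes the summed intensity of its peaks within +-tol_ppm of
    target_mz, or 0 if none fall inside.
    """
    if not scans:
        raise ValueError("empty scan list")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    lo, hi = rt_window
    tol = target_mz * tol_ppm * 1e-6
    pts: list[tuple[float, float]] = []
    for scan in sorted(scans, key=lambda s: s.retention_time):
        if not (lo <= scan.retention_time <= hi):
            continue
        mz = np.array([p.mz for p in scan.peaks])
        inten = np.array([p.intensity for p in scan.peaks])
        if len(mz):
            mask = np.abs(mz - target_mz) <= tol
            total = float(inten[mask].sum())
        else:
            total = 0.0
        pts.append((scan.retention_time, total))
    if pts:
        t = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        area = float(np.trapezoid(y, t))
    else:
        area = 0.0
    return Xic(species, adduct, pts, area)


def quantify_assignments(
    scans: Sequence[Ms1Scan],
    assignments: dict[str, list[MatchResult]],
    spectrum_rts: dict[str, float],
    replicate_id: int = 1,
    tol_ppm: float = 10.0,
    rt_halfwidth: float = DEFAULT_RT_HALFWIDTH,
) -> pd.DataFrame:
    """Integrate one XIC per top-ranked assignment.

    ``spectrum_rts`` maps spectrum titles to the MS2 retention time used to
    center the XIC window. Duplicate species (several spectra assigned to the
    same lipid) keep the largest area.
    """
    rows = []
    for title, results in assignments.items():
        if not results:
            continue
        top = results[0]
        rt = spectrum_rts[title]
        mz = precursor_mz(top.species, top.adduct)
        xic = reconstruct_xic(scans, mz, tol_ppm,
                              (rt - rt_halfwidth, rt + rt_halfwidth),
                              species=top.species, adduct=top.adduct)
        rows.append({
            "headgroup": headgroup(top.species.lipid_class),
            "lipid_class": top.species.lipid_class,
            "species": top.species.name,
            "replicate": replicate_id,
            "rt": rt,
            "area": xic.area,
        })
    df = pd.DataFrame(rows, columns=["headgroup", "lipid_class", "species",
                                     "replicate", "rt", "area"])
    if len(df):
        df = (df.sort_values("area", ascending=False)
                .drop_duplicates(["species", "replicate"])
                .reset_index(drop=True))
    return df


def class_relative_abundance(areas: pd.DataFrame) -> pd.DataFrame:
    """Within-headgroup relative abundances per replicate.

    Input columns: headgroup, species, replicate, area (>= 0). Output adds
    ``relative_abundance`` with fractions summing to 1 within each
    (headgroup, replicate); headgroups with zero total area are excluded
    with a warning.
    """
    if (areas["area"] < 0).any():
        raise ValueError("areas must be non-negative")
    out = []
    for (grp, rep), sub in areas.groupby(["headgroup", "replicate"], sort=True):
        total = sub["area"].sum()
        if total <= 0:
            logger.warning("headgroup %s replicate %s has zero total area; excluded",
                           grp, rep)
            continue
        sub = sub.copy()
        sub["relative_abundance"] = sub["area"] / total
        out.append(sub)
    if not out:
        return areas.iloc[0:0].assign(relative_abundance=pd.Series(dtype=float))
    return pd.concat(out, ignore_index=True)


def replicate_summary(composition: pd.DataFrame) -> pd.DataFrame:
    """Tukey box-plot statistics per (headgroup, species) across replicates.

    Quartiles use linear interpolation; whiskers reach the most extreme
    replicate within 1.5 x IQR of the box; points beyond are outliers.
    """
    rows = []
    for (grp, sp), sub in composition.groupby(["headgroup", "species"], sort=True):
        v = np.sort(sub["relative_abundance"].to_numpy(dtype=float))
        q25, med, q75 = np.percentile(v, [25, 50, 75])
        iqr = q75 - q25
        lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        outliers = v[(v < lo_fence) | (v > hi_fence)]
        rows.append({
            "headgroup": grp,
            "species": sp,
            "n": len(v),
            "median": med,
            "q25": q25,
            "q75": q75,
            "whisker_lo": inside.min() if len(inside) else np.nan,
            "whisker_hi": inside.max() if len(inside) else np.nan,
            "outliers": list(outliers),
        })
    return pd.DataFrame(rows, columns=["headgroup", "species", "n", "median",
                                       "q25", "q75", "whisker_lo", "whisker_hi",
                                       "outliers"])


# ---------------------------------------------------------------------------
# CSV I/O: long table (scan_rt, mz, intensity)
# ---------------------------------------------------------------------------

def read_ms1_csv(path: str | Path) -> list[Ms1Scan]:
    df = pd.read_csv(path)
    scans = []
    for rt, sub in df.groupby("scan_rt", sort=True):
        peaks = [Peak(m, i) for m, i in zip(sub["mz"], sub["intensity"])]
        scans.append(Ms1Scan(float(rt), peaks))
    return scans


def write_ms1_csv(scans: Sequence[Ms1Scan], path: str | Path) -> None:
    rows = [{"scan_rt": s.retention_time, "mz": p.mz, "intensity": p.intensity}
            for s in scans for p in s.peaks]
    pd.DataFrame(rows, columns=["scan_rt", "mz", "intensity"]).to_csv(path, index=False)
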