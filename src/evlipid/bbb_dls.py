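"""Transwell BBB permeability accounting, DLS summary statistics, fold changes.

The permeability assay partitions a fixed amount of fluorescent tracer
between four fates: passed the bare transwell filter, passed the full
endothelial barrier, retained on the apical side, and retained inside the
endothelial cells. Each compartment is sampled (an aliquot of a known pool
volume, possibly concentrated), so readings are first scaled back to
compartment totals, then normalized to percentages of the grand total
(total fluorescence = 100%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompartmentReading",
    "FluorescenceReadings",
    "PermeabilityResult",
    "DlsDistribution",
    "compartment_totals",
    "permeability_percentages",
    "dls_summary",
    "fold_change",
    "read_readings_csv",
    "write_readings_csv",
    "read_dls_csv",
    "write_dls_csv",
    "COMPARTMENTS",
]

COMPARTMENTS = ("apical_supernatant", "apical_pellet", "basal_supernatant",
                "basal_pellet", "cell_lysate", "filter")


@dataclass(frozen=True)
class CompartmentReading:
    """One plate reading with its volume accounting.

    ``reading`` was measured on ``sampled_volume`` uL drawn from a pool of
    ``total_volume`` uL; ``concentration_factor`` > 1 means the pool was
    concentrated by that factor before sampling (e.g. a pellet from 1400 uL
    resuspended in 280 uL is 5x concentrated: give total_volume=1400,
    concentration_factor=5).
    """

    reading: float
    sampled_volume: float
    total_volume: float
    concentration_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.reading < 0:
            raise ValueError("readings must be non-negative")
        if self.sampled_volume <= 0:
            raise ValueError("sampled volume must be positive")
        if self.concentration_factor <= 0:
            raise ValueError("concentration factor must be positive")
        if self.sampled_volume > self.total_volume / self.concentration_factor + 1e-9:
            raise ValueError("cannot sample more than the (concentrated) pool volume")

    @property
    def total(self) -> float:
        """Total fluorescence in the compartment."""
        return self.reading * (self.total_volume / self.sampled_volume) \
            / self.concentration_factor


@dataclass
class FluorescenceReadings:
    """Readings for all six sampled compartments."""

    apical_supernatant: CompartmentReading
    apical_pellet: CompartmentReading
    basal_supernatant: CompartmentReading
    basal_pellet: CompartmentReading
    cell_lysate: CompartmentReading
    filter: CompartmentReading


@dataclass(frozen=True)
class PermeabilityResult:
    """Four-way percentage partition of the tracer; sums to 100."""

    pct_passed_filter: float
    pct_passed_bbb: float
    pct_retained_apical: float
    pct_retained_cells: float

    def as_dict(self) -> dict[str, float]:
        return {
            "pct_passed_filter": self.pct_passed_filter,
            "pct_passed_bbb": self.pct_passed_bbb,
            "pct_retained_apical": self.pct_retained_apical,
            "pct_retained_cells": self.pct_retained_cells,
        }


def compartment_totals(readings: FluorescenceReadings) -> dict[str, float]:
    """Scale each reading back to its compartment's total fluorescence."""
    return {name: getattr(readings, name).total for name in COMPARTMENTS}


def permeability_percentages(totals: Mapping[str, float]) -> PermeabilityResult:
    """Normalize compartment totals to the Table-style percentage partition.

    Apical supernatant + pellet pool into 'retained apical'; basal
    supernatant + pellet into 'passed BBB'; the cell lysate is 'retained in
    cells' and the filter compartment is 'passed filter'.
    """
    if any(v < 0 for v in totals.values()):
        raise ValueError("compartment totals must be non-negative")
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("total fluorescence is zero; nothing to partition")
    apical = totals["apical_supernatant"] + totals["apical_pellet"]
    basal = totals["basal_supernatant"] + totals["basal_pellet"]
    return PermeabilityResult(
        pct_passed_filter=100.0 * totals["filter"] / grand,
        pct_passed_bbb=100.0 * basal / grand,
        pct_retained_apical=100.0 * apical / grand,
        pct_retained_cells=100.0 * totals["cell_lysate"] / grand,
    )


@dataclass
class DlsDistribution:
    """Intensity-weighted hydrodynamic-diameter distribution."""

    diameters: np.ndarray  # nm
    intensity: np.ndarray  # weights >= 0

    def __post_init__(self) -> None:
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.diameters.shape != self.intensity.shape:
            raise ValueError("diameters and intensity must have equal length")
        if (self.intensity < 0).any():
            raise ValueError("intensity weights must be non-negative")
        if self.intensity.sum() <= 0:
            raise ValueError("total intensity must be positive")


def dls_summary(distribution: DlsDistribution) -> dict[str, float]:
    """Intensity-weighted mean hydrodynamic diameter and polydispersity index.

    mean_hd = sum(w*d)/sum(w); PDI = weighted variance / mean_hd**2
    (relative-variance convention; 0 iff the distribution is a point mass).
    """
    w = distribution.intensity
    d = distribution.diameters
    mean = float(np.average(d, weights=w))
    var = float(np.average((d - mean) ** 2, weights=w))
    return {"mean_hd": mean, "pdi": var / mean ** 2}


def fold_change(value_before: float, value_after: float) -> float:
    """Ratio before/after (e.g. A280 drop across the isolation step)."""
    if value_after <= 0:
        raise ValueError("denominator must be positive")
    return value_before / value_after


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_readings_csv(readings: FluorescenceReadings, path: str | Path) -> None:
    rows = []
    for name in COMPARTMENTS:
        r = getattr(readings, name)
        rows.append({"compartment": name, "reading": r.reading,
                     "sampled_volume": r.sampled_volume,
                     "total_volume": r.total_volume,
                     "concentration_factor": r.concentration_factor})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_readings_csv(path: str | Path) -> FluorescenceReadings:
    df = pd.read_csv(path).set_index("compartment")
    kwargs = {}
    for name in COMPARTMENTS:
        row = df.loc[name]
        kwargs[name] = CompartmentReading(
            reading=float(row["reading"]),
            sampled_volume=float(row["sampled_volume"]),
            total_volume=float(row["total_volume"]),
            concentration_factor=float(row.get("concentration_factor", 1.0)),
        )
    return FluorescenceReadings(**kwargs)


def write_dls_csv(distribution: DlsDistribution, path: str | Path) -> None:
    pd.DataFrame({"diameter_nm": distribution.diameters,
                  "intensity": distribution.intensity}).to_csv(path, index=False)


def read_dls_csv(path: str | Path) -> DlsDistribution:
    df = pd.read_csv(path)
    return DlsDistribution(df["diameter_nm"].to_numpy(), df["intensity"].to_numpy())
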