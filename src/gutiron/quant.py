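"""Calibration-curve quantification of iron and porphyrins.

Two instrument channels are supported:

* atomic absorption (AA) for total iron — calibration standards in ppm
  (µg Fe/mL), signal in absorbance units;
* LC-Q-TOF-MS for heme (m/z 616.17) and protoporphyrin IX (m/z 563.26) —
  calibration standards in µM, signal in integrated extracted-ion-
  chromatogram (EIC) peak area (counts·min).

Raw signals are converted with a linear standard curve, corrected for
dilution and extraction volumes, and expressed first per mL of culture
(nmol/mL) and then per µg of genomic DNA (pmol/µg), the cell-count
surrogate used for all reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "IRON_MOLAR_MASS",
    "HEME_MZ",
    "PPIX_MZ",
    "PPIX_FRAGMENT_MZ",
    "LOD_UM",
    "CalibrationPoint",
    "CalibrationCurve",
    "Scan",
    "Chromatogram",
    "EICTrace",
    "AnalyteMeasurement",
    "fit_calibration",
    "extract_eic",
    "integrate_peak",
    "signal_to_concentration",
    "normalize_to_dna",
]

IRON_MOLAR_MASS = 55.845  # g/mol
HEME_MZ = 616.17  # [M+H]+ of heme b
PPIX_MZ = 563.26  # [M+H]+ of protoporphyrin IX
PPIX_FRAGMENT_MZ = 282.13  # confirmatory fragment, recorded as annotation only
LOD_UM = 0.25  # limit of detection, µM per injection


@dataclass(frozen=True)
class CalibrationPoint:
    """One standard: known concentration level and measured signal."""

    level: float  # ppm for AA, µM for porphyrins
    signal: float

    def __post_init__(self) -> None:
        if self.level < 0:
            raise ValueError(f"standard level must be non-negative, got {self.level}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear standard curve signal = slope·level + intercept."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    valid_range: tuple[float, float]
    level_unit: str = "uM"  # "uM" or "ppm"

    def __post_init__(self) -> None:
        if not (self.slope > 0):
            raise ValueError(f"calibration slope must be positive, got {self.slope}")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


@dataclass
class Scan:
    """One MS scan: acquisition time plus paired m/z and intensity arrays."""

    time: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class Chromatogram:
    """A dense sequence of scans on a strictly increasing time grid."""

    scans: list[Scan]

    def __post_init__(self) -> None:
        times = self.times
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("scan times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.scans], dtype=float)

    def __len__(self) -> int:
        return len(self.scans)


@dataclass
class EICTrace:
    """Extracted ion chromatogram: per-scan summed intensity in an m/z window."""

    target_mz: float
    tolerance: float
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class AnalyteMeasurement:
    """One analyte's concentration per mL culture, optionally per µg DNA."""

    analyte: str  # total_iron | heme | ppix
    conc_per_culture: float  # nmol/mL culture
    dilution_factor: float
    culture_volume_ml: float
    below_lod: bool = False
    conc_per_dna: Optional[float] = field(default=None)  # pmol/µg DNA


def fit_calibration(
    points: Sequence[CalibrationPoint], analyte: str, level_unit: str = "uM"
) -> CalibrationCurve:
    """Least-squares linear standard curve over ≥ 3 distinct levels.

    Warns (does not fail) when R² < 0.99 or when the intercept exceeds
    5 % of the maximum signal — both signs of a degraded standard series.
    """
    levels = np.array([p.level for p in points], dtype=float)
    signals = np.array([p.signal for p in points], dtype=float)
    if len(set(levels.tolist())) < 3:
        raise ValueError(f"need at least 3 distinct standard levels, got {levels!r}")
    out = stats.linregress(levels, signals)
    r2 = float(out.rvalue**2)
    if r2 < 0.99:
        warnings.warn(
            f"{analyte} calibration R² = {r2:.4f} < 0.99", stacklevel=2
        )
    max_sig = float(np.max(np.abs(signals)))
    if max_sig > 0 and abs(out.intercept) > 0.05 * max_sig:
        warnings.warn(
            f"{analyte} calibration intercept {out.intercept:.4g} exceeds "
            f"5 % of the maximum signal",
            stacklevel=2,
        )
    return CalibrationCurve(
        analyte=analyte,
        slope=float(out.slope),
        intercept=float(out.intercept),
        r_squared=min(r2, 1.0),
        valid_range=(float(levels.min()), float(levels.max())),
        level_unit=level_unit,
    )


def extract_eic(chrom: Chromatogram, target_mz: float, tolerance: float = 0.02) -> EICTrace:
    """Sum, per scan, all intensities with \\|m/z − target\\| ≤ tolerance."""
    if tolerance <= 0:
        raise ValueError(f"m/z tolerance must be positive, got {tolerance}")
    if len(chrom) == 0:
        raise ValueError("cannot extract an EIC from an empty chromatogram")
    intens = np.empty(len(chrom))
    for i, scan in enumerate(chrom.scans):
        sel = np.abs(scan.mz - target_mz) <= tolerance
        intens[i] = float(scan.intensity[sel].sum())
    return EICTrace(
        target_mz=target_mz, tolerance=tolerance, times=chrom.times, intensities=intens
    )


def integrate_peak(trace: EICTrace, window: tuple[float, float]) -> float:
    """Trapezoidal EIC peak area (counts·min) after baseline subtraction.

    The baseline is the median intensity outside the integration window
    (constant model); on baseline-free synthetic traces this subtraction
    is a no-op.
    """
    t_start, t_end = window
    if t_end <= t_start:
        raise ValueError(f"empty integration window {window!r}")
    if t_start < trace.times[0] or t_end > trace.times[-1]:
        raise ValueError(
            f"window {window!r} outside trace time range "
            f"[{trace.times[0]}, {trace.times[-1]}]"
        )
    inside = (trace.times >= t_start) & (trace.times <= t_end)
    if not np.any(inside):
        raise ValueError(f"no scans fall inside window {window!r}")
    outside = ~inside
    baseline = float(np.median(trace.intensities[outside])) if np.any(outside) else 0.0
    y = trace.intensities[inside] - baseline
    return float(np.trapezoid(y, trace.times[inside]))


def signal_to_concentration(
    signal: float,
    curve: CalibrationCurve,
    dilution_factor: float,
    culture_volume_ml: float,
    *,
    extract_volume_ml: float = 1.0,
    lod_um: float = LOD_UM,
    molar_mass_g_mol: float = IRON_MOLAR_MASS,
) -> AnalyteMeasurement:
    """Convert a raw signal to nmol analyte per mL of original culture.

    The calibration gives the concentration in the injected (diluted)
    solution; multiplying by the dilution factor recovers the extract
    concentration, and the extract-to-culture volume ratio maps that back
    onto the culture.  ppm-calibrated channels (AA iron) are converted to
    µM via the analyte molar mass before volume bookkeeping.  Injected
    concentrations below ``lod_um`` are flagged ``below_lod`` (the value
    is still reported, not zeroed).
    """
    if signal < 0:
        raise ValueError(f"signal must be non-negative, got {signal}")
    if dilution_factor < 1:
        raise ValueError(f"dilution factor must be ≥ 1, got {dilution_factor}")
    if culture_volume_ml <= 0 or extract_volume_ml <= 0:
        raise ValueError("volumes must be positive")
    measured = (signal - curve.intercept) / curve.slope  # in curve.level_unit
    if curve.level_unit == "ppm":
        measured_um = measured * 1000.0 / molar_mass_g_mol  # µg/mL → µmol/L
    elif curve.level_unit == "uM":
        measured_um = measured
    else:
        raise ValueError(f"unknown calibration unit {curve.level_unit!r}")
    measured_um = max(measured_um, 0.0)
    below = measured_um < lod_um
    conc = measured_um * dilution_factor * extract_volume_ml / culture_volume_ml
    return AnalyteMeasurement(
        analyte=curve.analyte,
        conc_per_culture=conc,
        dilution_factor=dilution_factor,
        culture_volume_ml=culture_volume_ml,
        below_lod=below,
    )


def normalize_to_dna(conc_per_culture: float, dna_conc_ug_per_ml: float) -> float:
    """nmol·mL⁻¹ culture → pmol per µg of DNA extracted from that culture."""
    if not (dna_conc_ug_per_ml > 0):
        raise ValueError(f"DNA concentration must be positive, got {dna_conc_ug_per_ml}")
    if conc_per_culture < 0:
        raise ValueError("concentration must be non-negative")
    return conc_per_culture * 1000.0 / dna_conc_ug_per_ml
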