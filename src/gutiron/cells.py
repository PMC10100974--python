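"""Genome-based cell accounting: DNA mass per cell, cells per µg DNA,
OD-to-quantity conversions, and the heme fraction of total iron.

DNA concentration is used throughout as a surrogate for CFU counts: the
mass of one chromosome equivalent follows from the genome size (6.26 Mbp
for *B. thetaiotaomicron* VPI 5482) and the average mass of a double-
stranded base pair, so a µg of genomic DNA maps onto a definite number of
cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from scipy.constants import Avogadro

from .growth import ConversionFactors

__all__ = [
    "CellModel",
    "Quantities",
    "dna_mass_per_cell",
    "cells_per_microgram",
    "od_to_quantities",
    "heme_fraction",
    "rate_to_cells",
    "BP_MASS_G_PER_MOL",
    "BT_GENOME_BP",
]

#: Average molar mass of one double-stranded base pair (g/mol, sodium-free).
BP_MASS_G_PER_MOL = 650.0

#: Genome size of Bacteroides thetaiotaomicron VPI 5482 (bp).
BT_GENOME_BP = 6.26e6


def dna_mass_per_cell(genome_bp: float, bp_mass: float = BP_MASS_G_PER_MOL) -> float:
    """Mass of one chromosome equivalent in femtograms.

    genome_bp × bp_mass / N_A, converted g → fg.  For the 6.26-Mbp
    *B. thetaiotaomicron* genome this is 6.76 fg.
    """
    if not (genome_bp > 0):
        raise ValueError(f"genome size must be positive, got {genome_bp}")
    if not (bp_mass > 0):
        raise ValueError(f"base-pair mass must be positive, got {bp_mass}")
    return genome_bp * bp_mass / Avogadro * 1e15


def cells_per_microgram(dna_per_cell_fg: float) -> float:
    """Number of cells holding 1 µg of genomic DNA (10⁹ fg / fg-per-cell)."""
    if not (dna_per_cell_fg > 0):
        raise ValueError(f"DNA mass per cell must be positive, got {dna_per_cell_fg}")
    return 1e9 / dna_per_cell_fg


@dataclass(frozen=True)
class CellModel:
    """Genome-derived per-cell DNA accounting."""

    genome_bp: float = BT_GENOME_BP
    bp_mass: float = BP_MASS_G_PER_MOL

    @property
    def dna_per_cell_fg(self) -> float:
        return dna_mass_per_cell(self.genome_bp, self.bp_mass)

    @property
    def cells_per_ug(self) -> float:
        return cells_per_microgram(self.dna_per_cell_fg)

    def conversion_factors(self, dna_per_od: float, pellet_per_od: float) -> ConversionFactors:
        """Build OD conversion factors with cells_per_od = dna_per_od × cells/µg."""
        return ConversionFactors(
            dna_per_od=dna_per_od,
            pellet_per_od=pellet_per_od,
            cells_per_od=dna_per_od * self.cells_per_ug,
        )


class Quantities(NamedTuple):
    dna_ug_per_ml: float
    cells_per_ml: float
    pellet_mg_per_ml: float


def od_to_quantities(od: float, factors: ConversionFactors, model: CellModel) -> Quantities:
    """Convert an OD600 reading to DNA, cell and wet-pellet densities.

    DNA and pellet scale linearly with OD; cells are derived from the DNA
    amount via the genome model (cells = µg DNA × cells/µg).
    """
    if od < 0:
        raise ValueError(f"OD must be non-negative, got {od}")
    dna = od * factors.dna_per_od
    return Quantities(
        dna_ug_per_ml=dna,
        cells_per_ml=dna * model.cells_per_ug,
        pellet_mg_per_ml=od * factors.pellet_per_od,
    )


def heme_fraction(heme_pmol_per_ug: float, total_fe_pmol_per_ug: float) -> float:
    """Percentage of cellular iron present as heme, to 3 significant figures.

    A 5 % overshoot of heme above total iron is tolerated (measurement
    noise on two independent assays); anything larger is rejected.
    """
    if not (total_fe_pmol_per_ug > 0):
        raise ValueError("total iron must be positive")
    if heme_pmol_per_ug < 0:
        raise ValueError("heme must be non-negative")
    if heme_pmol_per_ug > total_fe_pmol_per_ug * 1.05:
        raise ValueError(
            f"heme ({heme_pmol_per_ug}) exceeds total iron "
            f"({total_fe_pmol_per_ug}) beyond the 5 % noise tolerance"
        )
    frac = 100.0 * heme_pmol_per_ug / total_fe_pmol_per_ug
    if frac == 0.0:
        return 0.0
    return float(f"{frac:.3g}")


def rate_to_cells(mu_m: float, factors: ConversionFactors) -> float:
    """Convert a maximum growth rate in au/h to cells·mL⁻¹·h⁻¹."""
    if mu_m < 0:
        raise ValueError(f"growth rate must be non-negative, got {mu_m}")
    return mu_m * factors.cells_per_od
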