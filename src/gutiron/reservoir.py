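"""Whole-microbiome iron reservoir extrapolation.

Per-µg-DNA metabolite loads measured in saturated *B. thetaiotaomicron*
cultures are scaled to a hypothetical human GI-tract microbiome composed
entirely of that species: ~3.8 × 10¹³ cells, each carrying one 6.26-Mbp
chromosome equivalent of DNA, for a community wet mass near 200 g.

The heme column is reported as the iron-equivalent mass of the heme pool
(one Fe atom per heme, M = 55.845 g/mol), not as the mass of the hemin
complex — this is the convention under which the per-condition heme
masses are directly comparable with (and bounded by) the total-iron
masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .cells import CellModel
from .quant import IRON_MOLAR_MASS

__all__ = [
    "MicrobiomeModel",
    "ReservoirEstimate",
    "total_microbiome_dna",
    "extrapolate_iron",
    "extrapolate_heme_iron",
    "buffer_days",
    "reservoir_table",
]


@dataclass(frozen=True)
class MicrobiomeModel:
    """Size model of a reference-human GI-tract microbiome.

    Defaults: 3.8 × 10¹³ cells at 5 pg wet mass each (≈ 200 g total),
    with DNA content per cell taken from the genome model.
    """

    n_cells: float = 3.8e13
    cell_mass_pg: float = 5.0
    cell_model: CellModel = field(default_factory=CellModel)

    def __post_init__(self) -> None:
        if not (self.n_cells > 0):
            raise ValueError(f"cell count must be positive, got {self.n_cells}")
        if not (self.cell_mass_pg > 0):
            raise ValueError(f"cell mass must be positive, got {self.cell_mass_pg}")

    @property
    def total_mass_g(self) -> float:
        return self.n_cells * self.cell_mass_pg * 1e-12


@dataclass(frozen=True)
class ReservoirEstimate:
    """Extrapolated iron pools for one growth condition."""

    condition: str
    total_iron_mg: float
    heme_iron_mg: float
    total_dna_ug: float
    total_iron_sd_mg: Optional[float] = None
    heme_iron_sd_mg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.total_iron_mg < 0 or self.heme_iron_mg < 0 or self.total_dna_ug < 0:
            raise ValueError("reservoir masses must be non-negative")
        if self.heme_iron_mg > self.total_iron_mg * 1.05:
            raise ValueError("heme iron exceeds total iron beyond the 5 % tolerance")


def total_microbiome_dna(model: MicrobiomeModel) -> float:
    """Total genomic DNA in the microbiome, in µg (cells × fg/cell × 10⁻⁹)."""
    return model.n_cells * model.cell_model.dna_per_cell_fg * 1e-9


def extrapolate_iron(
    pmol_per_ug: float, model: MicrobiomeModel, molar_mass: float = IRON_MOLAR_MASS
) -> float:
    """Scale a per-µg-DNA load (pmol/µg) to whole-microbiome milligrams.

    pmol/µg × total µg DNA gives pmol of analyte; × molar mass and
    pmol→mmol conversion yields mg.
    """
    if pmol_per_ug < 0:
        raise ValueError(f"per-DNA load must be non-negative, got {pmol_per_ug}")
    return pmol_per_ug * total_microbiome_dna(model) * molar_mass * 1e-9


def extrapolate_heme_iron(heme_pmol_per_ug: float, model: MicrobiomeModel) -> float:
    """Iron-equivalent mass (mg) of the microbiome heme pool (1 Fe per heme)."""
    return extrapolate_iron(heme_pmol_per_ug, model, molar_mass=IRON_MOLAR_MASS)


def buffer_days(
    total_iron_mg: float, daily_absorption_mg: tuple[float, float] = (1.0, 3.0)
) -> tuple[float, float]:
    """Days of host iron absorption the reservoir could cover (min, max).

    A human absorbs roughly 1–3 mg iron per day; the reservoir divided by
    the fast and slow absorption rates brackets the buffer window.
    """
    lo, hi = sorted(daily_absorption_mg)
    if lo <= 0:
        raise ValueError("daily absorption rates must be positive")
    if total_iron_mg < 0:
        raise ValueError("total iron must be non-negative")
    return total_iron_mg / hi, total_iron_mg / lo


def reservoir_table(
    measurements: Sequence[dict], model: Optional[MicrobiomeModel] = None
) -> pd.DataFrame:
    """Build a per-condition reservoir table from per-µg-DNA measurements.

    Each measurement dict needs ``condition``, ``total_fe_pmol_per_ug`` and
    ``heme_pmol_per_ug``; optional ``total_fe_sd`` / ``heme_sd`` columns are
    propagated by the same linear scaling as the means.
    """
    model = model or MicrobiomeModel()
    rows = []
    for m in measurements:
        est = ReservoirEstimate(
            condition=str(m["condition"]),
            total_iron_mg=extrapolate_iron(float(m["total_fe_pmol_per_ug"]), model),
            heme_iron_mg=extrapolate_heme_iron(float(m["heme_pmol_per_ug"]), model),
            total_dna_ug=total_microbiome_dna(model),
            total_iron_sd_mg=(
                extrapolate_iron(float(m["total_fe_sd"]), model)
                if m.get("total_fe_sd") is not None
                else None
            ),
            heme_iron_sd_mg=(
                extrapolate_heme_iron(float(m["heme_sd"]), model)
                if m.get("heme_sd") is not None
                else None
            ),
        )
        rows.append(
            {
                "condition": est.condition,
                "total_iron_mg": est.total_iron_mg,
                "total_iron_sd_mg": est.total_iron_sd_mg,
                "heme_iron_mg": est.heme_iron_mg,
                "heme_iron_sd_mg": est.heme_iron_sd_mg,
            }
        )
    return pd.DataFrame(rows)
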