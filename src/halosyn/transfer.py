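"""Interspecies H2 transfer: diffusive flux, maximum transfer distance, cell spacing.

A fermenting (hydrogenogenic) cell and a dechlorinating cell exchange H2 by
molecular diffusion.  At steady state the per-cell H2 flux J (mol/s) over a
distance d between the partners satisfies

    J = A_syn * D_H2 * (C_syn - C_cons) / d

where A_syn is the syntroph surface area, D_H2 the aqueous diffusivity of H2
and C_syn, C_cons the dissolved H2 concentrations at the two cell surfaces
(bounded by the thermodynamic ceiling and floor of the syntrophic window).
Solving for d at the observed per-cell H2 demand gives the maximum spacing
that can sustain the observed dechlorination rate, to be compared with the
mean nearest-neighbour distance of randomly dispersed cells, (1/N)^(1/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CellGeometry",
    "PopulationState",
    "TransferProblem",
    "mean_cell_spacing",
    "percell_h2_demand",
    "max_interspecies_distance",
    "proximity_assessment",
]

SECONDS_PER_DAY = 86400.0


class TransferError(ValueError):
    """Raised for invalid geometries, densities or infeasible transfer problems."""


@dataclass(frozen=True)
class CellGeometry:
    """Cell shape and size; surface area derived unless overridden.

    ``diameter`` and ``length`` are in μm.  A rod is modelled as a cylinder
    with hemispherical caps (total length = ``length``); a sphere uses
    ``diameter`` only.
    """

    shape: str = "rod"
    diameter: float = 0.5
    length: float = 2.0
    surface_area_um2: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "rod"):
            raise TransferError(f"unknown cell shape {self.shape!r}")
        if self.diameter <= 0:
            raise TransferError("cell diameter must be positive")
        if self.shape == "rod" and self.length <= self.diameter:
            raise TransferError("rod length must exceed its diameter")

    @property
    def area_um2(self) -> float:
        """Surface area in μm²."""
        if self.surface_area_um2 is not None:
            return self.surface_area_um2
        r = self.diameter / 2.0
        if self.shape == "sphere":
            return 4.0 * math.pi * r * r
        # cylinder of length (L - 2r) plus two hemispherical caps
        return 2.0 * math.pi * r * (self.length - 2.0 * r) + 4.0 * math.pi * r * r


@dataclass
class PopulationState:
    """Cell densities (cells/mL) of the two partners plus syntroph geometry."""

    total_density: float
    syntroph_density: float
    dechlorinator_density: float
    syntroph_geometry: CellGeometry = CellGeometry()

    def __post_init__(self) -> None:
        for v in (self.total_density, self.syntroph_density, self.dechlorinator_density):
            if v < 0:
                raise TransferError("cell densities must be nonnegative")
        if self.syntroph_density + self.dechlorinator_density > self.total_density * (1 + 1e-9):
            raise TransferError("partner densities exceed the total density")


@dataclass
class TransferProblem:
    """Inputs of the diffusive-transfer distance calculation.

    J_h2_mol_s : per-cell H2 flux demand, mol/s
    D_h2_cm2_s : aqueous diffusivity of H2, cm²/s
    C_syn / C_cons : dissolved H2 at syntroph / dechlorinator surface, mol/cm³
    geometry : syntroph cell geometry providing the exchange area
    """

    J_h2_mol_s: float
    D_h2_cm2_s: float = 6.31e-5
    C_syn_mol_cm3: float = 0.0
    C_cons_mol_cm3: float = 0.0
    geometry: CellGeometry = CellGeometry()

    def __post_init__(self) -> None:
        if self.J_h2_mol_s <= 0:
            raise TransferError("per-cell H2 flux must be positive")
        if self.D_h2_cm2_s <= 0:
            raise TransferError("diffusivity must be positive")


def mean_cell_spacing(total_density: float) -> float:
    """Mean cell-cell distance (μm) of randomly dispersed cells at *total_density* (cells/mL).

    Uses the random-dispersion convention d = (1/N)^(1/3): each cell occupies
    on average a cube of volume 1/N, whose edge is the nearest-neighbour scale.
    """
    if total_density <= 0:
        raise TransferError("cell density must be positive")
    return (1.0 / total_density) ** (1.0 / 3.0) * 1e4  # cm -> μm


def percell_h2_demand(dechlorination_rate_umol_day: float, h2_per_cl: float,
                      consumer_density_per_ml: float, liquid_volume_ml: float) -> float:
    """Per-cell H2 demand (mol/s) from a flask-level dechlorination rate.

    One H2 is consumed per Cl- released in hydrogenolysis, so ``h2_per_cl``
    defaults to 1 in callers.  The flask rate (μmol Cl-/day) is divided over
    every dechlorinating cell in the flask.
    """
    if dechlorination_rate_umol_day < 0:
        raise TransferError("dechlorination rate must be nonnegative")
    if h2_per_cl <= 0 or liquid_volume_ml <= 0:
        raise TransferError("h2_per_cl and liquid volume must be positive")
    cells = consumer_density_per_ml * liquid_volume_ml
    if cells <= 0:
        raise TransferError("consumer cell count must be positive")
    return dechlorination_rate_umol_day * h2_per_cl * 1e-6 / SECONDS_PER_DAY / cells


def max_interspecies_distance(p: TransferProblem) -> float:
    """Maximum syntroph-dechlorinator distance (μm) sustaining the flux demand.

    d = A_syn * D_H2 * (C_syn - C_cons) / J, with A_syn converted from μm² to
    cm² and the result from cm to μm.  Raises if there is no concentration
    gradient to drive diffusion.
    """
    dc = p.C_syn_mol_cm3 - p.C_cons_mol_cm3
    if dc <= 0:
        raise TransferError(
            "no diffusive H2 transfer possible: surface concentration at the "
            "syntroph does not exceed that at the dechlorinator"
        )
    area_cm2 = p.geometry.area_um2 * 1e-8
    d_cm = area_cm2 * p.D_h2_cm2_s * dc / p.J_h2_mol_s
    return d_cm * 1e4


def proximity_assessment(measured_spacing_um: float, max_distance_um: float,
                         tolerance: float = 0.1) -> str:
    """Classify measured spacing against the diffusive limit.

    Returns ``within-limit`` if measured < (1 - tolerance) * max,
    ``beyond-limit`` if measured > (1 + tolerance) * max, else ``at-limit``.
    """
    if measured_spacing_um <= 0 or max_distance_um <= 0:
        raise TransferError("spacing and limit must be positive")
    if measured_spacing_um < (1.0 - tolerance) * max_distance_um:
        return "within-limit"
    if measured_spacing_um > (1.0 + tolerance) * max_distance_um:
        return "beyond-limit"
    return "at-limit"
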