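"""Closed two-phase serum-flask bookkeeping.

Cultures grow in sealed 160 mL serum flasks holding 80 mL liquid under an
anaerobic headspace.  Volatile analytes partition between the phases
according to a dimensionless Henry constant kcc = C_gas / C_aq; amounts are
tracked per flask in μmol and concentrations derived on demand.  The module
also covers chloride-release stoichiometry of the hydrogenolytic ladder
(each daughter congener accounts for parent-minus-daughter chlorines),
serial-transfer dilution arithmetic and nominal gas concentrations by the
ideal-gas law.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

__all__ = [
    "FlaskSpec",
    "Compound",
    "load_henry",
    "partition",
    "chloride_release",
    "serial_dilution",
    "nominal_concentration",
]

#: Gas constant in L bar mol-1 K-1.
R_L_BAR = 0.0831446


class FlaskError(ValueError):
    """Raised for inconsistent flask geometry or stoichiometry inputs."""


@dataclass(frozen=True)
class FlaskSpec:
    """Closed-vessel geometry and temperature (defaults: 160/80 mL at 30 C)."""

    total_volume_ml: float = 160.0
    liquid_volume_ml: float = 80.0
    temperature_k: float = 303.15

    def __post_init__(self) -> None:
        if not (0 < self.liquid_volume_ml < self.total_volume_ml):
            raise FlaskError("need 0 < liquid volume < total volume")
        if self.temperature_k <= 0:
            raise FlaskError("temperature must be positive (K)")

    @property
    def headspace_volume_ml(self) -> float:
        return self.total_volume_ml - self.liquid_volume_ml


@dataclass(frozen=True)
class Compound:
    """A volatile analyte with its partitioning and chlorination metadata."""

    name: str
    henry_kcc: float
    n_chlorines: int = 0
    molar_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.henry_kcc < 0:
            raise FlaskError("Henry constant must be nonnegative")
        if not (0 <= self.n_chlorines <= 6):
            raise FlaskError("chlorobenzene congeners carry 0-6 chlorines")


def load_henry(path: str | None = None, temperature: str = "25C") -> dict[str, Compound]:
    """Load the packaged (or user) Henry-constant table.

    ``temperature`` selects the ``kcc_25C`` (culture) or ``kcc_80C``
    (headspace-GC incubation) column.
    """
    if path is None:
        text = resources.files("halosyn.data").joinpath("henry.csv").read_text(encoding="utf-8")
        df = pd.read_csv(io.StringIO(text), comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    col = f"kcc_{temperature}"
    if col not in df.columns:
        raise FlaskError(f"no Henry-constant column {col!r}; have {list(df.columns)}")
    return {
        row["compound"]: Compound(
            name=row["compound"],
            henry_kcc=float(row[col]),
            n_chlorines=int(row["n_chlorines"]),
            molar_mass=float(row["molar_mass_g_per_mol"]),
        )
        for _, row in df.iterrows()
    }


def partition(total_amount_umol: float, c: Compound, f: FlaskSpec) -> tuple[float, float, float]:
    """Equilibrium two-phase split of a per-flask amount.

    Solves C_gas = kcc * C_aq together with mass balance
    C_aq * V_liq + C_gas * V_gas = total.  Returns
    ``(aqueous μM, headspace μM, gas-phase mole fraction)``.
    """
    if total_amount_umol < 0:
        raise FlaskError("amount must be nonnegative")
    c_aq_umol_ml = total_amount_umol / (f.liquid_volume_ml + c.henry_kcc * f.headspace_volume_ml)
    c_gas_umol_ml = c.henry_kcc * c_aq_umol_ml
    gas_amount = c_gas_umol_ml * f.headspace_volume_ml
    gas_fraction = gas_amount / total_amount_umol if total_amount_umol > 0 else 0.0
    return c_aq_umol_ml * 1e3, c_gas_umol_ml * 1e3, gas_fraction


def chloride_release(daughter_amounts: Mapping[Compound, float], parent: Compound) -> float:
    """μmol Cl- released, from daughter congener amounts (μmol) and the parent.

    Each μmol of a daughter with n chlorines accounts for
    (parent.n_chlorines - n) μmol of released chloride.
    """
    total = 0.0
    for daughter, amount in daughter_amounts.items():
        if daughter.n_chlorines >= parent.n_chlorines:
            raise FlaskError(
                f"{daughter.name} carries {daughter.n_chlorines} chlorines, not fewer "
                f"than parent {parent.name} ({parent.n_chlorines})"
            )
        if amount < 0:
            raise FlaskError("daughter amounts must be nonnegative")
        total += amount * (parent.n_chlorines - daughter.n_chlorines)
    return total


def serial_dilution(c0: float, transfer_fraction: float, n_transfers: int) -> float:
    """Concentration after *n_transfers* serial transfers at *transfer_fraction* v/v."""
    if not (0 < transfer_fraction < 1):
        raise FlaskError("transfer fraction must lie in (0, 1)")
    if n_transfers < 0:
        raise FlaskError("number of transfers must be nonnegative")
    return c0 * transfer_fraction**n_transfers


def nominal_concentration(gas_pressure_bar: float, f: FlaskSpec, basis: str = "liquid") -> float:
    """Nominal concentration (mM) of a headspace gas amendment.

    Moles from the ideal-gas law (P * V_headspace / RT at the flask
    temperature) divided by the liquid or total flask volume.
    """
    if gas_pressure_bar < 0:
        raise FlaskError("pressure must be nonnegative")
    if basis not in ("liquid", "total"):
        raise FlaskError("basis must be 'liquid' or 'total'")
    mol = gas_pressure_bar * (f.headspace_volume_ml / 1e3) / (R_L_BAR * f.temperature_k)
    volume_l = (f.liquid_volume_ml if basis == "liquid" else f.total_volume_ml) / 1e3
    return mol / volume_l * 1e3  # mol/L -> mM
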