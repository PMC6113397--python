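"""Gibbs-energy engine for fermentation and reductive-dechlorination reactions.

Syntrophic hydrogen transfer is governed by a narrow window of H2 activity:
fermentation of lactate, propionate or acetate is exergonic only *below* a
critical H2 level (the producer's ceiling), while hydrogenolytic
dechlorination of chlorobenzenes is exergonic only *above* its own, much
lower, critical level (the consumer's floor).  This module computes standard
transformed reaction energies from a packaged formation-energy table,
mass-action-corrected energies at given activities, and the critical H2
activities bounding that window.

Conventions
-----------
* Energies are standard *transformed* values (primed): pH 7 is folded into
  the formation energies, so H+ never contributes an activity term.
* Liquid water likewise contributes no activity term.
* Aqueous activities are molar concentrations relative to 1 M; gas
  activities are partial pressures relative to 1 bar.
* ``dG0_prime`` is treated as temperature independent; only the RT factor
  uses the condition temperature.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "R_KJ",
    "ChemSpecies",
    "Reaction",
    "ThermoConditions",
    "SpeciesTable",
    "load_species",
    "load_reactions",
    "species_table_hash",
    "delta_g_standard",
    "delta_g_prime",
    "critical_h2",
    "h2_window",
]

#: Gas constant, kJ mol-1 K-1.
R_KJ = 8.31446e-3

_SILENT_PHASES = frozenset({"liquid-water", "proton-pH7"})
_VALID_PHASES = frozenset({"aqueous", "gas"}) | _SILENT_PHASES

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class ThermoError(ValueError):
    """Raised for lookup, balance or domain violations in thermodynamic calculations."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an empirical formula like ``C6HCl5`` into an element-count map."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ThermoError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ThermoError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class ChemSpecies:
    """A chemical species with a standard transformed formation energy.

    Parameters
    ----------
    name : str
        Identifier used in reaction stoichiometries.
    phase : str
        One of ``aqueous``, ``gas``, ``liquid-water``, ``proton-pH7``.
        The last two contribute no activity term to reaction quotients.
    dGf0_prime : float
        Standard transformed Gibbs energy of formation, kJ/mol (pH 7, 298 K).
    formula, charge
        Empirical formula and net charge, used for balance checking.
    """

    name: str
    phase: str
    dGf0_prime: float
    formula: str = ""
    charge: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        if self.phase not in _VALID_PHASES:
            raise ThermoError(f"unknown phase {self.phase!r} for species {self.name!r}")

    @property
    def silent(self) -> bool:
        """True if the species contributes no activity term to Q."""
        return self.phase in _SILENT_PHASES


class SpeciesTable:
    """Lookup of :class:`ChemSpecies` by name."""

    def __init__(self, species: Iterable[ChemSpecies]):
        self._by_name: dict[str, ChemSpecies] = {}
        for sp in species:
            if sp.name in self._by_name:
                raise ThermoError(f"duplicate species {sp.name!r} in formation table")
            self._by_name[sp.name] = sp

    def __getitem__(self, name: str) -> ChemSpecies:
        try:
            return self._by_name[name]
        except KeyError:
            raise ThermoError(f"species {name!r} missing from formation table") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)


@dataclass
class Reaction:
    """A stoichiometric reaction (products positive, reactants negative)."""

    name: str
    stoichiometry: Mapping[str, float]
    role: str = ""  # "hydrogenogenic" or "hydrogen-consuming"
    dG0_prime: float | None = None

    def __post_init__(self) -> None:
        self.stoichiometry = dict(self.stoichiometry)
        if self.role and self.role not in ("hydrogenogenic", "hydrogen-consuming"):
            raise ThermoError(f"unknown reaction role {self.role!r}")

    @property
    def nu_h2(self) -> float:
        return self.stoichiometry.get("H2", 0.0)

    def check_balance(self, table: SpeciesTable, tol: float = 1e-9) -> None:
        """Verify element and charge balance against the species table."""
        elements: dict[str, float] = {}
        charge = 0.0
        for name, nu in self.stoichiometry.items():
            sp = table[name]
            if not sp.formula:
                continue
            for el, n in parse_formula(sp.formula).items():
                elements[el] = elements.get(el, 0.0) + nu * n
            charge += nu * sp.charge
        bad = {el: v for el, v in elements.items() if abs(v) > tol}
        if bad or abs(charge) > tol:
            raise ThermoError(
                f"reaction {self.name!r} is unbalanced: elements {bad}, charge {charge:+g}"
            )


@dataclass
class ThermoConditions:
    """Temperature, activities and the feasibility threshold for ΔG' evaluation.

    ``activities`` maps species name to activity (aqueous mol/L relative to
    1 M, gas bar relative to 1 bar); species absent from the map default to
    activity 1.  ``dG_crit`` (kJ/reaction, default 0) is the free-energy
    change treated as the margin of feasibility; set it to e.g. -20 for a
    "minimum energy quantum" analysis.
    """

    temperature: float = 298.15
    activities: dict[str, float] = field(default_factory=dict)
    dG_crit: float = 0.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ThermoError("temperature must be positive (K)")
        for name, a in self.activities.items():
            if a <= 0:
                raise ThermoError(f"activity of {name!r} must be positive, got {a}")

    def activity(self, name: str) -> float:
        return self.activities.get(name, 1.0)


# ---------------------------------------------------------------------------
# packaged tables

def _data_text(filename: str) -> str:
    return resources.files("halosyn.data").joinpath(filename).read_text(encoding="utf-8")


def load_species(path: str | None = None) -> SpeciesTable:
    """Load a formation-energy table (packaged table when *path* is None)."""
    if path is None:
        import io

        df = pd.read_csv(io.StringIO(_data_text("species.csv")), comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    required = {"name", "phase", "dGf0_prime_kJ_per_mol"}
    missing = required - set(df.columns)
    if missing:
        raise ThermoError(f"species table missing columns: {sorted(missing)}")
    species = [
        ChemSpecies(
            name=row["name"],
            phase=row["phase"],
            dGf0_prime=float(row["dGf0_prime_kJ_per_mol"]),
            formula=str(row.get("formula", "") or ""),
            charge=int(row.get("charge", 0) or 0),
            source=str(row.get("source", "") or ""),
        )
        for _, row in df.iterrows()
    ]
    return SpeciesTable(species)


def parse_stoichiometry(text: str) -> dict[str, float]:
    """Parse ``species:coeff;species:coeff;...`` (species names may contain commas)."""
    stoich: dict[str, float] = {}
    for term in text.split(";"):
        term = term.strip()
        if not term:
            continue
        name, _, coeff = term.rpartition(":")
        if not name:
            raise ThermoError(f"cannot parse stoichiometry term {term!r}")
        stoich[name.strip()] = float(coeff)
    return stoich


def load_reactions(path: str | None = None, table: SpeciesTable | None = None) -> dict[str, Reaction]:
    """Load packaged (or user) reactions; computes ΔG0' when a table is given."""
    if path is None:
        import io

        df = pd.read_csv(io.StringIO(_data_text("reactions.csv")), comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    reactions: dict[str, Reaction] = {}
    for _, row in df.iterrows():
        rxn = Reaction(
            name=row["name"],
            stoichiometry=parse_stoichiometry(row["stoichiometry"]),
            role=row.get("role", "") or "",
        )
        if table is not None:
            delta_g_standard(rxn, table)
        reactions[rxn.name] = rxn
    return reactions


def species_table_hash(path: str | None = None) -> str:
    """Short content hash of the formation-energy table, for report provenance."""
    if path is None:
        text = _data_text("species.csv")
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    return hashlib.sha256(text.encode("utf-8")).hexdigest()[:12]


# ---------------------------------------------------------------------------
# operations

def delta_g_standard(reaction: Reaction, table: SpeciesTable) -> float:
    """ΔG0' of *reaction* (kJ/reaction) as the stoichiometric sum of formation energies.

    The result is also stored on ``reaction.dG0_prime``.  Raises
    :class:`ThermoError` for a species missing from the table or an
    element/charge-unbalanced stoichiometry.
    """
    reaction.check_balance(table)
    total = 0.0
    for name, nu in reaction.stoichiometry.items():
        total += nu * table[name].dGf0_prime
    reaction.dG0_prime = total
    return total


def _ln_q(reaction: Reaction, cond: ThermoConditions, table: SpeciesTable | None,
          exclude: frozenset[str] = frozenset()) -> float:
    """ln of the mass-action quotient over activity-carrying species."""
    lnq = 0.0
    for name, nu in reaction.stoichiometry.items():
        if name in exclude:
            continue
        if table is not None and name in table and table[name].silent:
            continue
        if table is None and name in ("H2O", "H+"):
            continue
        a = cond.activity(name)
        if a <= 0:
            raise ThermoError(f"nonpositive activity for {name!r}")
        lnq += nu * math.log(a)
    return lnq


def delta_g_prime(reaction: Reaction, cond: ThermoConditions,
                  table: SpeciesTable | None = None) -> float:
    """Concentration-adjusted ΔG' = ΔG0' + RT ln Q (kJ/reaction).

    Q runs over aqueous and gas species only; water and the pH-7 proton are
    silent.  When no species table is passed, species named ``H2O`` and
    ``H+`` are treated as silent.
    """
    if reaction.dG0_prime is None:
        raise ThermoError(f"reaction {reaction.name!r} has no dG0_prime set")
    rt = R_KJ * cond.temperature
    return reaction.dG0_prime + rt * _ln_q(reaction, cond, table)


def critical_h2(reaction: Reaction, cond: ThermoConditions,
                table: SpeciesTable | None = None) -> float:
    """H2 activity at which ΔG' equals ``cond.dG_crit``.

    Closed form ``a_H2 = exp[(dG_crit - dG0' - RT ln Q_other) / (nu_H2 RT)]``
    with Q_other the quotient over every activity-carrying species except H2.
    For a hydrogenogenic reaction this is the ceiling below which fermentation
    stays exergonic; for a hydrogen-consuming reaction it is the floor the
    dechlorinator needs.
    """
    nu = reaction.nu_h2
    if nu == 0:
        raise ThermoError(f"reaction {reaction.name!r} has no H2 in its stoichiometry")
    if reaction.dG0_prime is None:
        raise ThermoError(f"reaction {reaction.name!r} has no dG0_prime set")
    rt = R_KJ * cond.temperature
    ln_q_other = _ln_q(reaction, cond, table, exclude=frozenset({"H2"}))
    return math.exp((cond.dG_crit - reaction.dG0_prime - rt * ln_q_other) / (nu * rt))


def h2_window(producer: Reaction, consumer: Reaction, cond: ThermoConditions,
              table: SpeciesTable | None = None) -> tuple[float, float, bool]:
    """Syntrophic H2 window: (floor, ceiling, feasible).

    The floor is the consumer's critical H2, the ceiling the producer's; the
    window is feasible when floor < ceiling.  Roles are enforced.
    """
    if producer.role != "hydrogenogenic":
        raise ThermoError(f"producer {producer.name!r} is not hydrogenogenic")
    if consumer.role != "hydrogen-consuming":
        raise ThermoError(f"consumer {consumer.name!r} is not hydrogen-consuming")
    floor = critical_h2(consumer, cond, table)
    ceiling = critical_h2(producer, cond, table)
    return floor, ceiling, floor < ceiling
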