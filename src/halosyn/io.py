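"""Readers, writers, run configuration and the combined feasibility report.

The feasibility report chains the thermodynamic window, the diffusive
transfer-distance model and the cell-spacing calculation for the three
co-cultures (lactate-, propionate- and acetate-fed), mirroring the layout
of a two-table summary: one table per co-culture (densities, spacing,
maximum transfer distance, proximity classification) and one per reaction
(ΔG0', ΔG' at the configured activities, critical H2).

Time-series CSV dialect: UTF-8, header required, period decimal separator,
columns ``time_days, analyte, amount_umol, flask_id``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import thermo, transfer
from .kinetics import TimeSeries

__all__ = [
    "RunConfig",
    "CocultureSpec",
    "default_run_config",
    "load_run_config",
    "read_timeseries",
    "write_timeseries",
    "run_feasibility_report",
    "write_report",
]

TIMESERIES_COLUMNS = ["time_days", "analyte", "amount_umol", "flask_id"]


class IOError_(ValueError):
    """Raised for malformed input files or configurations."""


@dataclass
class CocultureSpec:
    """One co-culture line of the feasibility report."""

    name: str
    donor_reaction: str
    total_density_per_ml: float
    dechlorination_rate_umol_day: float
    activities: dict[str, float] = field(default_factory=dict)
    reference_max_um: float | None = None


@dataclass
class RunConfig:
    """Configuration of the combined feasibility/distance analysis."""

    temperature_k: float = 303.15
    dG_crit: float = 0.0
    consumer_reaction: str = "hcb_to_pecb"
    consumer_activities: dict[str, float] = field(
        default_factory=lambda: {"HCB": 1e-6, "PeCB": 1e-6, "Cl-": 1e-3})
    dechlorinator_fraction: float = 0.5
    liquid_volume_ml: float = 80.0
    d_h2_cm2_s: float = 6.31e-5
    h2_solubility_m_per_bar: float = 7.8e-4
    h2_ceiling_cap_bar: float = 1.0
    cell_shape: str = "rod"
    cell_diameter_um: float = 0.5
    cell_length_um: float = 2.0
    proximity_tolerance: float = 0.1
    species_table: str | None = None
    reactions_table: str | None = None
    cocultures: list[CocultureSpec] = field(default_factory=list)


def default_run_config() -> RunConfig:
    """Packaged defaults: the three co-cultures at their day-60 densities and rates."""
    cfg = RunConfig()
    cfg.cocultures = [
        CocultureSpec("DSV/CBDB1", "lactate_oxidation", 2.11e8, 0.59,
                      {"lactate": 0.01, "acetate": 1e-3, "bicarbonate": 0.1}, 178.0),
        CocultureSpec("GBL/CBDB1", "acetate_oxidation", 1.34e8, 0.45,
                      {"acetate": 0.03, "bicarbonate": 0.1}, 10.1),
        CocultureSpec("SFO/CBDB1", "propionate_oxidation", 6.89e7, 0.39,
                      {"propionate": 0.03, "acetate": 1e-3, "bicarbonate": 0.1}, 18.6),
    ]
    return cfg


def load_run_config(path: str) -> RunConfig:
    """Read a YAML run configuration; unspecified fields keep package defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = default_run_config()
    cocultures = raw.pop("cocultures", None)
    for key, value in raw.items():
        if not hasattr(cfg, key):
            raise IOError_(f"unknown configuration key {key!r}")
        setattr(cfg, key, value)
    if cocultures is not None:
        cfg.cocultures = [CocultureSpec(**c) for c in cocultures]
    return cfg


# ---------------------------------------------------------------------------
# time-series CSV

def read_timeseries(path: str) -> dict[tuple[str, str], TimeSeries]:
    """Read a time-series CSV into per-(analyte, flask) series, stably ordered.

    Raises :class:`IOError_` naming the missing column or the offending line
    number for malformed rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing required column(s) {missing}")
    for idx, row in df.iterrows():
        try:
            float(row["time_days"]); float(row["amount_umol"])
        except (TypeError, ValueError):
            raise IOError_(f"{path}: malformed row at line {idx + 2}: {row.to_dict()}") from None
    out: dict[tuple[str, str], TimeSeries] = {}
    for (analyte, flask_id), grp in df.groupby(["analyte", "flask_id"], sort=True):
        grp = grp.sort_values("time_days")
        out[(str(analyte), str(flask_id))] = TimeSeries(
            times=grp["time_days"].to_numpy(dtype=float),
            values=grp["amount_umol"].to_numpy(dtype=float),
            analyte=str(analyte), flask_id=str(flask_id),
        )
    return out


def write_timeseries(series: dict[tuple[str, str], TimeSeries] | pd.DataFrame,
                     path: str) -> None:
    """Write time series in the standard CSV dialect (round-trips with the reader)."""
    if isinstance(series, pd.DataFrame):
        df = series[TIMESERIES_COLUMNS]
    else:
        rows = []
        for (analyte, flask_id), ts in sorted(series.items()):
            for t, v in zip(ts.times, ts.values):
                rows.append((t, analyte, v, flask_id))
        df = pd.DataFrame(rows, columns=TIMESERIES_COLUMNS)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# feasibility report

def run_feasibility_report(cfg: RunConfig | None = None) -> dict:
    """Chain thermodynamics, spacing and transfer distance for each co-culture.

    Returns a dict with ``coculture_table`` and ``reaction_table`` DataFrames
    plus provenance metadata.  Deterministic: repeated runs on the same
    configuration yield identical frames.
    """
    if cfg is None:
        cfg = default_run_config()
    table = thermo.load_species(cfg.species_table)
    reactions = thermo.load_reactions(cfg.reactions_table, table)
    consumer = reactions[cfg.consumer_reaction]
    geometry = transfer.CellGeometry(shape=cfg.cell_shape, diameter=cfg.cell_diameter_um,
                                     length=cfg.cell_length_um)

    consumer_cond = thermo.ThermoConditions(
        temperature=cfg.temperature_k, activities=dict(cfg.consumer_activities),
        dG_crit=cfg.dG_crit)
    floor_bar = thermo.critical_h2(consumer, consumer_cond, table)

    rows = []
    rx_rows = []
    for cc in cfg.cocultures:
        producer = reactions[cc.donor_reaction]
        cond = thermo.ThermoConditions(
            temperature=cfg.temperature_k,
            activities={**cc.activities, **cfg.consumer_activities},
            dG_crit=cfg.dG_crit)
        floor, ceiling, feasible = thermo.h2_window(producer, consumer, cond, table)
        ceiling_capped = min(ceiling, cfg.h2_ceiling_cap_bar)
        c_syn = ceiling_capped * cfg.h2_solubility_m_per_bar * 1e-3   # mol/cm3
        c_cons = floor * cfg.h2_solubility_m_per_bar * 1e-3
        spacing = transfer.mean_cell_spacing(cc.total_density_per_ml)
        j = transfer.percell_h2_demand(
            cc.dechlorination_rate_umol_day, 1.0,
            cc.total_density_per_ml * cfg.dechlorinator_fraction, cfg.liquid_volume_ml)
        problem = transfer.TransferProblem(
            J_h2_mol_s=j, D_h2_cm2_s=cfg.d_h2_cm2_s,
            C_syn_mol_cm3=c_syn, C_cons_mol_cm3=c_cons, geometry=geometry)
        d_max = transfer.max_interspecies_distance(problem)
        classification = (
            transfer.proximity_assessment(spacing, cc.reference_max_um, cfg.proximity_tolerance)
            if cc.reference_max_um else
            transfer.proximity_assessment(spacing, d_max, cfg.proximity_tolerance))
        rows.append({
            "coculture": cc.name,
            "total_density_per_ml": cc.total_density_per_ml,
            "mean_spacing_um": spacing,
            "rate_umol_cl_day": cc.dechlorination_rate_umol_day,
            "percell_J_mol_s": j,
            "h2_floor_bar": floor,
            "h2_ceiling_bar": ceiling,
            "window_feasible": feasible,
            "max_distance_um": d_max,
            "reference_max_um": cc.reference_max_um,
            "classification": classification,
        })
        rx_rows.append({
            "reaction": producer.name, "role": producer.role,
            "dG0_prime_kJ": producer.dG0_prime,
            "dG_prime_kJ": thermo.delta_g_prime(producer, cond, table),
            "critical_h2_bar": ceiling,
        })
    rx_rows.append({
        "reaction": consumer.name, "role": consumer.role,
        "dG0_prime_kJ": consumer.dG0_prime,
        "dG_prime_kJ": thermo.delta_g_prime(consumer, consumer_cond, table),
        "critical_h2_bar": floor_bar,
    })
    return {
        "coculture_table": pd.DataFrame(rows),
        "reaction_table": pd.DataFrame(rx_rows),
        "species_table_hash": thermo.species_table_hash(cfg.species_table),
        "config": dataclasses.asdict(cfg),
    }


def write_report(report: dict, out_dir: str) -> list[str]:
    """Write report tables and provenance to *out_dir*; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for key in ("coculture_table", "reaction_table"):
        p = out / f"{key}.csv"
        report[key].to_csv(p, index=False)
        paths.append(str(p))
    meta = out / "report_meta.yaml"
    with open(meta, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"species_table_hash": report["species_table_hash"],
                        "config": report["config"]}, fh, sort_keys=True)
    paths.append(str(meta))
    return paths
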