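"""Seeded generator of in-silico syntrophic co-culture experiments.

The generator reproduces the statistical structure the estimators assume,
so parameter recovery can be demonstrated end to end without laboratory
data.  The noise-free latent model of a closed flask is:

* donor (lactate/propionate/acetate) decays first order,
  donor(t) = donor0 * exp(-k t);
* H2 produced is stoichiometric in donor consumed (2, 3 or 4 H2 per donor);
  H2-fed pure cultures start with a fixed H2 pool instead;
* cumulative chloride release grows at the true maximum rate but can never
  exceed the H2 made available (1 H2 per Cl-), which yields the
  accumulate-then-consume H2 pool shape of fermenting co-cultures;
* CO accumulates in proportion to chloride released, less the fraction a
  CO-consuming partner removes;
* daughter congeners split the chloride release between dichloro- and
  trichlorobenzene equivalents; an optional first-order stripping constant
  emulates headspace adsorption on granular activated carbon;
* cell density grows in proportion to cumulative chloride released.

Observed values are latent * (1 + N(0, cv)), truncated at zero (censoring);
everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import DoseResponse, TimeSeries, four_pl

__all__ = [
    "ExperimentConfig",
    "SyntheticExperiment",
    "partner_defaults",
    "generate",
    "generate_dose_response",
    "generate_first_order",
]


class SyntheticError(ValueError):
    """Raised for invalid generator configurations."""


#: Study-condition presets per fermenting partner: electron donor amendment
#: (mM), its first-order oxidation constant (day^-1, matched to the donor
#: consumed after 60 days), H2 per donor oxidized, true maximum
#: dechlorination rate (μmol Cl-/day) and cell yield (cells per μmol Cl-).
PARTNER_PRESETS: dict[str, dict] = {
    "DSV": dict(donor="lactate", donor_initial_mm=10.0, donor_k=0.012, h2_per_donor=2,
                true_max_rate=0.59, cell_yield=3.7e8),
    "SFO": dict(donor="propionate", donor_initial_mm=30.0, donor_k=0.0063, h2_per_donor=3,
                true_max_rate=0.39, cell_yield=2.7e8),
    "GBL": dict(donor="acetate", donor_initial_mm=30.0, donor_k=0.010, h2_per_donor=4,
                true_max_rate=0.45, cell_yield=3.8e8),
    "none": dict(donor="H2", donor_initial_mm=7.5, donor_k=0.0, h2_per_donor=1,
                 true_max_rate=0.23, cell_yield=2.3e8),
}


@dataclass
class ExperimentConfig:
    """Generating truth of one in-silico flask experiment.

    Partner ``none`` is the H2-fed pure culture; ``donor_initial_mm`` is then
    the nominal dissolved-equivalent H2 amendment.  ``co_consumed_fraction``
    defaults to 0.9 when a CO-consuming partner is present, 0 otherwise.
    ``gac_k`` (day^-1, <= 0), when set, strips daughter congeners from the
    flask first order.
    """

    partner: str = "none"
    donor_initial_mm: float = 7.5
    donor_k: float = 0.0
    h2_per_donor: int = 1
    true_max_rate: float = 0.23
    co_yield_per_cl: float = 0.08
    cell_yield: float = 2.3e8
    gac_k: float | None = None
    noise_cv: float = 0.1
    seed: int = 0
    sampling_days: tuple = tuple(np.linspace(0.0, 60.0, 10))
    liquid_volume_ml: float = 80.0
    dcb_fraction: float = 0.6
    acetate_per_cl: float = 0.1
    co_consumed_fraction: float | None = None
    initial_cells_per_ml: float = 5e6

    def __post_init__(self) -> None:
        if self.partner not in PARTNER_PRESETS:
            raise SyntheticError(f"unknown partner {self.partner!r}")
        days = np.asarray(self.sampling_days, dtype=float)
        if len(days) < 3 or np.any(np.diff(days) <= 0):
            raise SyntheticError("sampling_days must be >= 3 strictly increasing values")
        for name in ("donor_initial_mm", "donor_k", "true_max_rate", "co_yield_per_cl",
                     "cell_yield", "noise_cv"):
            if getattr(self, name) < 0:
                raise SyntheticError(f"{name} must be nonnegative")
        if self.gac_k is not None and self.gac_k > 0:
            raise SyntheticError("gac_k is a removal constant and must be <= 0")
        if not (0.0 <= self.dcb_fraction <= 1.0):
            raise SyntheticError("dcb_fraction must lie in [0, 1]")
        if self.co_consumed_fraction is None:
            self.co_consumed_fraction = 0.9 if self.partner != "none" else 0.0


def partner_defaults(partner: str, **overrides) -> ExperimentConfig:
    """Config preset for a co-culture partner (or the H2-fed pure culture)."""
    preset = PARTNER_PRESETS[partner] if partner in PARTNER_PRESETS else None
    if preset is None:
        raise SyntheticError(f"unknown partner {partner!r}")
    kwargs = dict(partner=partner, donor_initial_mm=preset["donor_initial_mm"],
                  donor_k=preset["donor_k"], h2_per_donor=preset["h2_per_donor"],
                  true_max_rate=preset["true_max_rate"], cell_yield=preset["cell_yield"])
    kwargs.update(overrides)
    return ExperimentConfig(**kwargs)


@dataclass
class SyntheticExperiment:
    """Latent and observed time series of one generated flask, plus the truth."""

    config: ExperimentConfig
    latent: dict[str, np.ndarray] = field(default_factory=dict)
    observed: dict[str, TimeSeries] = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.config.sampling_days, dtype=float)

    def to_frame(self):
        """Long-format DataFrame (time_days, analyte, amount_umol, flask_id)."""
        import pandas as pd

        rows = []
        for analyte, ts in self.observed.items():
            for t, v in zip(ts.times, ts.values):
                rows.append((t, analyte, v, ts.flask_id or "synthetic"))
        return pd.DataFrame(rows, columns=["time_days", "analyte", "amount_umol", "flask_id"])


def _noisy(rng: np.random.Generator, latent: np.ndarray, cv: float) -> np.ndarray:
    if cv == 0:
        return latent.copy()
    return np.maximum(latent * (1.0 + rng.normal(0.0, cv, size=latent.shape)), 0.0)


def generate(config: ExperimentConfig) -> SyntheticExperiment:
    """Generate one seeded in-silico experiment from its configuration."""
    t = np.asarray(config.sampling_days, dtype=float)
    v = config.liquid_volume_ml
    donor0_umol = config.donor_initial_mm * v  # mM * mL = μmol

    if config.partner == "none":
        donor = np.full_like(t, donor0_umol)  # H2 pool amended once
        h2_produced = np.full_like(t, donor0_umol)
        acetate_produced = np.zeros_like(t)
    else:
        donor = donor0_umol * np.exp(-config.donor_k * t)
        consumed = donor0_umol - donor
        h2_produced = config.h2_per_donor * consumed
        # one acetate per lactate/propionate oxidized; the acetate donor of
        # GBL is itself consumed, so no product acetate pool there
        acetate_produced = consumed if config.partner in ("DSV", "SFO") else np.zeros_like(t)

    # chloride release: rate-capped, never beyond the H2 made available
    cl = np.minimum(config.true_max_rate * t, h2_produced)
    h2_pool = h2_produced - cl

    co_latent = config.co_yield_per_cl * cl
    co = co_latent * (1.0 - config.co_consumed_fraction)

    acetate = np.maximum(acetate_produced - config.acetate_per_cl * cl, 0.0)

    dcb = config.dcb_fraction * cl / 4.0        # 4 Cl- per HCB -> DCB
    tcb = (1.0 - config.dcb_fraction) * cl / 3.0  # 3 Cl- per HCB -> 1,3,5-TCB
    if config.gac_k is not None:
        decay = np.exp(config.gac_k * t)
        dcb_flask, tcb_flask = dcb * decay, tcb * decay
    else:
        dcb_flask, tcb_flask = dcb, tcb

    cells = config.initial_cells_per_ml + config.cell_yield * cl / v  # cells/mL

    latent = {
        "donor": donor, "acetate": acetate, "H2": h2_pool, "H2_produced": h2_produced,
        "Cl": cl, "CO": co, "CO_produced": co_latent,
        "DCB": dcb_flask, "TCB": tcb_flask, "DCB_produced": dcb, "TCB_produced": tcb,
        "cells": cells,
    }

    rng = np.random.default_rng(config.seed)
    observed = {}
    for analyte in ("donor", "acetate", "H2", "Cl", "CO", "DCB", "TCB", "cells"):
        observed[analyte] = TimeSeries(
            times=t, values=_noisy(rng, latent[analyte], config.noise_cv),
            analyte=analyte, flask_id=f"{config.partner}-seed{config.seed}",
        )
    return SyntheticExperiment(config=config, latent=latent, observed=observed)


def generate_dose_response(truth: dict, doses, noise_cv: float = 0.1, seed: int = 0,
                           replicates: int = 1) -> DoseResponse:
    """Endpoint inhibition data from a four-parameter log-logistic truth.

    ``truth`` holds ``top``, ``bottom``, ``ic50`` and ``hill``.  Responses
    are the 4PL mean plus multiplicative Gaussian noise, truncated at zero.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise SyntheticError("doses must be nonempty")
    doses = np.repeat(doses, replicates)
    mean = four_pl(doses, truth["top"], truth["bottom"], truth["ic50"], truth["hill"])
    rng = np.random.default_rng(seed)
    return DoseResponse(doses=doses, responses=_noisy(rng, mean, noise_cv))


def generate_first_order(a0: float, k: float, times, noise_cv: float = 0.05,
                         seed: int = 0, analyte: str = "DCB") -> TimeSeries:
    """Seeded first-order series a0 * exp(k t) with multiplicative noise."""
    t = np.asarray(times, dtype=float)
    latent = a0 * np.exp(k * t)
    rng = np.random.default_rng(seed)
    return TimeSeries(times=t, values=_noisy(rng, latent, noise_cv), analyte=analyte,
                      flask_id=f"decay-seed{seed}")
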