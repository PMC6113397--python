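"""Gibbs-energy engine: formation-table sums, mass-action adjustment, critical H2."""

import math

import numpy as np
import pytest
from scipy import optimize

from halosyn import thermo
from halosyn.thermo import (
    Reaction,
    ThermoConditions,
    ThermoError,
    critical_h2,
    delta_g_prime,
    delta_g_standard,
    h2_window,
)

R = thermo.R_KJ


@pytest.mark.parametrize(
    "name, expected",
    [
        ("propionate_oxidation", 76.1),
        ("acetate_oxidation", 104.6),
        ("hcb_to_pecb", -171.4),
        ("hcb_to_dcb", -447.0),
    ],
)
def test_packaged_reaction_energies(reactions, name, expected):
    """ΔG0' of the fermentation and dechlorination reactions matches the published table."""
    assert reactions[name].dG0_prime == pytest.approx(expected, abs=0.5)


def test_null_reaction_is_zero(species_table):
    assert delta_g_standard(Reaction("null", {}), species_table) == 0.0


def test_missing_species_named_in_error(species_table):
    rxn = Reaction("bad", {"unobtainium": 1.0})
    with pytest.raises(ThermoError, match="unobtainium"):
        delta_g_standard(rxn, species_table)


def test_unbalanced_reaction_rejected(species_table):
    rxn = Reaction("lopsided", {"acetate": -1, "bicarbonate": 1, "H2": 1})
    with pytest.raises(ThermoError, match="unbalanced"):
        delta_g_standard(rxn, species_table)


def test_unit_activities_reduce_to_standard(reactions, species_table):
    """At Q = 1 the adjusted energy equals ΔG0' to machine precision."""
    cond = ThermoConditions(temperature=303.15)
    for rxn in reactions.values():
        assert delta_g_prime(rxn, cond, species_table) == rxn.dG0_prime


def test_mass_action_adjustment_matches_per_species_sum(reactions, species_table):
    """ΔG' at culture-like activities agrees with an independent per-species RT·ln(a)·ν sum.

    Water and the pH-7 proton are silent; at low H2 the acetate oxidation
    becomes exergonic.
    """
    rxn = reactions["acetate_oxidation"]
    acts = {"acetate": 0.03, "bicarbonate": 0.1, "H2": 1e-5}
    cond = ThermoConditions(temperature=303.0, activities=acts)
    expected = rxn.dG0_prime
    for name, nu in rxn.stoichiometry.items():
        if name in ("H2O", "H+"):
            continue
        expected += nu * R * 303.0 * math.log(acts.get(name, 1.0))
    got = delta_g_prime(rxn, cond, species_table)
    assert got == pytest.approx(expected, rel=1e-12)
    assert got < 0


def test_nonpositive_activity_rejected():
    with pytest.raises(ThermoError):
        ThermoConditions(activities={"H2": 0.0})


def test_additivity_along_the_congener_ladder(reactions):
    """HCB→DCB energy equals the sum over the stepwise hydrogenolytic path."""
    path = ["hcb_to_pecb", "pecb_to_tecb", "tecb_to_tcb", "tcb_to_13dcb"]
    stepwise = sum(reactions[name].dG0_prime for name in path)
    assert stepwise == pytest.approx(reactions["hcb_to_dcb"].dG0_prime, abs=1e-9)


def test_critical_h2_trivial_unit_case():
    rxn = Reaction("toy", {"H2": 1.0}, role="hydrogenogenic", dG0_prime=0.0)
    assert critical_h2(rxn, ThermoConditions()) == pytest.approx(1.0)


def test_critical_h2_requires_h2(species_table, reactions):
    rxn = Reaction("no_h2", {"acetate": 1.0}, dG0_prime=0.0)
    with pytest.raises(ThermoError, match="H2"):
        critical_h2(rxn, ThermoConditions())


def _bisect_critical_h2(rxn, cond):
    """Independent oracle: root of ΔG'(a_H2) − dG_crit on a log-spaced bracket."""

    def g(log10_a):
        c = ThermoConditions(temperature=cond.temperature,
                             activities={**cond.activities, "H2": 10.0**log10_a},
                             dG_crit=cond.dG_crit)
        return delta_g_prime(rxn, c) - cond.dG_crit

    grid = np.linspace(-40, 40, 4001)
    vals = np.array([g(x) for x in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    assert len(sign_change) == 1
    i = sign_change[0]
    return 10.0 ** optimize.brentq(g, grid[i], grid[i + 1], xtol=1e-13)


def test_critical_h2_closed_form_vs_bisection_propionate(reactions, species_table):
    """The fermentation ceiling matches a brute-force sign-change scan to 4+ figures."""
    rxn = reactions["propionate_oxidation"]
    cond = ThermoConditions(
        temperature=303.0,
        activities={"propionate": 0.03, "acetate": 1e-3, "bicarbonate": 0.1})
    rxn_plain = Reaction(rxn.name, rxn.stoichiometry, rxn.role, rxn.dG0_prime)
    closed = critical_h2(rxn_plain, cond)
    assert closed == pytest.approx(_bisect_critical_h2(rxn_plain, cond), rel=1e-6)


def test_window_exists_for_propionate_against_hcb(reactions, species_table):
    """The dechlorination floor lies far below the fermentation ceiling."""
    cond = ThermoConditions(
        temperature=303.0,
        activities={"propionate": 0.03, "acetate": 1e-3, "bicarbonate": 0.1,
                    "HCB": 1e-6, "PeCB": 1e-6, "Cl-": 1e-3})
    floor, ceiling, feasible = h2_window(
        reactions["propionate_oxidation"], reactions["hcb_to_pecb"], cond, species_table)
    assert feasible and floor < ceiling
    assert floor < 1e-20  # −171.4 kJ/reaction leaves essentially no floor


def test_window_symmetry_and_role_checks(reactions):
    stoich = {"propionate": -1, "H2O": -3, "acetate": 1, "bicarbonate": 1, "H+": 1, "H2": 3}
    producer = Reaction("p", stoich, "hydrogenogenic", dG0_prime=76.5)
    consumer = Reaction("c", stoich, "hydrogen-consuming", dG0_prime=76.5)
    floor, ceiling, feasible = h2_window(producer, consumer, ThermoConditions())
    assert floor == pytest.approx(ceiling)
    assert not feasible
    with pytest.raises(ThermoError, match="hydrogenogenic"):
        h2_window(consumer, consumer, ThermoConditions())


def test_infeasible_window_for_endergonic_consumer(reactions):
    producer = reactions["propionate_oxidation"]
    consumer = Reaction("uphill", {"HCB": -1, "H2": -1, "PeCB": 1, "H+": 1, "Cl-": 1},
                        "hydrogen-consuming", dG0_prime=500.0)
    cond = ThermoConditions(temperature=303.0)
    floor, ceiling, feasible = h2_window(producer, consumer, cond)
    assert not feasible and floor > ceiling


def test_dg_prime_monotone_in_h2(reactions, species_table):
    """ΔG' rises with H2 for hydrogenogenic reactions and falls for consumers."""
    cond_at = lambda a: ThermoConditions(temperature=303.0, activities={"H2": a})
    grid = np.logspace(-8, 0, 9)
    for name, increasing in (("acetate_oxidation", True), ("hcb_to_pecb", False)):
        vals = [delta_g_prime(reactions[name], cond_at(a), species_table) for a in grid]
        diffs = np.diff(vals)
        assert np.all(diffs > 0) if increasing else np.all(diffs < 0)
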