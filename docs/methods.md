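# Methods

`halosyn` models the quantitative reasoning behind syntrophic reductive
dechlorination of hexachlorobenzene (HCB) in closed anaerobic microcosms: a
fermenting partner (*Desulfovibrio*, *Syntrophobacter* or *Geobacter*
lineages on lactate, propionate or acetate) supplies H₂ to an obligately
hydrogenotrophic dechlorinator, which in turn keeps the H₂ level low enough
for fermentation to stay exergonic. This note records the models, the
defaults, and the design choices made where the problem was genuinely open.

## Thermodynamics (`halosyn.thermo`)

Reaction energies are standard *transformed* values (ΔG⁰′, pH 7, 298 K,
1 M / 1 bar standard states) computed as stoichiometry-weighted sums of
formation energies from the packaged `species.csv`. The proton carries the
pH-7 transformation (−39.87 kJ/mol) and, like liquid water, never
contributes an activity term to the mass-action quotient Q. ΔG′ at culture
conditions is ΔG⁰′ + RT ln Q with R = 8.314×10⁻³ kJ mol⁻¹ K⁻¹ and the
condition's temperature; ΔG⁰′ itself is treated as temperature independent
(no enthalpy correction), mirroring the common practice of applying 25 °C
standard values to 30 °C cultures.

The critical H₂ activity where ΔG′ crosses a feasibility threshold
`dG_crit` (default 0 kJ/reaction; set to e.g. −20 for a minimum-energy-
quantum analysis) has the closed form

    a_H2 = exp[(dG_crit − ΔG⁰′ − RT ln Q_other) / (ν_H2 · RT)],

the ceiling of a hydrogenogenic reaction and the floor of a
hydrogen-consuming one; the syntrophic window is (floor, ceiling). The
closed form is cross-checked in the tests against a numeric root of ΔG′ on
randomized reactions.

**Formation table.** Fermentation-species values follow the
Thauer-convention compilation and reproduce the canonical net energies:
propionate oxidation to acetate/bicarbonate/3 H₂ at +76.5 kJ/reaction and
acetate oxidation to 2 bicarbonate/4 H₂ at +104.6 kJ/reaction. Two caveats
are deliberate:

* *Lactate.* The compiled energies give −4.0 kJ/reaction for lactate
  oxidation; a value of −8.4 kJ/reaction circulates in the co-culture
  literature (≈2× the compiled number). No standard compilation we are
  aware of reproduces −8.4; the packaged table keeps the compiled value and
  records the discrepancy here rather than resolving it.
* *Chlorobenzenes.* No formation energies for the congeners are printed in
  the primary sources for this system, so the congener rows are
  back-calculated from the net hydrogenolysis energies (HCB→PeCB −171.4,
  HCB→DCB −447 kJ/reaction) anchored at HCB = +47.20 kJ/mol, with the
  intermediate steps (−105.0, −95.0, −75.6) chosen to sum exactly while
  decreasing in exergonicity down the ladder, as expected chemically. Only
  differences within balanced reactions are meaningful; additivity along
  any stepwise congener path is exact by construction and asserted in the
  tests. Condensed textbook stoichiometries are rebalanced where needed
  (acetate oxidation requires 4 H₂O; propionate oxidation requires an
  explicit H⁺) — rebalancing changes no energy because the added species
  are activity-silent.

## Transfer distances (`halosyn.transfer`)

Steady-state diffusive H₂ exchange between a syntroph and a dechlorinator
at distance d obeys J = A_syn · D_H2 · (C_syn − C_cons) / d. Solving for d
at the per-cell H₂ demand gives the maximum spacing compatible with the
observed dechlorination rate. Defaults: D_H2 = 6.31×10⁻⁵ cm² s⁻¹ (the
aqueous diffusivity of H₂ near 35 °C; note this constant is sometimes
misprinted with a positive exponent), rod-shaped syntroph 0.5 × 2 μm
(cylinder plus hemispherical caps, A_syn ≈ 3.53 μm²), per-cell demand =
flask rate × 1 H₂/Cl⁻ divided over the dechlorinator population (default:
half the day-60 total count; the partition between partners is not measured
directly). C_syn and C_cons come from the thermodynamic window at default
activities (donor at its amendment level, product acetate 1 mM,
bicarbonate 0.1 M), converted to dissolved concentration via an H₂
solubility of 7.8×10⁻⁴ M/bar and with the ceiling capped at 1 bar — a
fermentation ceiling above the headspace pressure (lactate) is physically
cut off by the gas phase.

Mean spacing of randomly dispersed cells is (1/N)^(1/3) (each cell occupies
on average a cube of volume 1/N); this reproduces the day-60 spacings
16.8 / 19.5 / 24.4 μm from the measured total densities exactly.

**What the pipeline can and cannot reproduce.** The published maximum
distances (178 / 10.1 / 18.6 μm for the lactate / acetate / propionate
co-cultures) depend on unprinted inputs — the syntroph surface area
actually used, the exact concentration thresholds, and how the flask rate
was attributed to cells. With the documented defaults the pipeline
reproduces the *ordering* (lactate ≫ propionate > acetate; default run:
≈1.9×10⁷ / 2.6×10³ / 6.6×10² μm) and the ratio between the propionate and
acetate limits, but sits roughly two orders of magnitude above the absolute
published values; the absolute scale is therefore not asserted anywhere.
Proximity classification (within / at / beyond the diffusive limit, ±10 %
band) is computed against the reported reference maxima carried in the
default configuration, reproducing the published conclusion that the
lactate co-culture sits well inside its limit while the other two sit
marginally beyond.

## Flask mass balance (`halosyn.flask`)

Amounts are tracked per flask in μmol (the 160/80 mL serum-flask geometry
is the default); concentrations are derived on demand. Henry partitioning
solves C_gas = kcc·C_aq with mass conservation; kcc values are packaged at
25 °C (culture) and 80 °C (headspace-GC incubation), the hot values being
van't Hoff-style estimates. Chloride release is Σ amount × (parent −
daughter chlorine count). Serial transfer dilution is c₀·f^n — four 10 %
transfers dilute 0.5 μg/L cobalamin to 0.05 ng/L. Nominal gas amendments
use the ideal-gas law in bar (0.3 bar H₂ over 80 mL headspace at 30 °C is
11.9 mM on the liquid basis; the often-quoted 7.5 mM follows from neither
volume basis, which is why the basis is an explicit argument).

## Kinetics (`halosyn.kinetics`)

* **Maximum dechlorination rate**: the largest OLS slope over a sliding
  window of consecutive samples. The op-level default window is 4 points —
  appropriate for courses with lag or saturation phases, where the maximum
  is a local feature. The recovery study instead uses a window spanning the
  sustained linear phase (all but the first two samples of a 10-point
  course): maximizing narrow-window slopes over a fully linear course
  inflates the estimate by construction (the maximum of several noisy
  unbiased slopes), while the wide window keeps the residual positive bias
  of the max-over-windows step near +5 % at 10 % CV noise.
* **First-order constants**: nonlinear least squares of A·e^{kt} seeded by
  a log-linear fit; decay series must be strictly positive.
* **IC50**: four-parameter log-logistic response = bottom +
  (top−bottom)/(1+(dose/IC50)^hill), parameterized directly on dose so the
  zero-dose control is a regular point; bottom ≥ 0; IC50 bounded by 3× the
  largest dose (beyond which the design does not identify it). Residuals
  are weighted by response magnitude by default, matching the constant-CV
  error of replicate headspace-GC measurements; with unweighted residuals
  the heteroscedasticity induces a systematic ≈−7 % small-sample bias at
  the study noise level, which the weighting removes. Non-convergence and
  no-inhibition fits are flagged, not raised. Confidence information is
  asymptotic standard errors from the fit covariance.
* **Mitigation margin**: |k_adsorption| − k_production; positive margin
  means headspace activated carbon strips daughter products faster than the
  culture makes them (0.1 vs −0.14 day⁻¹ and 0.07 vs −0.16 day⁻¹ both
  mitigate).
* Group-comparison hypothesis testing (t-tests, ANOVA, Dunnett) is out of
  scope; reports print means and spreads only.

## Synthetic experiments (`halosyn.synthetic`)

The generator emulates the closed-flask dynamics the estimators assume.
Noise-free latent model: first-order donor oxidation (rate constants
matched to the donor consumed after 60 days: 0.012 / 0.0063 / 0.010 day⁻¹
for 10 mM lactate / 30 mM propionate / 30 mM acetate); H₂ stoichiometric in
donor consumed (2 / 3 / 4 per donor); chloride release at the true maximum
rate (0.59 / 0.39 / 0.45 μmol Cl⁻ day⁻¹ for the three co-cultures,
0.23 for the H₂-fed pure culture) but capped by H₂ availability at 1 H₂
per Cl⁻, which yields the accumulate-then-consume H₂ pool; CO proportional
to cumulative chloride (yield 0.08 μmol/μmol, the pure-culture value
0.9/11.2), with a CO-consuming partner removing 90 % by default; daughter
congeners split 60/40 between DCB- and TCB-equivalents (not measured as a
ratio; configurable); optional first-order stripping of daughters to
activated carbon; cells grow in proportion to cumulative chloride (yields
2.3–3.8×10⁸ cells per μmol Cl⁻). Observed values are latent × (1 + N(0,
CV)) truncated at zero — truncation is censoring, not resampling — and
bit-identical given the seed.

What the generator does **not** emulate: Monod/thermodynamic feedback of
the H₂ pool on fermentation (the window is checked statically), sulfate or
fumarate side-metabolism of the partners (so the absolute acetate/H₂ pools
overshoot the measured mM-scale peaks), aggregate formation, and congener
succession within the ladder. Passing recovery tests therefore demonstrate
estimator correctness under the assumed error structure, not fidelity of
the latent curves to any particular measured time course.

## Problem sizes and numerics

Recovery studies use 100 seeds (rate, adsorption constant) and 200 seeds
(IC50) at the study noise levels (CV 0.1 and 0.05), 10-point/60-day rate
courses and 8-point/14-day decay series — ensembles large enough that the
Monte-Carlo error on the ensemble mean is a small fraction of the 10 %
recovery band, while a full run stays in the seconds range. Nonlinear fits
use tight least-squares tolerances (1e-14) so noise-free recovery is exact
to ≤1e-6. Replicate seeds are drawn from a seeded generator so every study
is reproducible from one base seed.
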