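# Methods

## Scope and model of the system

The package analyses steady-state, CO-limited chemostat cultures of a
gas-fermenting acetogen at dilution rate D ≈ 1 day⁻¹ (so µ = D/24 h⁻¹ at
steady state) on three feed gases: CO (~60% CO / 40% Ar), a high-H₂ CO mix
(~15% CO / 45% H₂ / 40% Ar) and syngas (~50% CO / 20% H₂ / 20% CO₂ / 10%
inert), each at a low (~0.5 gDCW/L) and a high (~1.4 gDCW/L) biomass level,
working volume 750 mL, pH 5, 37 °C. All derived quantities are steady-state
averages; startup dynamics, pH/ORP control and gas–liquid mass-transfer
(kLa) modelling are out of scope.

## Off-gas rate calculation

The off-gas molar flow is inferred from the inert tracer: Ar (or the
N₂/Ar share of syngas) is neither consumed nor produced, so
F_out = F_in · y_inert,in / y_inert,out. The specific rate of species i is

    q_i = (F_in·y_i,in − F_out·y_i,out) · 60 / (V_m · V_L · X)   [mmol/gDCW/h]

with F in mL/min, V_m the ideal-gas molar volume in mL/mmol, V_L the
working volume in L and X the biomass concentration in gDCW/L. Signs:
uptake positive for CO and H₂, production positive for CO₂ and ethanol.
Negative uptake (net production, routinely seen for H₂ on CO-only feeds) is
reported as-is, never clipped.

Two correction terms complete the totals:

* **Ethanol stripping.** Ethanol in the off-gas at fraction y_EtOH is an
  export flux F_out·y_EtOH converted exactly like any other gas species and
  added to the liquid-outflow term D·c_EtOH/X.
* **Dissolved CO₂.** CO₂ leaves dissolved in the broth outflow:
  c = k_H·p_CO₂·(1 + 10^(pH − pKa₁)) with k_H = 0.0215 mol/(L·atm) at
  37 °C and pKa₁ = 6.35; the export rate is D·c/X. The bicarbonate term can
  be disabled (`include_bicarbonate=False`) to keep only the Henry term;
  both treatments are defensible at pH 5, where the correction is below 1%
  of total CO₂ production either way. Carbonate (second dissociation) is
  neglected.

Conventions chosen once and surfaced in `AnalysisConfig`: molar volume
24.465 mL/mmol (25 °C, 1 atm, the usual off-gas analyser reference),
headspace pressure 1 atm, OD600→gDCW/L factor 0.21. Steady-state rates are
arithmetic means over the provided window with per-quantity standard
deviations; no outlier rejection is applied because the window is assumed
to be an already-screened stable steady state.

The biomass entering the per-gDCW normalisation is always derived from the
observed OD series (X = 0.21·mean OD), not from the nominal setpoint, so
the analysis is self-contained given the raw observables.

## Carbon and electron balancing

Carbon recovery is the C-mol product sum over C-mol CO consumed:
q_CO₂ + 2q_EtOH + 2q_Ac + 4q_BDO + µ·C_X, divided by q_CO, times 100.
Biomass is CH₁.₈O₀.₅N₀.₂ (24.63 g/C-mol, C_X ≈ 40.6 mmol C/gDCW) — the
standard bioprocess default, exposed in the configuration because measured
elemental compositions vary by a few percent. Normalized distributions
scale every fraction by 100/recovery, preserving ordering and pairwise
ratios.

Electron bookkeeping uses degrees of reduction relative to CO₂/H₂O/NH₃:
γ = 4c + h − 2o − 3n (CO 2, H₂ 2, ethanol 12, acetate 8, 2,3-BDO 22,
biomass 4.2 per C-mol, CO₂ 0). Acetate is balanced as the free acid; the
proton bookkeeping of dissociation cancels in this convention.

## Closed-form CO + H₂ → ethanol stoichiometry

For an ethanol-only spectrum, electron conservation (2 + 2r = 12·E per CO,
r the H₂/CO uptake ratio, E ethanol per CO) fixes the overall equation:
CO₂ loss f(r) = (2 − r)/3 and yield Y(r) = (1 + r)/6 on r ∈ [0, 2], with
f ≡ 0 and Y capped at 1/2 beyond. The water coefficient follows from the
oxygen balance, (1 − r)/2 per CO. `overall_stoichiometry` refuses r > 2
(an ethanol-only spectrum cannot consume the surplus H₂) while the scalar
functions clamp, which is the behaviour callers usually want. Exact floats
are returned everywhere; rounding happens only at presentation.

## The synthetic-data generator

The generator is the exact algebraic inverse of the analyzer. Given truth
rates it computes species molar outflows (inert conserved; outflow =
inflow − uptake·X·V_L/60 + production·X·V_L/60), broth concentrations
c = q·X/D, and OD = X/0.21. Two details make the inversion exact rather
than approximate:

* the gaseous CO₂ outflow is solved by a short fixed-point iteration so
  that gas term + dissolved-broth export equals the true total CO₂
  production (the dissolved term depends on the off-gas CO₂ fraction it
  itself perturbs; the iteration contracts by ~10⁻³ per step);
* a fixed stripping fraction (default 10% of total ethanol production
  leaving via gas — a deliberate, exercisable magnitude; real strip
  fractions depend on gas flow and temperature) splits ethanol between the
  gas and liquid routes, and the analyzer reassembles the total from both.

Noise is multiplicative Gaussian, independent per timepoint and observable:
σ = 1% on gas mole fractions, 2% on HPLC concentrations, 3% on OD. These
defaults are realistic instrument-level magnitudes for MS off-gas analysis,
HPLC and spectrophotometry; the study conditions fix them and the
parameter-recovery census (200 seeds, 50 timepoints) is run at exactly
these values. What the generator does **not** emulate: analyser calibration
drift (the measured feed composition is taken as exact, mirroring per-cycle
online recalibration), autocorrelated process drift, sampling-interval
irregularity, and biological replicate-to-replicate variation. Passing
recovery tests therefore demonstrates correctness of the balance algebra
under honest instrument noise, not robustness to systematic error.

Condition profiles: the packaged rate profiles carry the reported headline
ratios (qCO₂/qCO 0.69 on CO and 0.21 on high-H₂ CO; qH₂/qCO 1.44 on
high-H₂ CO and 0.39 on syngas; marginal net H₂ production on CO; molar
acetate/ethanol ≈ 1 on syngas vs ≈ 0.2 on high-H₂ CO; no 2,3-BDO on
high-H₂ CO). Absolute magnitudes, where not reported, were set once so the
emitted off-gas CO fraction matches the observed ~9% (high-H₂ CO) and ~32%
(syngas) levels and broth ethanol reaches ~11 g/L on high-H₂ CO.

`truth_from_carbon_profile` converts a normalized carbon distribution into
absolute rates that close carbon at exactly 100%. Because the chemostat
pins µ = D/24 and the biomass carbon content is fixed, a non-zero biomass
fraction determines q_CO uniquely — so q_CO is inferred from it (an
explicit q_CO must agree). The H₂/CO ratio is solved from the electron
balance when not supplied; a supplied ratio that fails to close electrons
within tolerance is rejected with the surplus/deficit and the closing
ratio in the message. A zero biomass fraction yields the degenerate µ = 0
truth used for stoichiometric edge cases.

## The core metabolic network

The packaged network (34 reactions, 33 metabolites) covers the scope the
flux analyses need: CO dehydrogenase and CODH/ACS, the full methyl branch,
three routes into formate (NADPH-consuming formate dehydrogenase
`rxn00103_c0`, formate-H₂ lyase `rxn08518_c0`, electron-bifurcating
hydrogenase `leq000001` producing Fd_red + NADPH from 2 H₂), Pta–AckA,
AdhE and AOR ethanol routes, PFOR and the 2,3-BDO branch, Nfn, Rnf, ATP
synthase, an ATP-dissipation (maintenance) reaction and a one-C-mol
biomass drain (CH₁.₈O₀.₅N₀.₂ from acetyl-CoA, NH₃, NADPH and a
growth-associated ATP cost, default 2 ATP/C-mol). The three ModelSEED-style
ids are kept verbatim so constraint schemes written against the core
network apply unchanged to a genome-scale model using the same ids.

Cofactors carry full chemical formulas (ferredoxin as a pseudo-element
with a −2 charge difference between redox states), so the validator checks
element and charge — and hence electron — conservation of every internal
reaction exactly; the packaged model passes with an empty report and no
dead-end metabolites.

Open cofactor stoichiometries are parameters with defaults: Rnf
translocates 2 H⁺ per Fd_red oxidised; ATP synthase imports 4 H⁺ per ATP
(one consumed chemically). The methylene-THF reductase ships in two
selectable variants — electron-bifurcating/Fd-reducing (2 NADH + Fd_ox →
2 NAD⁺ + Fd_red per methylene-THF reduced; the default, physiologically
supported form) and plain NADH-dependent — because this reaction's
energetics decide whether experimental flux patterns are feasible at all.

The model is also shipped as a two-file TSV table (`data/reactions.tsv`,
`data/metabolites.tsv`; a test asserts it equals the code-built network)
and round-trips through SBML Level 3 + fbc.

## Flux balance analysis

LPs are solved with HiGHS via `scipy.optimize.linprog`. Degeneracy
handling: after the primary optimum the objective is pinned and total
absolute flux is minimised (parsimonious secondary objective), making
reported flux maps deterministic vertices. Steady-state residuals |S·v| of
accepted solutions are below 10⁻⁶; infeasible/unbounded outcomes are
returned as statuses, never raised.

Three schemes:

1. **ATP-dissipation analysis** — every measured exchange (gas rates,
   secretions, biomass at µ·C_X) is fixed as an equality (an optional
   ± tolerance band absorbs measurement noise) and the maintenance flux is
   maximised. Measured rate sets with recovery ≠ 100% are infeasible under
   equalities; `rescale_uptakes=True` resets q_CO to the product-carbon sum
   and q_H₂ to the electron-closing value. One scalar cannot close both
   balances, which is why the adjustment touches the two gas uptakes and
   nothing else — product concentrations and µ are the better-measured
   quantities.
2. **Optimal growth prediction** — uptakes and maintenance fixed, biomass
   maximised, secretions free; substrates not listed cannot be taken up.
   On CO this predicts acetate-only secretion (acetate yields more ATP per
   CO than ethanol), reproducing the known failure of yield-maximising FBA
   to predict ethanol on CO.
3. **H₂-coupling scheme** — `rxn00103_c0` bounded to zero and
   v(rxn08518) = k·v(leq000001) added as an equality row. k defaults to the
   identity function of qH₂/qCO and must be supplied for quantitative use;
   the scheme is only applicable to H₂-containing gases (on CO it removes
   every route into formate and ethanol-requiring patterns go infeasible).

Summaries partition reduced-ferredoxin production by source (CO oxidation
vs H₂ vs other) and acetaldehyde formation by route (AOR vs AdhE). At the
ATP optimum ethanol is 100% AOR-routed: the acetate detour gains 1 ATP by
substrate-level phosphorylation at the cost of one Fd_red, which is worth
only 0.5 ATP through Rnf/ATPase at the default proton stoichiometries.

The methylene-THF-reductase feasibility check mirrors the observation that
experimental flux patterns require the Fd-reducing form: the maintenance
capacity of the Fd variant exceeds the NADH-only variant's by 0.5 ATP per
methyl-branch flux, so a pattern demanding ≥95% of the Fd variant's
capacity is optimal with it and infeasible without it. The 95% level is
computed from the model at run time, not fitted.

Quantities that depend on the full genome-scale model and exact
experimental exchange values (maintenance 5.5→9.3 mmol/gDCW/h, Fd_red
source fractions 82%/41%, recoveries 111/99/124%, the ~4% ethanol
prediction error) are reproduced in direction only on the core network;
the constraint machinery is identical.

## Problem sizes and numerics

Synthetic series use 50 timepoints by default (hourly sampling of a stable
steady state); the parameter-recovery census runs 200 seeds. The LP-oracle
census compares HiGHS against exhaustive basic-feasible-solution
enumeration on 200 random networks with ≤5 metabolites and ≤7 reactions
(the enumeration is exponential and independent of any LP code). Fixed-point
and LP tolerances: 10⁻¹⁵ relative for the generator's CO₂ solve, 10⁻⁶ for
steady-state residuals and closed-form comparisons, 10⁻⁹ objective pinning
in the parsimonious pass.

## Known limitations

* The core network is a deliberately small central-metabolism abstraction:
  absolute flux and maintenance magnitudes differ from genome-scale
  results; directions and feasibility structure are the claims.
* The biomass reaction is a single C-mol drain; amino-acid-resolved
  composition, GAM/NGAM partitioning and gene–protein–reaction rules are
  out of scope.
* The closed-form theory assumes an ethanol-only spectrum; multi-product
  stoichiometry is handled numerically by `truth_from_carbon_profile`.
* Thermodynamic (Gibbs energy) feasibility and kinetic regulation are not
  modelled; the H₂-coupling ratio function k is a free parameter.
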