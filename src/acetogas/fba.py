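"""Flux balance analysis and the chemostat simulation schemes.

Three analyses mirror how steady-state gas-fermentation data are confronted
with a stoichiometric model:

1. :func:`atp_dissipation_analysis` -- all measured exchange rates (gas
   uptakes, product secretions, growth) are fixed and the ATP maintenance
   (dissipation) flux is maximised, yielding the intracellular flux pattern
   and the maintenance ATP cost the network can support.
2. :func:`optimal_growth_prediction` -- only substrate uptakes and the
   maintenance ATP cost are fixed, biomass yield is maximised and product
   secretion is left free ("optimal" phenotype prediction).
3. :func:`apply_h2_coupling_scheme` -- on H2-containing gases the
   redox-consuming formate dehydrogenase (``rxn00103_c0``) is closed and the
   flux ratio between direct CO2 reduction with H2 (``rxn08518_c0``) and
   H2-driven ferredoxin/NADPH generation (``leq000001``) is pinned to a
   function of the measured qH2/qCO ratio.

LPs are solved with HiGHS through :func:`scipy.optimize.linprog`. After the
primary objective, the objective value is fixed and the total absolute flux
is minimised (a parsimonious secondary objective) so reported flux maps are
deterministic vertices rather than an arbitrary member of the optimal face.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

from .balances import SPECIES, SpecificRates
from .config import AnalysisConfig, DEFAULT_CONFIG
from .metabolic_model import (
    ATP_DISSIPATION_ID,
    BIOMASS_ID,
    FDH_NADPH_ID,
    FHL_ID,
    HYT_ID,
    StoichiometricModel,
)

__all__ = [
    "FBAProblem",
    "FluxState",
    "solve",
    "atp_dissipation_analysis",
    "optimal_growth_prediction",
    "apply_h2_coupling_scheme",
    "fdred_source_fractions",
    "ethanol_route_attribution",
]


@dataclass
class RatioConstraint:
    """v[numerator] = k * v[denominator]."""

    numerator: str
    denominator: str
    k: float


@dataclass
class FBAProblem:
    """A fully specified linear flux-balance problem.

    ``fixed_fluxes`` maps reaction ids to (value, tolerance); the flux is
    constrained to value +/- tolerance (tolerance 0 means equality).
    ``zeroed`` reactions get bounds [0, 0].
    """

    model: StoichiometricModel
    objective: str
    sense: str = "max"
    fixed_fluxes: dict[str, tuple[float, float]] = field(default_factory=dict)
    ratio_constraints: list[RatioConstraint] = field(default_factory=list)
    zeroed: list[str] = field(default_factory=list)
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [self.objective, *self.fixed_fluxes, *self.zeroed,
               *self.bound_overrides]
        for rc in self.ratio_constraints:
            if not np.isfinite(rc.k):
                raise ValueError("ratio constraint k must be finite")
            ids += [rc.numerator, rc.denominator]
        for rid in ids:
            if not self.model.has_reaction(rid):
                raise ValueError(f"unknown reaction id {rid!r} in problem")
        if self.sense not in ("max", "min"):
            raise ValueError("sense must be 'max' or 'min'")


@dataclass
class FluxState:
    """Solved flux vector with objective value and solver status."""

    fluxes: dict[str, float]
    objective_value: float | None
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


def _assemble(problem: FBAProblem):
    S, _, rxn_ids = problem.model.stoichiometric_matrix()
    idx = {r: j for j, r in enumerate(rxn_ids)}
    bounds = list(problem.model.bounds())
    for rid, bnd in problem.bound_overrides.items():
        bounds[idx[rid]] = bnd
    for rid in problem.zeroed:
        bounds[idx[rid]] = (0.0, 0.0)
    for rid, (value, tol) in problem.fixed_fluxes.items():
        bounds[idx[rid]] = (value - tol, value + tol)
    rows = []
    for rc in problem.ratio_constraints:
        row = np.zeros(len(rxn_ids))
        row[idx[rc.numerator]] = 1.0
        row[idx[rc.denominator]] = -rc.k
        rows.append(row)
    A_eq = np.vstack([S] + rows) if rows else S
    b_eq = np.zeros(A_eq.shape[0])
    return A_eq, b_eq, bounds, rxn_ids, idx


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def solve(problem: FBAProblem, parsimonious: bool = True) -> FluxState:
    """Solve the LP; optionally minimise total |flux| at the fixed optimum.

    Infeasible or unbounded problems are returned as statuses, not raised.
    """
    A_eq, b_eq, bounds, rxn_ids, idx = _assemble(problem)
    n = len(rxn_ids)
    c = np.zeros(n)
    c[idx[problem.objective]] = -1.0 if problem.sense == "max" else 1.0
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxState(fluxes={}, objective_value=None, status=status)
    obj = float(res.x[idx[problem.objective]])
    v = res.x
    if parsimonious:
        v2 = _parsimonious(A_eq, b_eq, bounds, idx[problem.objective], obj, n)
        if v2 is not None:
            v = v2
    return FluxState(
        fluxes={r: float(v[j]) for j, r in enumerate(rxn_ids)},
        objective_value=obj,
        status="optimal",
    )


def _parsimonious(A_eq, b_eq, bounds, obj_idx, obj_value, n):
    """min sum(u) s.t. u >= |v|, original constraints, objective pinned."""
    bounds2 = list(bounds)
    lo, hi = bounds2[obj_idx]
    eps = 1e-9 * max(1.0, abs(obj_value))
    bounds2[obj_idx] = (max(lo, obj_value - eps), min(hi, obj_value + eps))
    A_eq2 = np.hstack([A_eq, np.zeros((A_eq.shape[0], n))])
    # u - v >= 0 and u + v >= 0  ->  -u + v <= 0 and -u - v <= 0
    I = np.eye(n)
    A_ub = np.vstack([np.hstack([I, -I]), np.hstack([-I, -I])])
    b_ub = np.zeros(2 * n)
    big = max(abs(b) for bb in bounds for b in bb if np.isfinite(b))
    c = np.concatenate([np.zeros(n), np.ones(n)])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq2,
        b_eq=b_eq,
        bounds=bounds2 + [(0, big)] * n,
        method="highs",
    )
    if res.status != 0:
        return None
    return res.x[:n]


# --------------------------------------------------------------------------
# Simulation schemes
# --------------------------------------------------------------------------

_EXCHANGE_FOR_RATE = {
    # rate attr -> (exchange id, sign of exchange flux per unit rate)
    "q_co": ("EX_co", -1.0),
    "q_h2": ("EX_h2", -1.0),
    "q_co2": ("EX_co2", 1.0),
    "q_etoh": ("EX_etoh", 1.0),
    "q_acetate": ("EX_ac", 1.0),
    "q_bdo": ("EX_bdo", 1.0),
}


def _closure_rescale(rates: SpecificRates, config: AnalysisConfig) -> SpecificRates:
    """Adjust gas uptakes so carbon and electrons close exactly.

    Measured rate sets with recoveries above 100% cannot satisfy the
    steady-state mass balance when every exchange is fixed. q_CO is reset to
    the product carbon sum and q_H2 to the electron-closing value; product
    rates and mu are untouched.
    """
    bio = config.biomass
    c_out = (
        rates.q_co2
        + 2.0 * rates.q_etoh
        + 2.0 * rates.q_acetate
        + 4.0 * rates.q_bdo
        + rates.mu * bio.carbon_content
    )
    e_out = (
        SPECIES["ethanol"].gamma * rates.q_etoh
        + SPECIES["acetate"].gamma * rates.q_acetate
        + SPECIES["bdo"].gamma * rates.q_bdo
        + bio.degree_of_reduction * rates.mu * bio.carbon_content
    )
    q_co = c_out
    q_h2 = (e_out - SPECIES["co"].gamma * q_co) / SPECIES["h2"].gamma
    return replace(rates, q_co=q_co, q_h2=q_h2)


def atp_dissipation_analysis(
    model: StoichiometricModel,
    rates: SpecificRates,
    mu: float | None = None,
    *,
    fix_products: bool = True,
    rescale_uptakes: bool = False,
    tolerance: float = 0.0,
    config: AnalysisConfig = DEFAULT_CONFIG,
    parsimonious: bool = True,
) -> FluxState:
    """Fix measured exchanges, maximise the ATP dissipation flux.

    ``mu`` defaults to ``rates.mu``; the biomass drain is fixed to
    mu * C_X (mmol C-mol/gDCW/h). With ``fix_products=False`` only the gas
    exchanges and growth are pinned and secretions are left free.
    ``rescale_uptakes`` applies the carbon/electron closure adjustment for
    rate sets whose recovery is not 100%. ``tolerance`` widens every fixed
    exchange to value +/- tolerance (absolute, mmol/gDCW/h).
    """
    if model.atp_dissipation_id is None:
        raise ValueError("model has no ATP dissipation reaction")
    if rescale_uptakes:
        rates = _closure_rescale(rates, config)
    mu = rates.mu if mu is None else mu
    fixed: dict[str, tuple[float, float]] = {}
    rate_keys = _EXCHANGE_FOR_RATE if fix_products else {
        k: v for k, v in _EXCHANGE_FOR_RATE.items() if k in ("q_co", "q_h2", "q_co2")
    }
    for attr, (ex_id, sign) in rate_keys.items():
        fixed[ex_id] = (sign * getattr(rates, attr), tolerance)
    fixed["EX_biomass"] = (mu * config.biomass.carbon_content, tolerance)
    problem = FBAProblem(
        model=model, objective=model.atp_dissipation_id, fixed_fluxes=fixed
    )
    state = solve(problem, parsimonious=parsimonious)
    if not state.optimal:
        return FluxState(
            fluxes={},
            objective_value=None,
            status=state.status
            + (
                "; measured exchange rates may not close carbon/electron "
                "balances (recovery != 100%) -- consider rescale_uptakes=True"
                if state.status == "infeasible" and not rescale_uptakes
                else ""
            ),
        )
    return state


def optimal_growth_prediction(
    model: StoichiometricModel,
    uptake_rates: dict[str, float],
    maintenance: float,
    *,
    config: AnalysisConfig = DEFAULT_CONFIG,
    parsimonious: bool = True,
) -> FluxState:
    """Fix uptakes and maintenance ATP, maximise the biomass drain.

    ``uptake_rates`` maps 'q_co'/'q_h2' (and optionally 'q_co2') to positive
    uptake values in mmol/gDCW/h; substrates not listed cannot be taken up
    (secretion stays possible) and product secretions stay free.
    """
    if model.biomass_id is None:
        raise ValueError("model has no biomass reaction")
    if maintenance < 0:
        raise ValueError("maintenance must be non-negative")
    fixed: dict[str, tuple[float, float]] = {}
    overrides: dict[str, tuple[float, float]] = {}
    for attr in ("q_co", "q_h2", "q_co2"):
        ex_id, sign = _EXCHANGE_FOR_RATE[attr]
        if attr in uptake_rates:
            fixed[ex_id] = (sign * uptake_rates[attr], 0.0)
        else:
            lb, ub = model.reaction(ex_id).lower_bound, model.reaction(ex_id).upper_bound
            overrides[ex_id] = (0.0, ub)
    unknown = set(uptake_rates) - {"q_co", "q_h2", "q_co2"}
    if unknown:
        raise ValueError(f"unknown uptake keys {sorted(unknown)}")
    fixed[model.atp_dissipation_id] = (maintenance, 0.0)
    problem = FBAProblem(
        model=model,
        objective=model.biomass_id,
        fixed_fluxes=fixed,
        bound_overrides=overrides,
    )
    return solve(problem, parsimonious=parsimonious)


def apply_h2_coupling_scheme(
    problem: FBAProblem,
    qh2_qco: float,
    k=None,
) -> FBAProblem:
    """Close the redox-consuming formate dehydrogenase and pin the
    rxn08518/leq000001 flux ratio to k(qH2/qCO).

    ``k`` is a caller-supplied monotone function of the uptake ratio
    (identity by default; the quantitatively fitted relation is
    dataset-specific and must be provided for quantitative use). Returns a
    new problem; the input is not modified.
    """
    model = problem.model
    for rid in (FDH_NADPH_ID, FHL_ID, HYT_ID):
        if not model.has_reaction(rid):
            raise ValueError(
                f"H2-coupling scheme requires reaction id {rid!r} (or a "
                "model mapped to these ids)"
            )
    k_value = float(qh2_qco if k is None else k(qh2_qco))
    if k_value <= 0:
        raise ValueError("coupling ratio k(qH2/qCO) must be positive")
    return FBAProblem(
        model=model,
        objective=problem.objective,
        sense=problem.sense,
        fixed_fluxes=dict(problem.fixed_fluxes),
        ratio_constraints=problem.ratio_constraints
        + [RatioConstraint(FHL_ID, HYT_ID, k_value)],
        zeroed=list(problem.zeroed) + [FDH_NADPH_ID],
    )


# --------------------------------------------------------------------------
# Flux summaries
# --------------------------------------------------------------------------


def _production_flux(
    state: FluxState, model: StoichiometricModel, met_id: str, rxn_id: str
) -> float:
    """Net production of ``met_id`` by ``rxn_id`` in ``state`` (>= 0)."""
    if not model.has_reaction(rxn_id):
        return 0.0
    coeff = model.reaction(rxn_id).stoichiometry.get(met_id, 0.0)
    return max(coeff * state.fluxes.get(rxn_id, 0.0), 0.0)


def fdred_source_fractions(
    state: FluxState, model: StoichiometricModel
) -> dict[str, float]:
    """Percent of reduced-ferredoxin production by source.

    ``from_co_oxidation`` is CO dehydrogenase; ``from_h2`` is the
    electron-bifurcating hydrogenase; anything else (e.g. the Fd-reducing
    methylene-THF reductase) is ``other``. Fractions sum to 100.
    """
    if not state.optimal:
        raise ValueError("need an optimal flux state")
    production: dict[str, float] = {}
    for r in model.reactions:
        coeff = r.stoichiometry.get("fd_red_c", 0.0)
        flux = coeff * state.fluxes.get(r.id, 0.0)
        if flux > 0:
            production[r.id] = flux
    total = sum(production.values())
    if total <= 0:
        raise ValueError("no reduced-ferredoxin turnover in this flux state")
    from_co = production.get("CODH", 0.0)
    from_h2 = production.get(HYT_ID, 0.0)
    return {
        "from_co_oxidation": 100.0 * from_co / total,
        "from_h2": 100.0 * from_h2 / total,
        "other": 100.0 * (total - from_co - from_h2) / total,
    }


def ethanol_route_attribution(
    state: FluxState, model: StoichiometricModel
) -> dict[str, float]:
    """Split acetaldehyde formation between the AOR and AdhE routes, %."""
    if not state.optimal:
        raise ValueError("need an optimal flux state")
    if state.fluxes.get("EX_etoh", 0.0) <= 0:
        raise ValueError("no ethanol secretion in this flux state")
    via_aor = _production_flux(state, model, "acald_c", "AOR")
    via_adhe = _production_flux(state, model, "acald_c", "ACALD")
    total = via_aor + via_adhe
    if total <= 0:
        raise ValueError("no acetaldehyde formation flux")
    return {
        "via_aor": 100.0 * via_aor / total,
        "via_adhe": 100.0 * via_adhe / total,
    }
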