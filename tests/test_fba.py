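"""LP solver correctness against brute-force vertex enumeration, schemes,
and flux summaries."""

import numpy as np
import pytest

from acetogas.balances import SpecificRates
from acetogas.fba import (
    FBAProblem,
    FluxState,
    apply_h2_coupling_scheme,
    atp_dissipation_analysis,
    ethanol_route_attribution,
    fdred_source_fractions,
    optimal_growth_prediction,
    solve,
)
from acetogas.metabolic_model import (
    FDH_NADPH_ID,
    FHL_ID,
    HYT_ID,
    Metabolite,
    Reaction,
    StoichiometricModel,
    parse_formula,
)
from acetogas.stoich_theory import co2_loss_fraction
from oracles import best_vertex_objective, random_flux_network


def _toy_chain():
    mets = [
        Metabolite("a_c", "A", parse_formula("C"), 0),
        Metabolite("b_c", "B", parse_formula("C"), 0),
    ]
    rxns = [
        Reaction("EX_a", "A uptake", {"a_c": 1}, 0, 5, frozenset({"exchange"})),
        Reaction("A2B", "A->B", {"a_c": -1, "b_c": 1}, 0, 1000),
        Reaction("EX_b", "B out", {"b_c": -1}, 0, 1000, frozenset({"exchange"})),
    ]
    return StoichiometricModel(mets, rxns)


def test_linear_chain_objective():
    state = solve(FBAProblem(model=_toy_chain(), objective="EX_b"))
    assert state.optimal
    assert state.objective_value == pytest.approx(5.0)


def test_all_exchanges_zero_gives_zero_flux():
    model = _toy_chain()
    state = solve(
        FBAProblem(
            model=model,
            objective="EX_b",
            fixed_fluxes={"EX_a": (0.0, 0.0), "EX_b": (0.0, 0.0)},
        )
    )
    assert state.optimal
    assert all(abs(v) < 1e-9 for v in state.fluxes.values())


def test_solver_matches_vertex_enumeration(rng):
    """LP optimum equals exhaustive basic-feasible-solution enumeration on
    random small networks (the acceptance suite runs the 200-instance
    census; this is a quick 40-instance spot check)."""
    from scipy.optimize import linprog

    for _ in range(40):
        S, lb, ub, c = random_flux_network(rng)
        oracle = best_vertex_objective(S, lb, ub, c, sense="max")
        res = linprog(
            -c, A_eq=S, b_eq=np.zeros(S.shape[0]),
            bounds=list(zip(lb, ub)), method="highs",
        )
        assert res.status == 0 and oracle is not None
        assert -res.fun == pytest.approx(oracle, abs=1e-6)


def test_infeasible_returned_as_status():
    model = _toy_chain()
    state = solve(
        FBAProblem(
            model=model,
            objective="EX_b",
            fixed_fluxes={"EX_a": (0.0, 0.0), "EX_b": (3.0, 0.0)},
        )
    )
    assert state.status == "infeasible"
    assert state.objective_value is None


def test_ratio_constraint_satisfied(core_model):
    fixed = {"EX_co": (-6.0, 0.0), "EX_h2": (-8.4, 0.0),
             "EX_biomass": (0.0, 0.0), "EX_bdo": (0.0, 0.0)}
    problem = apply_h2_coupling_scheme(
        FBAProblem(model=core_model, objective="ATPM", fixed_fluxes=fixed), 1.4
    )
    state = solve(problem)
    assert state.optimal
    assert state.fluxes[FHL_ID] == pytest.approx(1.4 * state.fluxes[HYT_ID])
    assert state.fluxes[FDH_NADPH_ID] == 0.0


def test_h2_coupling_rejects_nonpositive_k(core_model):
    problem = FBAProblem(model=core_model, objective="ATPM")
    with pytest.raises(ValueError, match="positive"):
        apply_h2_coupling_scheme(problem, 1.0, k=lambda r: 0.0)


def test_h2_coupling_infeasible_without_h2(core_model):
    """On a CO-only gas the scheme removes every route into formate, so an
    ethanol-requiring pattern cannot be satisfied."""
    fixed = {"EX_co": (-6.0, 0.0), "EX_h2": (0.0, 0.0),
             "EX_etoh": (1.0, 0.0), "EX_biomass": (0.0, 0.0)}
    problem = apply_h2_coupling_scheme(
        FBAProblem(model=core_model, objective="ATPM", fixed_fluxes=fixed), 1.0
    )
    assert solve(problem).status == "infeasible"


def test_steady_state_mass_balance_invariant(core_model):
    rates = SpecificRates(
        q_co=6.0, q_h2=8.4, q_co2=0.6, q_etoh=2.0, q_acetate=0.3, q_bdo=0.0,
        mu=0.0,
    )
    state = atp_dissipation_analysis(core_model, rates, mu=0.0,
                                     rescale_uptakes=True)
    assert state.optimal
    S, met_ids, rxn_ids = core_model.stoichiometric_matrix()
    v = np.array([state.fluxes[r] for r in rxn_ids])
    assert np.abs(S @ v).max() < 1e-6


@pytest.mark.parametrize("r", [0.0, 0.5, 1.0, 1.5, 2.0])
def test_ethanol_only_fba_reproduces_closed_form(core_model, r):
    """With CO and H2 fixed and all products but ethanol closed, the FBA
    CO2/CO ratio equals the closed-form loss fraction."""
    q = 6.0
    fixed = {
        "EX_co": (-q, 0.0),
        "EX_h2": (-r * q, 0.0),
        "EX_ac": (0.0, 0.0),
        "EX_bdo": (0.0, 0.0),
        "EX_biomass": (0.0, 0.0),
    }
    state = solve(FBAProblem(model=core_model, objective="ATPM", fixed_fluxes=fixed))
    assert state.optimal
    assert state.fluxes["EX_co2"] / q == pytest.approx(co2_loss_fraction(r), abs=1e-6)


def test_dissipation_infeasible_diagnostic_and_rescale(core_model):
    inflated = SpecificRates(
        q_co=6.0, q_h2=0.0, q_co2=4.4, q_etoh=1.1, q_acetate=0.0, q_bdo=0.0,
        mu=0.0,
    )  # 110% carbon recovery
    bad = atp_dissipation_analysis(core_model, inflated, mu=0.0)
    assert bad.status.startswith("infeasible")
    assert "rescale" in bad.status
    good = atp_dissipation_analysis(core_model, inflated, mu=0.0,
                                    rescale_uptakes=True)
    assert good.optimal


def test_maintenance_higher_with_h2_at_matched_carbon(core_model):
    """Direction check: H2 co-utilisation raises the supportable
    maintenance ATP at equal CO input."""
    q = 6.0
    co = SpecificRates(q_co=q, q_h2=0.0, q_co2=co2_loss_fraction(0) * q,
                       q_etoh=1.0, q_acetate=0.0, q_bdo=0.0, mu=0.0)
    hh = SpecificRates(q_co=q, q_h2=1.4 * q, q_co2=co2_loss_fraction(1.4) * q,
                       q_etoh=2.4, q_acetate=0.0, q_bdo=0.0, mu=0.0)
    m_co = atp_dissipation_analysis(core_model, co, mu=0.0).objective_value
    m_hh = atp_dissipation_analysis(core_model, hh, mu=0.0).objective_value
    assert m_hh > m_co


def test_aor_route_dominates_at_atp_optimum(core_model):
    rates = SpecificRates(q_co=6.0, q_h2=8.4, q_co2=co2_loss_fraction(1.4) * 6,
                          q_etoh=2.4, q_acetate=0.0, q_bdo=0.0, mu=0.0)
    state = atp_dissipation_analysis(core_model, rates, mu=0.0)
    att = ethanol_route_attribution(state, core_model)
    assert att["via_aor"] == pytest.approx(100.0)
    assert att["via_adhe"] == pytest.approx(0.0)


def test_aor_blocked_forces_adhe(core_model):
    fixed = {
        "EX_co": (-6.0, 0.0), "EX_h2": (0.0, 0.0), "EX_co2": (4.0, 0.0),
        "EX_etoh": (1.0, 0.0), "EX_ac": (0.0, 0.0), "EX_bdo": (0.0, 0.0),
        "EX_biomass": (0.0, 0.0),
    }
    state = solve(FBAProblem(model=core_model, objective="ATPM",
                             fixed_fluxes=fixed, zeroed=["AOR"]))
    att = ethanol_route_attribution(state, core_model)
    assert att["via_adhe"] == pytest.approx(100.0)


def test_route_attribution_hand_set_fluxes(core_model):
    state = FluxState(
        fluxes={"AOR": 1.0, "ACALD": 1.0, "EX_etoh": 2.0}, objective_value=0.0,
        status="optimal",
    )
    att = ethanol_route_attribution(state, core_model)
    assert att == {"via_aor": 50.0, "via_adhe": 50.0}


def test_fdred_sources_hand_set_fluxes(core_model):
    state = FluxState(
        fluxes={"CODH": 3.0, HYT_ID: 1.0}, objective_value=0.0, status="optimal"
    )
    src = fdred_source_fractions(state, core_model)
    assert src["from_co_oxidation"] == pytest.approx(75.0)
    assert src["from_h2"] == pytest.approx(25.0)


def test_fdred_sources_pure_conditions(core_model):
    co_only = FluxState(fluxes={"CODH": 2.0}, objective_value=0, status="optimal")
    h2_only = FluxState(fluxes={HYT_ID: 2.0}, objective_value=0, status="optimal")
    assert fdred_source_fractions(co_only, core_model)["from_co_oxidation"] == 100.0
    assert fdred_source_fractions(h2_only, core_model)["from_h2"] == 100.0


def test_fdred_source_shift_with_h2(core_model):
    """The share of reduced ferredoxin from CO oxidation drops when H2 is
    co-utilised (direction of the observed 82% -> 41% shift)."""
    q = 6.0
    co = SpecificRates(q_co=q, q_h2=0.0, q_co2=4.0, q_etoh=1.0,
                       q_acetate=0.0, q_bdo=0.0, mu=0.0)
    hh = SpecificRates(q_co=q, q_h2=1.4 * q, q_co2=co2_loss_fraction(1.4) * q,
                       q_etoh=2.4, q_acetate=0.0, q_bdo=0.0, mu=0.0)
    f_co = fdred_source_fractions(
        atp_dissipation_analysis(core_model, co, mu=0.0), core_model
    )
    f_hh = fdred_source_fractions(
        atp_dissipation_analysis(core_model, hh, mu=0.0), core_model
    )
    assert f_co["from_co_oxidation"] > f_hh["from_co_oxidation"]
    assert f_hh["from_h2"] > f_co["from_h2"]


def test_optimal_growth_on_co_secretes_acetate_not_ethanol(core_model):
    state = optimal_growth_prediction(core_model, {"q_co": 24.0}, 0.0)
    assert state.optimal
    assert state.objective_value > 0
    assert state.fluxes["EX_ac"] > 0.1
    assert state.fluxes["EX_etoh"] == pytest.approx(0.0, abs=1e-6)
    assert state.fluxes["EX_bdo"] == pytest.approx(0.0, abs=1e-6)


def test_optimal_growth_homogeneity_and_capacity(core_model):
    one = optimal_growth_prediction(core_model, {"q_co": 24.0}, 0.0)
    two = optimal_growth_prediction(core_model, {"q_co": 48.0}, 0.0)
    assert two.objective_value == pytest.approx(2 * one.objective_value, rel=1e-6)
    over = optimal_growth_prediction(core_model, {"q_co": 24.0}, 1000.0)
    assert over.status == "infeasible"


def test_problem_validation_errors(core_model):
    with pytest.raises(ValueError, match="unknown reaction"):
        FBAProblem(model=core_model, objective="NOPE")
    with pytest.raises(ValueError, match="sense"):
        FBAProblem(model=core_model, objective="ATPM", sense="sideways")
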