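"""Core network integrity, TSV/SBML round trips, variant behaviour."""

import importlib.resources

import numpy as np
import pytest

from acetogas.fba import FBAProblem, atp_dissipation_analysis, solve
from acetogas.balances import SpecificRates
from acetogas.metabolic_model import (
    FDH_NADPH_ID,
    FHL_ID,
    HYT_ID,
    Metabolite,
    Reaction,
    StoichiometricModel,
    core_acetogen_model,
    load_sbml,
    model_from_tsv,
    model_to_tsv,
    parse_formula,
    save_sbml,
    validate_model,
)
from acetogas.stoich_theory import co2_loss_fraction


def test_core_model_fully_balanced_and_connected(core_model):
    report = validate_model(core_model)
    assert report.element_imbalances == {}
    assert report.charge_imbalances == {}
    assert report.dead_end_metabolites == []
    assert report.ok


def test_core_model_contains_named_scheme_reactions(core_model):
    for rid in (FDH_NADPH_ID, FHL_ID, HYT_ID):
        assert core_model.has_reaction(rid)
    assert core_model.atp_dissipation_id == "ATPM"
    assert core_model.biomass_id == "BIOMASS"


def test_packaged_tsv_matches_code_built_model(core_model):
    data_dir = importlib.resources.files("acetogas") / "data"
    shipped = model_from_tsv(data_dir)
    assert [r.id for r in shipped.reactions] == [r.id for r in core_model.reactions]
    for r in core_model.reactions:
        s = shipped.reaction(r.id)
        assert s.stoichiometry == pytest.approx(r.stoichiometry)
        assert (s.lower_bound, s.upper_bound) == (r.lower_bound, r.upper_bound)


def test_unbalanced_reaction_flagged_with_deltas(core_model):
    model = core_model.copy()
    model.reactions.append(
        Reaction("BROKEN", "unbalanced", {"co_c": -1, "h2o_c": 1})
    )
    model = StoichiometricModel(
        model.metabolites, model.reactions, "ATPM", "BIOMASS"
    )
    report = validate_model(model)
    assert report.element_imbalances["BROKEN"] == {"C": -1.0, "H": 2.0}


def test_deleted_exchange_creates_dead_end(core_model):
    model = core_model.copy()
    model = StoichiometricModel(
        model.metabolites,
        [r for r in model.reactions if r.id != "EX_nh3"],
        "ATPM",
        "BIOMASS",
    )
    # without the ammonia supply the N source cannot be produced
    assert "nh3_c" in validate_model(model).dead_end_metabolites


def test_tsv_round_trip(tmp_path, core_model):
    model_to_tsv(core_model, tmp_path)
    back = model_from_tsv(tmp_path)
    for r in core_model.reactions:
        assert back.reaction(r.id).stoichiometry == pytest.approx(r.stoichiometry)
        assert back.reaction(r.id).tags == r.tags
    for m in core_model.metabolites:
        assert back.metabolite(m.id).formula == pytest.approx(m.formula)
        assert back.metabolite(m.id).charge == m.charge


def test_sbml_round_trip(tmp_path, core_model):
    path = tmp_path / "core.xml"
    save_sbml(core_model, path)
    back = load_sbml(path)
    assert [r.id for r in back.reactions] == [r.id for r in core_model.reactions]
    for r in core_model.reactions:
        b = back.reaction(r.id)
        assert b.stoichiometry == pytest.approx(r.stoichiometry)
        assert (b.lower_bound, b.upper_bound) == (r.lower_bound, r.upper_bound)
    assert validate_model(back).ok
    assert back.atp_dissipation_id == "ATPM"


def test_minimal_sbml_fixture_matrix_matches_hand_matrix(tmp_path):
    """A 3-reaction toy written to SBML reloads to the hand-written matrix."""
    mets = [
        Metabolite("a_c", "A", parse_formula("C"), 0),
        Metabolite("b_c", "B", parse_formula("C"), 0),
    ]
    rxns = [
        Reaction("EX_a", "A in", {"a_c": -1}, -10, 0, frozenset({"exchange"})),
        Reaction("A2B", "A to B", {"a_c": -1, "b_c": 1}, 0, 10),
        Reaction("EX_b", "B out", {"b_c": -1}, 0, 10, frozenset({"exchange"})),
    ]
    toy = StoichiometricModel(mets, rxns)
    path = tmp_path / "toy.xml"
    save_sbml(toy, path)
    back = load_sbml(path)
    S, met_ids, rxn_ids = back.stoichiometric_matrix()
    assert met_ids == ["a_c", "b_c"]
    assert rxn_ids == ["EX_a", "A2B", "EX_b"]
    np.testing.assert_allclose(S, [[-1, -1, 0], [0, 1, -1]])


def test_scheme_requires_named_reaction_ids(tmp_path):
    from acetogas.fba import apply_h2_coupling_scheme

    mets = [Metabolite("a_c", "A", parse_formula("C"), 0)]
    rxns = [Reaction("EX_a", "A", {"a_c": -1}, -10, 10, frozenset({"exchange"}))]
    toy = StoichiometricModel(mets, rxns)
    problem = FBAProblem(model=toy, objective="EX_a")
    with pytest.raises(ValueError, match="requires reaction id"):
        apply_h2_coupling_scheme(problem, 1.0)


@pytest.mark.parametrize("r", [0.0, 1.0, 2.0])
def test_core_model_carries_theoretical_ethanol_flux(core_model, r):
    """Fixing the exchange pattern of the closed-form overall equation is
    feasible, i.e. the network realises the theoretical stoichiometry."""
    q = 6.0
    rates = SpecificRates(
        q_co=q,
        q_h2=r * q,
        q_co2=co2_loss_fraction(r) * q,
        q_etoh=(1 + r) / 6 * q,
        q_acetate=0.0,
        q_bdo=0.0,
        mu=0.0,
    )
    state = atp_dissipation_analysis(core_model, rates, mu=0.0)
    assert state.optimal


def test_metfv_fd_variant_required_under_experimental_pattern():
    """An experimental-style constraint pattern (fixed exchanges plus a
    maintenance requirement near the network's capacity) is satisfiable
    only when the ferredoxin-reducing methylene-THF reductase is active."""
    rates = SpecificRates(
        q_co=6.0, q_h2=0.0, q_co2=4.0, q_etoh=1.0, q_acetate=0.0, q_bdo=0.0, mu=0.0
    )
    m_fd = core_acetogen_model(metfv_variant="fd")
    cap = atp_dissipation_analysis(m_fd, rates, mu=0.0).objective_value
    assert cap > 0

    def constrained(model):
        fixed = {
            "EX_co": (-6.0, 0.0),
            "EX_h2": (0.0, 0.0),
            "EX_co2": (4.0, 0.0),
            "EX_etoh": (1.0, 0.0),
            "EX_ac": (0.0, 0.0),
            "EX_bdo": (0.0, 0.0),
            "EX_biomass": (0.0, 0.0),
            "ATPM": (0.95 * cap, 0.05 * cap),
        }
        return solve(FBAProblem(model=model, objective="ATPM", fixed_fluxes=fixed))

    assert constrained(m_fd).status == "optimal"
    assert constrained(core_acetogen_model(metfv_variant="nadh")).status == "infeasible"


def test_ethanol_producible_without_aor(core_model):
    """Route redundancy: blocking AOR leaves the direct AdhE route open."""
    rates = SpecificRates(
        q_co=6.0, q_h2=0.0, q_co2=4.0, q_etoh=1.0, q_acetate=0.0, q_bdo=0.0, mu=0.0
    )
    problem_fixed = {
        "EX_co": (-6.0, 0.0),
        "EX_h2": (0.0, 0.0),
        "EX_co2": (4.0, 0.0),
        "EX_etoh": (1.0, 0.0),
        "EX_ac": (0.0, 0.0),
        "EX_bdo": (0.0, 0.0),
        "EX_biomass": (0.0, 0.0),
    }
    state = solve(
        FBAProblem(
            model=core_model,
            objective="ATPM",
            fixed_fluxes=problem_fixed,
            zeroed=["AOR"],
        )
    )
    assert state.optimal
    assert state.fluxes["ACALD"] > 0


def test_atp_optimum_agrees_with_independent_solver(tmp_path, core_model):
    """Cross-check: cobrapy solving the exported SBML reproduces the ATP
    dissipation optimum of the in-package LP on the ethanol-only pattern."""
    cobra = pytest.importorskip("cobra")

    path = tmp_path / "core.xml"
    save_sbml(core_model, path)
    cm = cobra.io.read_sbml_model(str(path))
    cm.objective = "ATPM"
    pattern = {"EX_co": -6.0, "EX_h2": 0.0, "EX_co2": 4.0, "EX_etoh": 1.0,
               "EX_ac": 0.0, "EX_bdo": 0.0, "EX_biomass": 0.0}
    for rid, v in pattern.items():
        rxn = cm.reactions.get_by_id(rid)
        rxn.lower_bound = v
        rxn.upper_bound = v
    sol = cm.optimize()

    rates = SpecificRates(q_co=6.0, q_h2=0.0, q_co2=4.0, q_etoh=1.0,
                          q_acetate=0.0, q_bdo=0.0, mu=0.0)
    ours = atp_dissipation_analysis(core_model, rates, mu=0.0)
    assert sol.status == "optimal" and ours.optimal
    assert ours.objective_value == pytest.approx(sol.objective_value, abs=1e-6)


def test_invalid_variant_and_stoichiometry_guards():
    with pytest.raises(ValueError):
        core_acetogen_model(metfv_variant="nope")
    with pytest.raises(ValueError):
        core_acetogen_model(rnf_h_per_fd=0.5)
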