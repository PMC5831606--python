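"""Core acetogen central-metabolism stoichiometric network.

A ~30-reaction, elementally and charge-balanced model of the Wood-Ljungdahl
pathway and associated energy metabolism of a CO/H2-fermenting acetogen:

* CO dehydrogenase (CO oxidation to CO2 with ferredoxin reduction) and the
  CODH/ACS carbonyl branch;
* the methyl branch: formate -> formyl-THF (ATP) -> methenyl- ->
  methylene- -> methyl-THF, with the methylene-THF reductase shipped in two
  selectable variants (electron-bifurcating, ferredoxin-reducing; or plain
  NADH-dependent);
* three routes into formate: the redox-consuming formate dehydrogenase
  (``rxn00103_c0``, NADPH), the formate-H2 lyase activity reducing CO2
  directly with H2 (``rxn08518_c0``), and H2-driven ferredoxin/NADPH
  generation by the electron-bifurcating hydrogenase (``leq000001``);
* Pta-AckA (substrate-level ATP), the direct AdhE ethanol route, the
  AOR route (acetate + Fd_red -> acetaldehyde) plus alcohol dehydrogenase;
* pyruvate:ferredoxin oxidoreductase and the 2,3-butanediol branch;
* Nfn transhydrogenase, the Rnf proton pump, ATP synthase, an ATP
  maintenance (dissipation) reaction and a one-C-mol biomass drain.

The three ModelSEED-style ids above are kept verbatim so constraint schemes
written against the core network apply unchanged to a genome-scale model
that uses the same ids. Cofactor carriers use full chemical formulas so the
validator can check element, charge and hence electron conservation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "ValidationReport",
    "core_acetogen_model",
    "validate_model",
    "model_to_tsv",
    "model_from_tsv",
    "save_sbml",
    "load_sbml",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)([0-9]*\.?[0-9]*)")


def parse_formula(formula: str) -> dict[str, float]:
    """'C21H26N7O14P2' -> {'C': 21, 'H': 26, ...}. Empty string -> {}."""
    atoms: dict[str, float] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        atoms[m.group(1)] = atoms.get(m.group(1), 0.0) + float(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return atoms


def format_formula(atoms: dict[str, float]) -> str:
    def num(x: float) -> str:
        return "" if x == 1 else (f"{x:g}")

    return "".join(f"{el}{num(n)}" for el, n in sorted(atoms.items()) if n)


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str
    formula: dict[str, float]
    charge: float = 0.0
    compartment: str = "c"


@dataclass
class Reaction:
    id: str
    name: str
    stoichiometry: dict[str, float]  # metabolite id -> coefficient
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(f"{self.id}: lb > ub")
        self.tags = frozenset(self.tags)

    @property
    def is_exchange(self) -> bool:
        return "exchange" in self.tags

    def equation(self) -> str:
        def side(items):
            return " + ".join(
                (f"{abs(c):g} " if abs(c) != 1 else "") + m for m, c in items
            )

        subs = [(m, c) for m, c in self.stoichiometry.items() if c < 0]
        prods = [(m, c) for m, c in self.stoichiometry.items() if c > 0]
        arrow = "<=>" if self.lower_bound < 0 else "-->"
        return f"{side(subs)} {arrow} {side(prods)}"


class StoichiometricModel:
    """Reaction network with bounds, ready for LP-based flux analysis."""

    def __init__(
        self,
        metabolites: list[Metabolite],
        reactions: list[Reaction],
        atp_dissipation_id: str | None = None,
        biomass_id: str | None = None,
    ):
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}
        if len(self._met_index) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")
        if len(self._rxn_index) != len(self.reactions):
            raise ValueError("duplicate reaction ids")
        for r in self.reactions:
            for m in r.stoichiometry:
                if m not in self._met_index:
                    raise ValueError(f"{r.id} references unknown metabolite {m}")
        self.atp_dissipation_id = atp_dissipation_id
        self.biomass_id = biomass_id

    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def stoichiometric_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        met_ids = [m.id for m in self.metabolites]
        rxn_ids = [r.id for r in self.reactions]
        pos = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, r in enumerate(self.reactions):
            for m, c in r.stoichiometry.items():
                S[pos[m], j] = c
        return S, met_ids, rxn_ids

    def bounds(self) -> list[tuple[float, float]]:
        return [(r.lower_bound, r.upper_bound) for r in self.reactions]

    def copy(self) -> "StoichiometricModel":
        return StoichiometricModel(
            self.metabolites,
            [
                Reaction(
                    r.id, r.name, dict(r.stoichiometry), r.lower_bound,
                    r.upper_bound, r.tags,
                )
                for r in self.reactions
            ],
            self.atp_dissipation_id,
            self.biomass_id,
        )


@dataclass
class ValidationReport:
    """Imbalances and structural problems found by :func:`validate_model`."""

    element_imbalances: dict[str, dict[str, float]] = field(default_factory=dict)
    charge_imbalances: dict[str, float] = field(default_factory=dict)
    dead_end_metabolites: list[str] = field(default_factory=list)
    bound_errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.element_imbalances
            or self.charge_imbalances
            or self.dead_end_metabolites
            or self.bound_errors
        )


def validate_model(model: StoichiometricModel, tol: float = 1e-9) -> ValidationReport:
    """Check element/charge balance of internal reactions and connectivity.

    Exchange-tagged reactions are exempt from balancing (they create or
    destroy matter by design). A metabolite is a dead end if no reaction can
    produce it or none can consume it given the bounds.
    """
    report = ValidationReport()
    for r in model.reactions:
        if r.is_exchange:
            continue
        atoms: dict[str, float] = {}
        charge = 0.0
        for mid, coeff in r.stoichiometry.items():
            met = model.metabolite(mid)
            charge += coeff * met.charge
            for el, n in met.formula.items():
                atoms[el] = atoms.get(el, 0.0) + coeff * n
        bad = {el: v for el, v in atoms.items() if abs(v) > tol}
        if bad:
            report.element_imbalances[r.id] = bad
        if abs(charge) > tol:
            report.charge_imbalances[r.id] = charge

    producible: set[str] = set()
    consumable: set[str] = set()
    for r in model.reactions:
        for mid, coeff in r.stoichiometry.items():
            if coeff > 0:
                if r.upper_bound > 0:
                    producible.add(mid)
                if r.lower_bound < 0:
                    consumable.add(mid)
            elif coeff < 0:
                if r.upper_bound > 0:
                    consumable.add(mid)
                if r.lower_bound < 0:
                    producible.add(mid)
    for m in model.metabolites:
        if m.id not in producible or m.id not in consumable:
            report.dead_end_metabolites.append(m.id)
    return report


# --------------------------------------------------------------------------
# The packaged core network
# --------------------------------------------------------------------------

_METS: list[tuple[str, str, str, float]] = [
    # id, name, formula, charge (cytosol unless noted)
    ("co_c", "carbon monoxide", "CO", 0),
    ("co2_c", "carbon dioxide", "CO2", 0),
    ("h2_c", "hydrogen", "H2", 0),
    ("h2o_c", "water", "H2O", 0),
    ("h_c", "proton (cytosol)", "H", 1),
    ("h_e", "proton (periplasm)", "H", 1),
    ("nh3_c", "ammonia", "H3N", 0),
    ("fd_ox_c", "oxidised ferredoxin", "Fd", 0),
    ("fd_red_c", "reduced ferredoxin", "Fd", -2),
    ("nad_c", "NAD+", "C21H26N7O14P2", -1),
    ("nadh_c", "NADH", "C21H27N7O14P2", -2),
    ("nadp_c", "NADP+", "C21H25N7O17P3", -3),
    ("nadph_c", "NADPH", "C21H26N7O17P3", -4),
    ("atp_c", "ATP", "C10H12N5O13P3", -4),
    ("adp_c", "ADP", "C10H12N5O10P2", -3),
    ("pi_c", "phosphate", "HO4P", -2),
    ("for_c", "formate", "CHO2", -1),
    ("thf_c", "tetrahydrofolate", "C19H21N7O6", -2),
    ("10fthf_c", "10-formyl-THF", "C20H21N7O7", -2),
    ("methf_c", "5,10-methenyl-THF", "C20H20N7O6", -1),
    ("mlthf_c", "5,10-methylene-THF", "C20H21N7O6", -2),
    ("5mthf_c", "5-methyl-THF", "C20H24N7O6", -1),
    ("coa_c", "coenzyme A", "C21H32N7O16P3S", -4),
    ("accoa_c", "acetyl-CoA", "C23H34N7O17P3S", -4),
    ("actp_c", "acetyl phosphate", "C2H3O5P", -2),
    ("ac_c", "acetate", "C2H3O2", -1),
    ("acald_c", "acetaldehyde", "C2H4O", 0),
    ("etoh_c", "ethanol", "C2H6O", 0),
    ("pyr_c", "pyruvate", "C3H3O3", -1),
    ("alac_c", "2-acetolactate", "C5H7O4", -1),
    ("actn_c", "acetoin", "C4H8O2", 0),
    ("bdo_c", "2,3-butanediol", "C4H10O2", 0),
    ("biomass_c", "biomass (1 C-mol)", "CH1.8N0.2O0.5", 0),
]

ATP_DISSIPATION_ID = "ATPM"
BIOMASS_ID = "BIOMASS"
MTHFR_FD_ID = "MTHFR_fd"
MTHFR_NADH_ID = "MTHFR_nadh"
FDH_NADPH_ID = "rxn00103_c0"
FHL_ID = "rxn08518_c0"
HYT_ID = "leq000001"


def _biomass_met_formula() -> dict[str, float]:
    return {"C": 1.0, "H": 1.8, "O": 0.5, "N": 0.2}


def core_acetogen_model(
    metfv_variant: str = "fd",
    rnf_h_per_fd: float = 2.0,
    atpase_h_per_atp: float = 4.0,
    gam_atp: float = 2.0,
) -> StoichiometricModel:
    """Build the packaged core network.

    Parameters
    ----------
    metfv_variant:
        Which methylene-THF reductase is active: ``'fd'`` (electron-
        bifurcating, ferredoxin-reducing; the physiologically supported
        form), ``'nadh'`` (plain NADH-dependent), or ``'both'``. Both
        reactions are always present; the inactive one is bounded to zero.
    rnf_h_per_fd:
        Protons translocated by Rnf per reduced ferredoxin oxidised.
    atpase_h_per_atp:
        Protons imported by ATP synthase per ATP formed (one of which is
        consumed chemically).
    gam_atp:
        Growth-associated ATP cost per C-mol biomass.
    """
    if metfv_variant not in ("fd", "nadh", "both"):
        raise ValueError("metfv_variant must be 'fd', 'nadh' or 'both'")
    if rnf_h_per_fd <= 1 or atpase_h_per_atp <= 1:
        raise ValueError("proton stoichiometries must exceed 1")

    mets = [
        Metabolite(
            mid,
            name,
            _biomass_met_formula() if mid == "biomass_c" else parse_formula(f),
            charge,
            "e" if mid.endswith("_e") else "c",
        )
        for mid, name, f, charge in _METS
    ]

    def rxn(rid, name, stoich, lb=0.0, ub=1000.0, tags=()):
        return Reaction(rid, name, stoich, lb, ub, frozenset(tags))

    t = rnf_h_per_fd
    n = atpase_h_per_atp
    g = gam_atp
    rxns = [
        # exchanges: positive flux = secretion, negative = uptake
        rxn("EX_co", "CO exchange", {"co_c": -1}, -1000, 1000, ("exchange",)),
        rxn("EX_h2", "H2 exchange", {"h2_c": -1}, -1000, 1000, ("exchange",)),
        rxn("EX_co2", "CO2 exchange", {"co2_c": -1}, -1000, 1000, ("exchange",)),
        rxn("EX_etoh", "ethanol exchange", {"etoh_c": -1}, 0, 1000, ("exchange",)),
        rxn("EX_ac", "acetate exchange", {"ac_c": -1}, 0, 1000, ("exchange",)),
        rxn("EX_bdo", "2,3-BDO exchange", {"bdo_c": -1}, 0, 1000, ("exchange",)),
        rxn("EX_biomass", "biomass drain", {"biomass_c": -1}, 0, 1000, ("exchange",)),
        rxn("EX_nh3", "NH3 uptake", {"nh3_c": -1}, -1000, 0, ("exchange",)),
        rxn("EX_h2o", "water exchange", {"h2o_c": -1}, -1000, 1000, ("exchange",)),
        rxn("EX_h", "proton exchange", {"h_c": -1}, -1000, 1000, ("exchange",)),
        # carbonyl branch and CO oxidation
        rxn(
            "CODH",
            "CO dehydrogenase",
            {"co_c": -1, "h2o_c": -1, "fd_ox_c": -1,
             "co2_c": 1, "fd_red_c": 1, "h_c": 2},
            -1000,
        ),
        rxn(
            "ACS",
            "acetyl-CoA synthase (CODH/ACS)",
            {"co_c": -1, "5mthf_c": -1, "coa_c": -1,
             "accoa_c": 1, "thf_c": 1, "h_c": 1},
        ),
        # routes into formate
        rxn(
            FDH_NADPH_ID,
            "formate dehydrogenase (NADPH, redox-consuming)",
            {"co2_c": -1, "nadph_c": -1, "for_c": 1, "nadp_c": 1},
        ),
        rxn(
            FHL_ID,
            "formate-H2 lyase (direct CO2 reduction with H2)",
            {"co2_c": -1, "h2_c": -1, "for_c": 1, "h_c": 1},
        ),
        rxn(
            HYT_ID,
            "electron-bifurcating hydrogenase (Fd_red + NADPH from 2 H2)",
            {"h2_c": -2, "fd_ox_c": -1, "nadp_c": -1,
             "fd_red_c": 1, "nadph_c": 1, "h_c": 3},
        ),
        # methyl branch of the Wood-Ljungdahl pathway
        rxn(
            "FTHFS",
            "formyl-THF synthetase",
            {"for_c": -1, "thf_c": -1, "atp_c": -1,
             "10fthf_c": 1, "adp_c": 1, "pi_c": 1},
        ),
        rxn(
            "MTHFC",
            "methenyl-THF cyclohydrolase",
            {"10fthf_c": -1, "h_c": -1, "methf_c": 1, "h2o_c": 1},
        ),
        rxn(
            "MTHFD",
            "methylene-THF dehydrogenase (NADH)",
            {"methf_c": -1, "nadh_c": -1, "mlthf_c": 1, "nad_c": 1},
        ),
        rxn(
            MTHFR_FD_ID,
            "methylene-THF reductase (electron-bifurcating, Fd-reducing)",
            {"mlthf_c": -1, "nadh_c": -2, "fd_ox_c": -1, "h_c": -1,
             "5mthf_c": 1, "nad_c": 2, "fd_red_c": 1},
            0,
            1000 if metfv_variant in ("fd", "both") else 0,
            ("variant:metfv",),
        ),
        rxn(
            MTHFR_NADH_ID,
            "methylene-THF reductase (NADH only)",
            {"mlthf_c": -1, "nadh_c": -1, "h_c": -2, "5mthf_c": 1, "nad_c": 1},
            0,
            1000 if metfv_variant in ("nadh", "both") else 0,
            ("variant:metfv",),
        ),
        # acetate and ethanol
        rxn(
            "PTA",
            "phosphotransacetylase",
            {"accoa_c": -1, "pi_c": -1, "actp_c": 1, "coa_c": 1},
            -1000,
        ),
        rxn(
            "ACKA",
            "acetate kinase",
            {"actp_c": -1, "adp_c": -1, "ac_c": 1, "atp_c": 1},
            -1000,
        ),
        rxn(
            "ACALD",
            "acetaldehyde dehydrogenase (AdhE, acylating)",
            {"accoa_c": -1, "nadh_c": -1, "h_c": -1,
             "acald_c": 1, "coa_c": 1, "nad_c": 1},
            -1000,
        ),
        rxn(
            "AOR",
            "acetaldehyde:ferredoxin oxidoreductase",
            {"ac_c": -1, "fd_red_c": -1, "h_c": -3,
             "acald_c": 1, "h2o_c": 1, "fd_ox_c": 1},
        ),
        rxn(
            "ADH",
            "alcohol dehydrogenase",
            {"acald_c": -1, "nadh_c": -1, "h_c": -1, "etoh_c": 1, "nad_c": 1},
            -1000,
        ),
        # pyruvate node and 2,3-BDO branch
        rxn(
            "PFOR",
            "pyruvate:ferredoxin oxidoreductase (synthase direction)",
            {"accoa_c": -1, "co2_c": -1, "fd_red_c": -1, "h_c": -1,
             "pyr_c": 1, "coa_c": 1, "fd_ox_c": 1},
        ),
        rxn(
            "ALS",
            "acetolactate synthase",
            {"pyr_c": -2, "h_c": -1, "alac_c": 1, "co2_c": 1},
        ),
        rxn(
            "ALDC",
            "acetolactate decarboxylase",
            {"alac_c": -1, "h_c": -1, "actn_c": 1, "co2_c": 1},
        ),
        rxn(
            "BDH",
            "2,3-butanediol dehydrogenase (NADPH)",
            {"actn_c": -1, "nadph_c": -1, "h_c": -1, "bdo_c": 1, "nadp_c": 1},
        ),
        # redox and energy conservation
        rxn(
            "NFN",
            "Nfn transhydrogenase (electron-bifurcating)",
            {"fd_red_c": -1, "nadh_c": -1, "nadp_c": -2, "h_c": -1,
             "fd_ox_c": 1, "nad_c": 1, "nadph_c": 2},
            -1000,
        ),
        rxn(
            "RNF",
            "Rnf ferredoxin:NAD+ oxidoreductase (proton pumping)",
            {"fd_red_c": -1, "nad_c": -1, "h_c": -(t + 1),
             "fd_ox_c": 1, "nadh_c": 1, "h_e": t},
        ),
        rxn(
            "ATPS",
            "ATP synthase",
            {"adp_c": -1, "pi_c": -1, "h_e": -n,
             "atp_c": 1, "h2o_c": 1, "h_c": n - 1},
        ),
        rxn(
            ATP_DISSIPATION_ID,
            "ATP maintenance dissipation",
            {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
            0,
            1000,
            ("maintenance",),
        ),
        rxn(
            BIOMASS_ID,
            "biomass synthesis (1 C-mol drain)",
            {"accoa_c": -0.5, "nh3_c": -0.2, "nadph_c": -0.1, "h_c": -0.1 + g,
             "atp_c": -g, "h2o_c": -g,
             "biomass_c": 1, "coa_c": 0.5, "nadp_c": 0.1,
             "adp_c": g, "pi_c": g},
        ),
    ]
    # merge the +g h_c product with the -0.1 h_c substrate into one coefficient
    bio = rxns[-1].stoichiometry
    bio["h_c"] = g - 0.1

    return StoichiometricModel(
        mets, rxns, atp_dissipation_id=ATP_DISSIPATION_ID, biomass_id=BIOMASS_ID
    )


# --------------------------------------------------------------------------
# TSV packaging
# --------------------------------------------------------------------------


def model_to_tsv(model: StoichiometricModel, directory) -> None:
    """Write reactions.tsv (id, name, equation, lb, ub, tags) and
    metabolites.tsv (id, name, formula, charge, compartment)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "metabolites.tsv", "w") as fh:
        fh.write("id\tname\tformula\tcharge\tcompartment\n")
        for m in model.metabolites:
            fh.write(
                f"{m.id}\t{m.name}\t{format_formula(m.formula)}\t"
                f"{m.charge:g}\t{m.compartment}\n"
            )
    with open(d / "reactions.tsv", "w") as fh:
        fh.write("id\tname\tequation\tlower_bound\tupper_bound\ttags\n")
        for r in model.reactions:
            fh.write(
                f"{r.id}\t{r.name}\t{_equation_tsv(r)}\t{r.lower_bound:g}\t"
                f"{r.upper_bound:g}\t{','.join(sorted(r.tags))}\n"
            )


def _equation_tsv(r: Reaction) -> str:
    return " ".join(f"{c:g}:{m}" for m, c in sorted(r.stoichiometry.items()))


def _parse_equation_tsv(s: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for token in s.split():
        c, m = token.split(":", 1)
        out[m] = float(c)
    return out


def model_from_tsv(directory) -> StoichiometricModel:
    d = Path(directory)
    mets = []
    with open(d / "metabolites.tsv") as fh:
        next(fh)
        for line in fh:
            mid, name, formula, charge, comp = line.rstrip("\n").split("\t")
            mets.append(
                Metabolite(mid, name, parse_formula(formula), float(charge), comp)
            )
    rxns = []
    atp_id = bio_id = None
    with open(d / "reactions.tsv") as fh:
        next(fh)
        for line in fh:
            rid, name, eq, lb, ub, tags = line.rstrip("\n").split("\t")
            tagset = frozenset(t for t in tags.split(",") if t)
            rxns.append(
                Reaction(rid, name, _parse_equation_tsv(eq), float(lb), float(ub), tagset)
            )
            if "maintenance" in tagset or rid == ATP_DISSIPATION_ID:
                atp_id = rid
            if rid == BIOMASS_ID:
                bio_id = rid
    return StoichiometricModel(mets, rxns, atp_id, bio_id)


# --------------------------------------------------------------------------
# SBML I/O (Level 3 + fbc)
# --------------------------------------------------------------------------


def _notes(text: str) -> str:
    return (
        f"<body xmlns='http://www.w3.org/1999/xhtml'><p>{text}</p></body>"
    )


def save_sbml(model: StoichiometricModel, path) -> None:
    """Write SBML Level 3 with fbc bounds.

    Metabolite and reaction ids get the conventional ``M_``/``R_`` prefixes
    (SBML SIds cannot start with a digit); non-integer formulas (the C-mol
    biomass pseudo-species) travel in species notes since fbc chemical
    formulas must have integer counts.
    """
    import libsbml

    doc = libsbml.SBMLDocument(3, 1)
    doc.enablePackage(libsbml.FbcExtension.getXmlnsL3V1V2(), "fbc", True)
    doc.setPackageRequired("fbc", False)
    sm = doc.createModel("core_acetogen")
    mplug = sm.getPlugin("fbc")
    mplug.setStrict(True)
    for comp_id in ("c", "e"):
        comp = sm.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    def make_param(pid: str, value: float) -> str:
        p = sm.createParameter()
        p.setId(pid)
        p.setValue(value)
        p.setConstant(True)
        return pid

    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(f"M_{m.id}")
        sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        splug = sp.getPlugin("fbc")
        splug.setCharge(int(m.charge) if m.charge == int(m.charge) else 0)
        integral = all(n == int(n) for n in m.formula.values())
        if integral:
            splug.setChemicalFormula(format_formula(m.formula))
        else:
            sp.setNotes(_notes(f"formula: {format_formula(m.formula)}"))
    seen_bounds: dict[float, str] = {}
    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId(f"R_{r.id}")
        rx.setName(r.name)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        for mid, coeff in r.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(f"M_{mid}")
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        rplug = rx.getPlugin("fbc")
        for bound, setter in ((r.lower_bound, rplug.setLowerFluxBound),
                              (r.upper_bound, rplug.setUpperFluxBound)):
            if bound not in seen_bounds:
                seen_bounds[bound] = make_param(
                    f"bound_{len(seen_bounds)}", bound
                )
            setter(seen_bounds[bound])
        if r.tags:
            rx.setNotes(_notes(f"tags: {','.join(sorted(r.tags))}"))
    libsbml.writeSBMLToFile(doc, str(path))


def load_sbml(path) -> StoichiometricModel:
    """Read an SBML (Level 3 fbc, or Level 2 with kinetic-law bounds) model.

    Reactions without explicit bounds default to [-1000, 1000] (reversible)
    or [0, 1000], with a warning. Species without a formula get an empty
    formula, which exempts them from element balancing but not from the
    stoichiometric matrix.
    """
    import warnings

    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ValueError(
            f"SBML parse failure: {doc.getErrorLog().toString()}"
        )
    sm = doc.getModel()
    if sm is None:
        raise ValueError("SBML file contains no model")
    def strip(sid: str, prefix: str) -> str:
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    mets = []
    for sp in sm.getListOfSpecies():
        splug = sp.getPlugin("fbc")
        formula = ""
        charge = 0.0
        if splug is not None and splug.isSetChemicalFormula():
            formula = splug.getChemicalFormula()
        if splug is not None and splug.isSetCharge():
            charge = float(splug.getCharge())
        if not formula and sp.isSetNotes():
            m = re.search(r"formula:\s*([A-Za-z0-9.]+)", sp.getNotesString())
            if m:
                formula = m.group(1)
        mets.append(
            Metabolite(
                strip(sp.getId(), "M_"),
                sp.getName() or sp.getId(),
                parse_formula(formula) if formula else {},
                charge,
                sp.getCompartment() or "c",
            )
        )
    params = {
        p.getId(): p.getValue() for p in sm.getListOfParameters()
    }
    rxns = []
    atp_id = bio_id = None
    for rx in sm.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rx.getListOfReactants():
            mid = strip(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for ref in rx.getListOfProducts():
            mid = strip(ref.getSpecies(), "M_")
            stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        rplug = rx.getPlugin("fbc")
        lb = ub = None
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lb = params.get(rplug.getLowerFluxBound())
            if rplug.isSetUpperFluxBound():
                ub = params.get(rplug.getUpperFluxBound())
        if lb is None or ub is None:
            warnings.warn(
                f"reaction {rx.getId()} has no flux bounds; defaulting to "
                f"[{-1000 if rx.getReversible() else 0}, 1000]",
                stacklevel=2,
            )
            lb = -1000.0 if rx.getReversible() else 0.0
            ub = 1000.0
        tags: set[str] = set()
        if rx.isSetNotes():
            notes = rx.getNotesString()
            m = re.search(r"tags:\s*([\w:,-]+)", notes)
            if m:
                tags = set(m.group(1).split(","))
        if len(stoich) == 1 and not tags:
            tags.add("exchange")
        rid = strip(rx.getId(), "R_")
        rxns.append(
            Reaction(rid, rx.getName() or rid, stoich, lb, ub, frozenset(tags))
        )
        if "maintenance" in tags or rid == ATP_DISSIPATION_ID:
            atp_id = rid
        if rid == BIOMASS_ID:
            bio_id = rid
    return StoichiometricModel(mets, rxns, atp_id, bio_id)
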