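"""Deterministic synthetic fixtures: toy networks, knowledge graphs,
ground-truth kinetic and thermodynamic parameters, and simulated proteomics.

Three network variants are provided:

* ``chain``                 linear uptake -> biomass (single mode)
* ``branched``              one uptake feeding a biomass branch and a
                            secretion branch (exactly two modes)
* ``respirofermentative``   glucose fed either to a high-yield, enzymatically
                            expensive respiratory route (consuming oxygen) or
                            to a low-yield, cheap fermentative route secreting
                            acetate — the minimal overflow-metabolism topology
                            whose growth/yield Pareto front has two modes.

Stoichiometries use small integers so brute-force oracles stay exact, and
every random table draws from its own named generator derived from the seed,
so adding a fixture never perturbs existing ones.  The networks target
testability, not biological realism: fluxes and growth rates are in model
units and are not calibrated to measured E. coli physiology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MetabolicModel
from .graph import KnowledgeGraph
from .ec import TurnoverSet, ECModel, build_ec_model, DEFAULT_TRANSPORTER_KCAT
from .kcatfit import ConditionSpec, compute_reference_fluxes
from .thermo import ThermoParameterSet

__all__ = [
    "ToyWorld",
    "make_toy_network",
    "make_ec_model",
    "default_proteomics_conditions",
    "perturb_turnovers",
    "simulate_proteomics",
    "simulate_thermo_params",
]


@dataclass
class ToyWorld:
    model: MetabolicModel
    graph: KnowledgeGraph
    true_kcat: TurnoverSet
    masses: dict
    seed: int
    variant: str
    thermo: ThermoParameterSet | None = None


def _rng(seed: int, table: str) -> np.random.Generator:
    """A named child generator so each table is independent of the others."""
    return np.random.default_rng(np.random.SeedSequence([seed, abs(hash(table)) % 2**31]))


def _model_from_reactions(mets, reactions, objective):
    rxn_ids = [r[0] for r in reactions]
    S = np.zeros((len(mets), len(rxn_ids)))
    lb = np.zeros(len(rxn_ids))
    ub = np.zeros(len(rxn_ids))
    midx = {m: i for i, m in enumerate(mets)}
    for j, (rid, stoich, lo, hi) in enumerate(reactions):
        for m, coef in stoich.items():
            S[midx[m], j] = coef
        lb[j], ub[j] = lo, hi
    m = MetabolicModel(list(mets), rxn_ids, S, lb, ub, dict(objective))
    m.validate()
    return m


def _monomer(graph, protein, polypeptide, gene, mass):
    graph.add_node(polypeptide, "polypeptide", molecular_mass=mass)
    graph.add_node(gene, "gene")
    graph.add_node(protein, "protein")
    graph.add_edge(gene, polypeptide, "coding")
    graph.add_edge(protein, polypeptide, "subunit_composition", stoichiometry=1)


def make_toy_network(variant: str, seed: int = 0) -> ToyWorld:
    """Build a deterministic toy world for the requested network variant."""
    if variant == "chain":
        model = _model_from_reactions(
            ["glc_e", "glc_c"],
            [
                ("EX_glc_e", {"glc_e": -1}, -10.0, 1000.0),
                ("GLCt", {"glc_e": -1, "glc_c": 1}, 0.0, 1000.0),
                ("BIOMASS", {"glc_c": -1}, 0.0, 1000.0),
            ],
            {"BIOMASS": 1.0},
        )
        graph = KnowledgeGraph()
        graph.add_node("GLCt", "reaction")
        graph.add_node("BIOMASS", "reaction")
        _monomer(graph, "E_GLCt", "pp_glcT", "g_glcT", 100.0)
        graph.add_edge("E_GLCt", "GLCt", "catalysis")
        kcats = TurnoverSet(
            {("GLCt", "fwd"): DEFAULT_TRANSPORTER_KCAT},
            {("GLCt", "fwd"): "default_transporter"},
            subunit_multiplier_applied=False,
        )
        masses = {"E_GLCt": 100.0}
        return ToyWorld(model, graph, kcats, masses, seed, variant)

    if variant == "branched":
        model = _model_from_reactions(
            ["a_e", "a_c", "c_c", "c_e"],
            [
                ("EX_a_e", {"a_e": -1}, -10.0, 1000.0),
                ("At", {"a_e": -1, "a_c": 1}, 0.0, 1000.0),
                ("BIOMASS", {"a_c": -1}, 0.0, 1000.0),
                ("RC", {"a_c": -1, "c_c": 1}, 0.0, 1000.0),
                ("Ct", {"c_c": -1, "c_e": 1}, 0.0, 1000.0),
                ("EX_c_e", {"c_e": -1}, 0.0, 1000.0),
            ],
            {"BIOMASS": 1.0},
        )
        graph = KnowledgeGraph()
        for r in ("At", "RC", "BIOMASS"):
            graph.add_node(r, "reaction")
        _monomer(graph, "E_At", "pp_at", "g_at", 100.0)
        _monomer(graph, "E_RC", "pp_rc", "g_rc", 100.0)
        graph.add_edge("E_At", "At", "catalysis")
        graph.add_edge("E_RC", "RC", "catalysis")
        kcats = TurnoverSet(
            {
                ("At", "fwd"): DEFAULT_TRANSPORTER_KCAT,
                ("RC", "fwd"): 100.0,
            },
            {("At", "fwd"): "default_transporter", ("RC", "fwd"): "measured"},
        )
        masses = {"E_At": 100.0, "E_RC": 100.0}
        return ToyWorld(model, graph, kcats, masses, seed, variant)

    if variant == "respirofermentative":
        model = _model_from_reactions(
            ["glc_e", "glc_c", "o2_e", "o2_c", "ac_c", "ac_e", "atp_c"],
            [
                ("EX_glc_e", {"glc_e": -1}, -1000.0, 1000.0),
                ("EX_o2_e", {"o2_e": -1}, -1000.0, 0.0),
                ("EX_ac_e", {"ac_e": -1}, 0.0, 1000.0),
                ("GLCpts", {"glc_e": -1, "glc_c": 1}, 0.0, 1000.0),
                ("O2t", {"o2_e": -1, "o2_c": 1}, 0.0, 1000.0),
                ("ACt", {"ac_c": -1, "ac_e": 1}, 0.0, 1000.0),
                # respiration: high ATP yield, slow (expensive) enzyme
                ("RESP", {"glc_c": -1, "o2_c": -2, "atp_c": 10}, 0.0, 1000.0),
                # fermentation: low ATP yield, fast (cheap) enzyme, secretes acetate
                ("FERM", {"glc_c": -1, "atp_c": 2, "ac_c": 2}, 0.0, 1000.0),
                ("BIOMASS", {"atp_c": -50}, 0.0, 1000.0),
                ("ATPM", {"atp_c": -1}, 0.0, 1000.0),
            ],
            {"BIOMASS": 1.0},
        )
        graph = KnowledgeGraph()
        for r in ("GLCpts", "O2t", "ACt", "RESP", "FERM", "BIOMASS", "ATPM"):
            graph.add_node(r, "reaction")
        _monomer(graph, "E_GLCpts", "pp_ptsG", "g_ptsG", 100.0)
        _monomer(graph, "E_O2t", "pp_o2t", "g_o2t", 100.0)
        _monomer(graph, "E_ACt", "pp_act", "g_act", 100.0)
        # respiratory complex: 2 x 40 kDa + 1 x 20 kDa (mass 100 kDa, 3 chains)
        graph.add_node("pp_respA", "polypeptide", molecular_mass=40.0)
        graph.add_node("pp_respB", "polypeptide", molecular_mass=20.0)
        graph.add_node("g_respA", "gene")
        graph.add_node("g_respB", "gene")
        graph.add_node("E_RESP", "protein")
        graph.add_edge("g_respA", "pp_respA", "coding")
        graph.add_edge("g_respB", "pp_respB", "coding")
        graph.add_edge("E_RESP", "pp_respA", "subunit_composition", stoichiometry=2)
        graph.add_edge("E_RESP", "pp_respB", "subunit_composition", stoichiometry=1)
        # fermentation: primary isozyme fermA, curated-secondary isozyme fermB
        _monomer(graph, "E_FERM1", "pp_fermA", "g_fermA", 100.0)
        _monomer(graph, "E_FERM2", "pp_fermB", "g_fermB", 100.0)
        graph.add_edge("E_GLCpts", "GLCpts", "catalysis")
        graph.add_edge("E_O2t", "O2t", "catalysis")
        graph.add_edge("E_ACt", "ACt", "catalysis")
        graph.add_edge("E_RESP", "RESP", "catalysis")
        graph.add_edge("E_FERM1", "FERM", "catalysis", catalysis_class="primary")
        graph.add_edge("E_FERM2", "FERM", "catalysis", catalysis_class="secondary")
        kcats = TurnoverSet(
            {
                ("GLCpts", "fwd"): DEFAULT_TRANSPORTER_KCAT,
                ("O2t", "fwd"): 100.0,
                ("ACt", "fwd"): 100.0,
                ("RESP", "fwd"): 1.0,
                ("FERM", "fwd"): 200.0,
            },
            {
                ("GLCpts", "fwd"): "default_transporter",
                ("O2t", "fwd"): "measured",
                ("ACt", "fwd"): "measured",
                ("RESP", "fwd"): "measured",
                ("FERM", "fwd"): "measured",
            },
            subunit_multiplier_applied=False,
        )
        masses = {
            "E_GLCpts": 100.0,
            "E_O2t": 100.0,
            "E_ACt": 100.0,
            "E_RESP": 100.0,
            "E_FERM1": 100.0,
            "E_FERM2": 100.0,
        }
        return ToyWorld(model, graph, kcats, masses, seed, variant)

    raise ValueError(f"unknown toy network variant {variant!r}")


def make_ec_model(
    world: ToyWorld,
    etot: float = 0.285,
    sigma: float = 1.0,
    turnovers: TurnoverSet | None = None,
) -> ECModel:
    """Enzyme-constrained model of a toy world (true kcats by default)."""
    return build_ec_model(
        world.model,
        world.graph,
        turnovers if turnovers is not None else world.true_kcat,
        masses=None,  # recurse masses from the graph
        etot=etot,
        sigma=sigma,
    )


def default_proteomics_conditions(world: ToyWorld) -> list:
    """Eight growth conditions for the respirofermentative world.

    Four aerobic conditions with acetate export blocked (forcing the
    respiratory route) and four anaerobic conditions (forcing fermentation),
    at increasing growth rates; each condition has a unique flux distribution
    at its growth rate, so reference fluxes do not depend on the turnover
    parameters used to compute them.
    """
    if world.variant != "respirofermentative":
        raise ValueError("proteomics conditions are defined for the "
                         "respirofermentative variant")
    conds = []
    for i, g in enumerate((0.8, 1.2, 1.6, 2.0)):
        conds.append(
            ConditionSpec(f"aer_{i}", g, {"EX_ac_e": (0.0, 0.0)})
        )
    for i, g in enumerate((1.0, 1.5, 2.0, 2.5)):
        conds.append(
            ConditionSpec(f"ana_{i}", g, {"EX_o2_e": (0.0, 0.0)})
        )
    return conds


def perturb_turnovers(
    turnovers: TurnoverSet, scale: float, seed: int, center: bool = True
) -> tuple:
    """Draw a ground-truth adjustment vector and mis-specify the turnovers.

    Returns ``(perturbed, u_star)`` where ``perturbed`` holds
    ``kcat * 10**(-u_star)`` per entry, so an adjustment of exactly
    ``u_star`` recovers the originals.  With free per-condition scalings the
    fit only identifies adjustments up to a global additive shift, so
    ``u_star`` is centred to zero mean by default (see module docs of
    :mod:`cbmkit.kcatfit`).
    """
    rng = _rng(seed, "kcat_perturbation")
    keys = sorted(turnovers.kcat)
    u = rng.normal(0.0, scale, size=len(keys))
    if center and len(u):
        u -= u.mean()
    new = dict(turnovers.kcat)
    u_star = {}
    for (rxn, d), du in zip(keys, u):
        new[(rxn, d)] = turnovers.kcat[(rxn, d)] * 10.0 ** (-du)
        # split-reaction id as used by the fit: irreversible forward reactions
        # keep the base id, reverse copies carry the _rev suffix
        u_star[rxn if d == "fwd" else f"{rxn}_rev"] = du
    return TurnoverSet(new, dict(turnovers.provenance),
                       turnovers.subunit_multiplier_applied), u_star


def simulate_proteomics(
    world: ToyWorld,
    conditions,
    noise_sd_log10: float,
    seed: int,
    ec: ECModel | None = None,
) -> tuple:
    """Simulated enzyme abundances for a set of growth conditions.

    Per condition, the reference (minimum-cost) flux distribution at the
    condition's growth rate is computed with the world's turnover numbers, a
    condition saturation ``sigma_c`` is drawn around 0.5, abundances are
    formed as ``a_i v_i / sigma_c`` aggregated per enzyme, and multiplicative
    log10-normal noise of standard deviation ``noise_sd_log10`` is applied.
    Returns ``(measured, sigma_true, reference_fluxes)``; deterministic under
    the seed.
    """
    ec = ec if ec is not None else make_ec_model(world)
    refs = compute_reference_fluxes(ec, conditions)
    missing = [c.label for c in conditions if c.label not in refs]
    if missing:
        raise ValueError(f"infeasible conditions: {missing}")
    rng = _rng(seed, "proteomics_noise")
    sig_rng = _rng(seed, "condition_saturation")
    measured = {}
    sigma_true = {}
    for cond in conditions:
        sigma_c = float(10.0 ** sig_rng.normal(np.log10(0.5), 0.1))
        sigma_true[cond.label] = sigma_c
        flux = refs[cond.label]
        alloc: dict = {}
        for rxn, enz in ec.enzyme_of.items():
            v = flux.values.get(rxn, 0.0)
            if v > 1e-10:
                alloc[enz] = alloc.get(enz, 0.0) + ec.cost[rxn] * ec.sigma * v / sigma_c
        for enz, e in alloc.items():
            noise = 10.0 ** rng.normal(0.0, noise_sd_log10) if noise_sd_log10 > 0 else 1.0
            measured[(cond.label, enz)] = e * noise
    return measured, sigma_true, refs


def simulate_thermo_params(
    world: ToyWorld, sd: float, correlation: str = "independent", seed: int = 0
) -> ThermoParameterSet:
    """Thermodynamic parameters for a toy world's internal reactions.

    Mean standard reaction energies of -10 kJ/mol give every pathway a
    strictly negative driving force; the covariance is either diagonal
    (``independent``) or rank one with a common error shared along the
    pathway (``pathway_correlated``).  ``sd`` is in kJ/mol.
    """
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    model = world.model
    exchanges = model.exchange_set
    index = [
        r
        for r in model.reaction_ids
        if r not in exchanges and r not in model.objective and r != "ATPM"
    ]
    n = len(index)
    mean = np.full(n, -10.0)
    if correlation == "independent":
        cov = np.eye(n) * sd**2
    elif correlation == "pathway_correlated":
        w = np.full(n, sd)
        cov = np.outer(w, w)
    else:
        raise ValueError(f"unknown correlation structure {correlation!r}")
    return ThermoParameterSet(index, mean, cov)
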