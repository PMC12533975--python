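"""Typed reaction-enzyme-polypeptide-gene knowledge graph.

Nodes represent biological entities (reactions, proteins, polypeptides,
genes, compounds); directed edges represent functional relationships:

* ``catalysis``   protein -> reaction (with ``catalysis_class`` primary/secondary)
* ``subunit_composition``  complex protein -> component (integer stoichiometry)
* ``coding``      gene -> polypeptide
* ``regulation``, ``modification``  stored and round-tripped, but not used in
  knockout propagation.

The graph supports recursive protein-mass computation, derivation of Boolean
gene-protein-reaction (GPR) rules, gene-knockout propagation, disruption
classification against growth conditions, and non-negative least-squares
estimation of complex abundances from polypeptide counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

import networkx as nx
import numpy as np
import sympy
from scipy.optimize import nnls

from .model import MetabolicModel, OPTIMAL, set_condition, solve_fba

__all__ = [
    "KnowledgeGraph",
    "DisruptionReport",
    "GrowthCondition",
    "validate_graph",
    "protein_mass",
    "derive_gpr",
    "propagate_knockout",
    "classify_disruption",
    "disruption_analysis",
    "estimate_complex_abundances",
]

NODE_TYPES = {"reaction", "protein", "polypeptide", "gene", "compound"}
EDGE_TYPES = {"catalysis", "subunit_composition", "coding", "regulation", "modification"}

#: severity order of disruption classes, most severe first
DISRUPTION_ORDER = ["complete", "full_primary", "partial_primary", "secondary", "none"]


class KnowledgeGraph:
    """A thin typed wrapper around a :class:`networkx.MultiDiGraph`."""

    def __init__(self, graph: nx.MultiDiGraph | None = None):
        self.g = graph if graph is not None else nx.MultiDiGraph()

    def add_node(self, node_id: str, node_type: str, **attrs) -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type!r}")
        self.g.add_node(node_id, node_type=node_type, **attrs)

    def add_edge(self, source: str, target: str, edge_type: str, **attrs) -> None:
        if edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {edge_type!r}")
        if edge_type == "catalysis":
            # catalytic relationships default to primary unless curated otherwise
            attrs.setdefault("catalysis_class", "primary")
        self.g.add_edge(source, target, edge_type=edge_type, **attrs)

    # -- typed views ------------------------------------------------------
    def nodes_of_type(self, node_type: str):
        return [n for n, d in self.g.nodes(data=True) if d.get("node_type") == node_type]

    def node_type(self, node_id: str) -> str:
        return self.g.nodes[node_id].get("node_type", "")

    def edges_of_type(self, edge_type: str):
        return [
            (u, v, d)
            for u, v, d in self.g.edges(data=True)
            if d.get("edge_type") == edge_type
        ]

    def catalysis_edges(self, reaction: str):
        """(protein, attrs) pairs for the catalysis edges of a reaction."""
        return [
            (u, d)
            for u, v, d in self.g.in_edges(reaction, data=True)
            if d.get("edge_type") == "catalysis"
        ]

    def subunit_children(self, protein: str):
        """(component, stoichiometry) pairs of the direct subunits of a protein."""
        return [
            (v, d.get("stoichiometry", 1))
            for u, v, d in self.g.out_edges(protein, data=True)
            if d.get("edge_type") == "subunit_composition"
        ]

    def coding_genes(self, polypeptide: str):
        return [
            u
            for u, v, d in self.g.in_edges(polypeptide, data=True)
            if d.get("edge_type") == "coding"
        ]

    # -- I/O --------------------------------------------------------------
    def write_gml(self, path) -> None:
        nx.write_gml(self.g, str(path))

    @classmethod
    def read_gml(cls, path) -> "KnowledgeGraph":
        g = nx.read_gml(str(path))
        if not g.is_multigraph():
            g = nx.MultiDiGraph(g)
        return cls(g)


def validate_graph(graph: KnowledgeGraph) -> list:
    """Return a list of human-readable invariant violations (empty iff valid)."""
    violations = []
    for n, d in graph.g.nodes(data=True):
        if d.get("node_type") not in NODE_TYPES:
            violations.append(f"node {n!r}: unknown or missing node_type")
    for u, v, d in graph.g.edges(data=True):
        et = d.get("edge_type")
        if et not in EDGE_TYPES:
            violations.append(f"edge {u!r}->{v!r}: unknown or missing edge_type")
            continue
        if et == "catalysis":
            if graph.node_type(u) != "protein" or graph.node_type(v) != "reaction":
                violations.append(
                    f"catalysis edge {u!r}->{v!r} must connect protein->reaction"
                )
            if d.get("catalysis_class", "primary") not in {"primary", "secondary"}:
                violations.append(f"catalysis edge {u!r}->{v!r}: bad catalysis_class")
        elif et == "subunit_composition":
            stoich = d.get("stoichiometry", 1)
            if not (float(stoich).is_integer() and stoich >= 1):
                violations.append(
                    f"subunit edge {u!r}->{v!r}: stoichiometry must be an integer >= 1"
                )
        elif et == "coding":
            if graph.node_type(u) != "gene" or graph.node_type(v) != "polypeptide":
                violations.append(
                    f"coding edge {u!r}->{v!r} must connect gene->polypeptide"
                )
    sub = nx.MultiDiGraph(
        (u, v) for u, v, d in graph.g.edges(data=True)
        if d.get("edge_type") == "subunit_composition"
    )
    if sub.number_of_edges() and not nx.is_directed_acyclic_graph(sub):
        cycle = nx.find_cycle(sub)
        violations.append(f"subunit composition contains a cycle: {cycle}")
    return violations


def protein_mass(graph: KnowledgeGraph, protein: str, _visiting=None) -> float:
    """Molecular mass (kDa) of a protein, summed recursively over subunits."""
    if _visiting is None:
        _visiting = set()
    if protein in _visiting:
        raise ValueError(f"subunit cycle detected at node {protein!r}")
    children = graph.subunit_children(protein)
    if not children:
        mass = graph.g.nodes[protein].get("molecular_mass")
        if mass is None:
            raise KeyError(f"polypeptide {protein!r} has no molecular_mass attribute")
        return float(mass)
    _visiting.add(protein)
    total = sum(
        stoich * protein_mass(graph, child, _visiting) for child, stoich in children
    )
    _visiting.discard(protein)
    return float(total)


def polypeptide_count(graph: KnowledgeGraph, protein: str) -> int:
    """Total number of polypeptide chains in a protein (recursively)."""
    counts = _expand_polypeptides(graph, protein)
    return int(sum(counts.values()))


def _expand_polypeptides(graph: KnowledgeGraph, protein: str) -> Counter:
    """Counter of leaf polypeptide -> copy number within a protein."""
    children = graph.subunit_children(protein)
    if not children:
        return Counter({protein: 1})
    total = Counter()
    for child, stoich in children:
        for leaf, k in _expand_polypeptides(graph, child).items():
            total[leaf] += int(stoich) * k
    return total


# ---------------------------------------------------------------------------
# GPR derivation and knockout propagation
# ---------------------------------------------------------------------------


def _protein_expr(graph: KnowledgeGraph, node: str):
    """sympy Boolean expression for a protein/polypeptide remaining intact."""
    children = graph.subunit_children(node)
    if children:
        return sympy.And(*[_protein_expr(graph, c) for c, _ in children])
    genes = graph.coding_genes(node)
    if not genes:
        return sympy.true  # constitutive: no genetic requirement recorded
    return sympy.Or(*[sympy.Symbol(g) for g in genes])


def derive_gpr(graph: KnowledgeGraph, reaction: str):
    """Boolean gene-protein-reaction rule for a reaction.

    The rule is an OR over catalysing proteins of the AND of their gene
    requirements, collected recursively through subunit and coding edges.
    Reactions with no catalysis edges (spontaneous/orphan) yield the constant
    ``sympy.true``.
    """
    if reaction not in graph.g:
        raise KeyError(f"unknown reaction node {reaction!r}")
    catalysts = graph.catalysis_edges(reaction)
    if not catalysts:
        return sympy.true
    return sympy.Or(*[_protein_expr(graph, p) for p, _ in catalysts])


def _survives(graph: KnowledgeGraph, node: str, knocked: frozenset, memo: dict) -> bool:
    if node in memo:
        return memo[node]
    children = graph.subunit_children(node)
    if children:
        ok = all(_survives(graph, c, knocked, memo) for c, _ in children)
    else:
        genes = graph.coding_genes(node)
        ok = (not genes) or any(g not in knocked for g in genes)
    memo[node] = ok
    return ok


def propagate_knockout(graph: KnowledgeGraph, knocked_genes) -> set:
    """Catalysis edges (protein, reaction) surviving a gene knockout set.

    A polypeptide is lost iff all of its coding genes are knocked out; a
    protein is lost iff any recursively required component is lost; a
    catalysis edge survives iff its protein survives.
    """
    knocked = frozenset(knocked_genes)
    gene_nodes = set(graph.nodes_of_type("gene"))
    unknown = knocked - gene_nodes
    if unknown:
        raise KeyError(f"unknown gene ids: {sorted(unknown)}")
    memo: dict = {}
    surviving = set()
    for protein, reaction, d in graph.g.edges(data=True):
        if d.get("edge_type") != "catalysis":
            continue
        if _survives(graph, protein, knocked, memo):
            surviving.add((protein, reaction))
    return surviving


def classify_disruption(graph: KnowledgeGraph, reaction: str, knocked_genes) -> str:
    """Disruption class of a reaction under a gene knockout set.

    ``complete`` if all catalysis edges are lost; ``full_primary`` if all
    primary edges are lost but a secondary one survives; ``partial_primary``
    if some but not all primary edges are lost; ``secondary`` if only
    secondary edges are lost; ``none`` otherwise.
    """
    edges = graph.catalysis_edges(reaction)
    if not edges:
        raise ValueError(f"reaction {reaction!r} has no catalysis edges")
    surviving = propagate_knockout(graph, knocked_genes)
    lost_primary = surv_primary = lost_secondary = surv_any = 0
    n_primary = 0
    for protein, d in edges:
        primary = d.get("catalysis_class", "primary") == "primary"
        alive = (protein, reaction) in surviving
        n_primary += primary
        surv_any += alive
        if primary:
            surv_primary += alive
            lost_primary += not alive
        else:
            lost_secondary += not alive
    if surv_any == 0:
        return "complete"
    if n_primary and lost_primary == n_primary:
        return "full_primary"
    if lost_primary:
        return "partial_primary"
    if lost_secondary:
        return "secondary"
    return "none"


@dataclass
class GrowthCondition:
    """One growth condition for disruption analysis (uptake in mmol/gDW/h)."""

    label: str
    carbon_exchange: str
    uptake: float = 10.0
    aerobic: bool = True
    maintenance: float = 6.86
    oxygen_exchange: str | None = "EX_o2_e"
    maintenance_reaction: str | None = "ATPM"

    def apply(self, model: MetabolicModel) -> MetabolicModel:
        return set_condition(
            model,
            self.carbon_exchange,
            self.uptake,
            self.aerobic,
            self.maintenance,
            oxygen_exchange=self.oxygen_exchange,
            maintenance_reaction=self.maintenance_reaction,
        )


@dataclass
class DisruptionReport:
    gene: str
    condition: str
    affected_reactions: frozenset
    disruption_class: str


def _reaction_genes(graph: KnowledgeGraph, reaction: str) -> set:
    """All genes appearing in a reaction's GPR (via catalysis/subunit/coding)."""
    genes = set()

    def collect(node):
        children = graph.subunit_children(node)
        if children:
            for c, _ in children:
                collect(c)
        else:
            genes.update(graph.coding_genes(node))

    for protein, _ in graph.catalysis_edges(reaction):
        collect(protein)
    return genes


def essential_reactions(
    model: MetabolicModel,
    condition_model: MetabolicModel,
    threshold_frac: float = 1e-6,
    excluded=(),
) -> list:
    """Reactions whose single knockout drops growth below a wild-type fraction."""
    wt = solve_fba(condition_model)
    if wt.status != OPTIMAL or wt.objective_value <= 0:
        raise ValueError("condition is infeasible or non-growing in the wild type")
    cut = threshold_frac * wt.objective_value
    ess = []
    work = condition_model.copy()
    for rid in model.reaction_ids:
        if rid in excluded or rid in model.objective:
            continue
        j = work.reaction_index(rid)
        lo, hi = work.lower_bound[j], work.upper_bound[j]
        work.lower_bound[j] = work.upper_bound[j] = 0.0
        ko = solve_fba(work)
        work.lower_bound[j], work.upper_bound[j] = lo, hi
        if ko.status != OPTIMAL or ko.objective_value < cut:
            ess.append(rid)
    return ess


def disruption_analysis(
    model: MetabolicModel,
    graph: KnowledgeGraph,
    conditions,
    threshold_frac: float = 1e-6,
    excluded_reactions=(),
) -> list:
    """Classify gene-knockout disruption of essential reactions per condition.

    For each condition, essential reactions are found by single-reaction
    knockout; each gene of each essential reaction is labelled with the most
    severe disruption class over its affected essential reactions (precedence
    complete > full_primary > partial_primary > secondary).  Reactions in
    ``excluded_reactions`` (e.g. known false essentials) are skipped, as are
    orphan/spontaneous reactions without catalysis edges.
    """
    reports = []
    for cond in conditions:
        cm = cond.apply(model)
        ess = essential_reactions(model, cm, threshold_frac, excluded_reactions)
        ess = [r for r in ess if r in graph.g and graph.catalysis_edges(r)]
        gene_to_rxns: dict = {}
        for rxn in ess:
            for g in _reaction_genes(graph, rxn):
                gene_to_rxns.setdefault(g, set()).add(rxn)
        for gene in sorted(gene_to_rxns):
            classes = {
                rxn: classify_disruption(graph, rxn, {gene})
                for rxn in gene_to_rxns[gene]
            }
            affected = frozenset(r for r, c in classes.items() if c != "none")
            if not affected:
                continue
            worst = min(
                (classes[r] for r in affected), key=DISRUPTION_ORDER.index
            )
            reports.append(DisruptionReport(gene, cond.label, affected, worst))
    return reports


# ---------------------------------------------------------------------------
# Complex abundance estimation (non-negative least squares)
# ---------------------------------------------------------------------------


def estimate_complex_abundances(
    graph: KnowledgeGraph,
    polypeptide_abundance: dict,
    complexes=None,
) -> dict:
    """Estimate protein-complex abundances from polypeptide counts by NNLS.

    Solves ``min ||P e - p||_2, e >= 0`` where ``P`` is the polypeptide x
    complex stoichiometry matrix obtained by recursively expanding subunit
    edges.  ``complexes`` defaults to every protein node with at least one
    catalysis edge.  Raises if a required polypeptide has no measurement.
    """
    if complexes is None:
        complexes = sorted(
            {
                u
                for u, v, d in graph.g.edges(data=True)
                if d.get("edge_type") == "catalysis"
            }
        )
    expansions = {c: _expand_polypeptides(graph, c) for c in complexes}
    needed = sorted(set().union(*[set(e) for e in expansions.values()]) or set())
    missing = [p for p in needed if p not in polypeptide_abundance]
    if missing:
        raise KeyError(f"polypeptides without measured/imputed abundance: {missing}")
    if any(polypeptide_abundance[p] < 0 for p in needed):
        raise ValueError("polypeptide abundances must be nonnegative")
    P = np.zeros((len(needed), len(complexes)))
    for j, c in enumerate(complexes):
        for leaf, k in expansions[c].items():
            P[needed.index(leaf), j] = k
    p = np.array([polypeptide_abundance[m] for m in needed], dtype=float)
    e, _ = nnls(P, p)
    return dict(zip(complexes, e))
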