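import numpy as np
import pytest

from cbmkit import MetabolicModel, KnowledgeGraph, make_toy_network


@pytest.fixture(scope="session")
def chain_world():
    return make_toy_network("chain", seed=0)


@pytest.fixture(scope="session")
def branched_world():
    return make_toy_network("branched", seed=0)


@pytest.fixture(scope="session")
def respferm_world():
    return make_toy_network("respirofermentative", seed=0)


def build_model(mets, reactions, objective=None):
    """Compact inline model builder: reactions are (id, stoich, lb, ub)."""
    rxn_ids = [r[0] for r in reactions]
    S = np.zeros((len(mets), len(rxn_ids)))
    midx = {m: i for i, m in enumerate(mets)}
    lb, ub = np.zeros(len(rxn_ids)), np.zeros(len(rxn_ids))
    for j, (_rid, stoich, lo, hi) in enumerate(reactions):
        for m, c in stoich.items():
            S[midx[m], j] = c
        lb[j], ub[j] = lo, hi
    model = MetabolicModel(list(mets), rxn_ids, S, lb, ub, dict(objective or {}))
    model.validate()
    return model


def random_network(rng: np.random.Generator) -> MetabolicModel:
    """A small random network for oracle cross-checks (<= 10 reactions)."""
    n_met = int(rng.integers(2, 5))
    n_rxn = int(rng.integers(5, 10))
    while True:
        S = rng.integers(-2, 3, size=(n_met, n_rxn)).astype(float)
        mask = rng.random((n_met, n_rxn)) < 0.5
        S = S * mask
        if np.all(np.any(S != 0, axis=0)):
            break
    lb = np.where(rng.random(n_rxn) < 0.5, -10.0, 0.0)
    ub = np.full(n_rxn, 10.0)
    mets = [f"m{i}" for i in range(n_met)]
    rxns = [f"r{j}" for j in range(n_rxn)]
    return MetabolicModel(mets, rxns, S, lb, ub, {})


@pytest.fixture
def shared_subunit_graph():
    """Two isozymes sharing a subunit, plus a two-gene-encoded polypeptide.

    R1 is catalysed by complex C1 (ppA from gA, ppB from gB) and by monomer
    M1 (ppC, encoded redundantly by gC1 or gC2); R2 is catalysed by complex
    C2 which shares ppB and adds ppD (gD).
    """
    g = KnowledgeGraph()
    for r in ("R1", "R2"):
        g.add_node(r, "reaction")
    for pp, mass in (("ppA", 10.0), ("ppB", 20.0), ("ppC", 30.0), ("ppD", 40.0)):
        g.add_node(pp, "polypeptide", molecular_mass=mass)
    for gene in ("gA", "gB", "gC1", "gC2", "gD"):
        g.add_node(gene, "gene")
    g.add_edge("gA", "ppA", "coding")
    g.add_edge("gB", "ppB", "coding")
    g.add_edge("gC1", "ppC", "coding")
    g.add_edge("gC2", "ppC", "coding")
    g.add_edge("gD", "ppD", "coding")
    for prot, parts in (("C1", [("ppA", 1), ("ppB", 2)]),
                        ("M1", [("ppC", 1)]),
                        ("C2", [("ppB", 1), ("ppD", 3)])):
        g.add_node(prot, "protein")
        for pp, st in parts:
            g.add_edge(prot, pp, "subunit_composition", stoichiometry=st)
    g.add_edge("C1", "R1", "catalysis")
    g.add_edge("M1", "R1", "catalysis")
    g.add_edge("C2", "R2", "catalysis")
    return g
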