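"""Enzyme-constrained FBA in the pooled (sMOMENT-style) format.

Each enzymatic reaction ``i`` is assigned a flux-specific enzyme cost

    a_i = M_i / (kcat_i * n_subunits * 3600 * sigma)      [g h / mmol]

with the enzyme's molecular mass ``M_i`` in kDa (interpreted as g/mmol),
the turnover number in 1/s (converted once to 1/h), and a condition-specific
average saturation ``sigma``.  Because turnover estimates are reported per
polypeptide, they are multiplied by the number of polypeptide chains in the
enzyme exactly once (tracked on :class:`TurnoverSet`).  A single pooled
constraint

    sum_i a_i v_i <= e_tot      [g/gDW]

is added to the direction-split model; this generates the same solution
space as per-enzyme formats such as GECKO unless reaction-specific capacity
bounds are imposed there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    OPTIMAL,
    FluxDistribution,
    MetabolicModel,
    solve_fba,
    solve_pfba,
)
from .graph import KnowledgeGraph, polypeptide_count, protein_mass

__all__ = [
    "TurnoverSet",
    "ECModel",
    "ECModelBuildError",
    "select_catalytic_enzyme",
    "compute_enzyme_cost",
    "build_ec_model",
    "predict_allocation",
    "fit_saturation",
    "rmse_log10",
    "DEFAULT_TRANSPORTER_KCAT",
]

#: default turnover for transporters without a measured estimate (1/s)
DEFAULT_TRANSPORTER_KCAT = 65.0

SECONDS_PER_HOUR = 3600.0


class ECModelBuildError(ValueError):
    """The enzyme-constrained model could not be assembled."""


@dataclass
class TurnoverSet:
    """Direction-specific turnover numbers.

    ``kcat`` maps (reaction id, direction in {"fwd", "rev"}) to a turnover in
    1/s; ``provenance`` records how each value was obtained (``measured``,
    ``default_transporter`` or ``adjusted``).  ``subunit_multiplier_applied``
    says whether per-polypeptide values have already been scaled by the
    number of subunits, so the correction is applied exactly once.
    """

    kcat: dict
    provenance: dict = field(default_factory=dict)
    subunit_multiplier_applied: bool = False

    def __post_init__(self):
        bad = {k: v for k, v in self.kcat.items() if not v > 0}
        if bad:
            raise ValueError(f"turnover numbers must be positive: {bad}")

    def get(self, reaction: str, direction: str):
        return self.kcat.get((reaction, direction))

    def adjusted(self, u: dict) -> "TurnoverSet":
        """New set with log10 adjustments applied per split-reaction id."""
        new = dict(self.kcat)
        prov = dict(self.provenance)
        for (rxn, direction), k in self.kcat.items():
            split_id = f"{rxn}_{direction}"
            du = u.get(split_id, u.get(rxn, 0.0))
            if du:
                new[(rxn, direction)] = k * 10.0 ** du
                prov[(rxn, direction)] = "adjusted"
        return TurnoverSet(new, prov, self.subunit_multiplier_applied)


def select_catalytic_enzyme(
    graph: KnowledgeGraph,
    reaction: str,
    abundance: dict | None = None,
    lexicographic_fallback: bool = True,
) -> str:
    """Pick the single enzyme to cost a reaction with.

    Secondary catalytic relationships are discarded; among multiple primary
    isozymes the one with the highest measured abundance wins.  Ties (or
    missing abundance data) fall back to the lexicographically smallest id
    when ``lexicographic_fallback`` is set, otherwise raise.
    """
    primaries = [
        p
        for p, d in graph.catalysis_edges(reaction)
        if d.get("catalysis_class", "primary") == "primary"
    ]
    if not primaries:
        raise ECModelBuildError(f"reaction {reaction!r} has no primary catalysis edge")
    if len(primaries) == 1:
        return primaries[0]
    abundance = abundance or {}
    scored = sorted(primaries, key=lambda p: (-abundance.get(p, float("-inf")), p))
    best = scored[0]
    tied = [p for p in primaries if abundance.get(p) == abundance.get(best)]
    if len(tied) > 1 or best not in abundance:
        if not lexicographic_fallback:
            raise ECModelBuildError(
                f"cannot break isozyme tie for {reaction!r} without abundance data"
            )
        return min(tied) if len(tied) > 1 else min(primaries)
    return best


def compute_enzyme_cost(
    M: float, kcat: float, sigma: float = 1.0, n_subunits: int = 1
) -> float:
    """Flux-specific enzyme cost a = M / (kcat * n * 3600 * sigma), g h/mmol."""
    if not (M > 0 and kcat > 0 and sigma > 0):
        raise ValueError("M, kcat and sigma must be positive")
    if n_subunits < 1:
        raise ValueError("n_subunits must be >= 1")
    return M / (kcat * n_subunits * SECONDS_PER_HOUR * sigma)


@dataclass
class ECModel:
    """Direction-split model with per-reaction enzyme costs and a pool bound.

    ``base`` has every reversible reaction duplicated into irreversible
    ``<id>_fwd`` / ``<id>_rev`` copies; ``cost`` maps split-reaction ids to
    a_i (zero entries omitted); ``enzyme_of`` maps costed split reactions to
    their protein id; ``parent`` maps split ids back to (original id, sign).
    """

    base: MetabolicModel
    cost: dict
    etot: float
    sigma: float
    enzyme_of: dict
    parent: dict
    build_report: dict = field(default_factory=dict)

    # -- plumbing ---------------------------------------------------------
    def copy(self) -> "ECModel":
        return ECModel(
            self.base.copy(),
            dict(self.cost),
            self.etot,
            self.sigma,
            dict(self.enzyme_of),
            dict(self.parent),
            dict(self.build_report),
        )

    def cost_vector(self) -> np.ndarray:
        a = np.zeros(self.base.n_reactions)
        for rxn, ai in self.cost.items():
            a[self.base.reaction_index(rxn)] = ai
        return a

    def pool_row(self):
        """The pooled-enzyme constraint as one inequality row a^T v <= etot."""
        return self.cost_vector()[None, :], np.array([self.etot])

    def with_bounds(self, overrides: dict) -> "ECModel":
        """Copy with (lb, ub) overrides given on *original* reaction ids."""
        out = self.copy()
        split_ids = set(out.base.reaction_ids)
        for rxn, (lo, hi) in overrides.items():
            if rxn in split_ids:
                j = out.base.reaction_index(rxn)
                out.base.lower_bound[j], out.base.upper_bound[j] = lo, hi
                continue
            fwd, rev = f"{rxn}_fwd", f"{rxn}_rev"
            if fwd not in split_ids and rev not in split_ids:
                raise KeyError(f"unknown reaction id {rxn!r}")
            if fwd in split_ids:
                j = out.base.reaction_index(fwd)
                out.base.lower_bound[j] = max(lo, 0.0)
                out.base.upper_bound[j] = max(hi, 0.0)
            if rev in split_ids:
                j = out.base.reaction_index(rev)
                out.base.lower_bound[j] = max(-hi, 0.0)
                out.base.upper_bound[j] = max(-lo, 0.0)
        return out

    # -- solving ----------------------------------------------------------
    def solve(self, parsimonious: bool = False) -> FluxDistribution:
        """Growth-maximising EC-FBA under the pooled enzyme constraint."""
        A, b = self.pool_row()
        solver = solve_pfba if parsimonious else solve_fba
        return solver(self.base, sense="max", extra_A_ub=A, extra_b_ub=b)

    def net_fluxes(self, flux: FluxDistribution) -> dict:
        """Re-aggregate split fwd/rev fluxes to net fluxes on original ids."""
        net: dict = {}
        for rxn, v in flux.values.items():
            orig, sign = self.parent[rxn]
            net[orig] = net.get(orig, 0.0) + sign * v
        return net


def _split_model(model: MetabolicModel):
    """Duplicate reversible reactions into irreversible fwd/rev copies."""
    cols, ids, lbs, ubs = [], [], [], []
    parent = {}
    for j, rid in enumerate(model.reaction_ids):
        lo, hi = model.lower_bound[j], model.upper_bound[j]
        col = model.S[:, j]
        if lo < 0 and hi > 0:
            ids += [f"{rid}_fwd", f"{rid}_rev"]
            cols += [col, -col]
            lbs += [0.0, 0.0]
            ubs += [hi, -lo]
            parent[f"{rid}_fwd"] = (rid, 1.0)
            parent[f"{rid}_rev"] = (rid, -1.0)
        elif hi <= 0:
            ids.append(f"{rid}_rev")
            cols.append(-col)
            lbs.append(max(-hi, 0.0))
            ubs.append(-lo)
            parent[f"{rid}_rev"] = (rid, -1.0)
        else:
            ids.append(rid)
            cols.append(col)
            lbs.append(max(lo, 0.0))
            ubs.append(hi)
            parent[rid] = (rid, 1.0)
    S = np.column_stack(cols) if cols else np.zeros((model.n_metabolites, 0))
    objective = {}
    for rxn, coef in model.objective.items():
        if rxn in parent:
            objective[rxn] = coef
        elif f"{rxn}_fwd" in parent:
            objective[f"{rxn}_fwd"] = coef
        else:
            objective[f"{rxn}_rev"] = -coef
    split = MetabolicModel(
        list(model.metabolite_ids), ids, S, np.array(lbs), np.array(ubs), objective
    )
    return split, parent


def build_ec_model(
    model: MetabolicModel,
    graph: KnowledgeGraph,
    turnovers: TurnoverSet,
    masses: dict | None = None,
    etot: float = 0.285,
    sigma: float = 1.0,
    abundance: dict | None = None,
    uncosted_whitelist=(),
) -> ECModel:
    """Assemble the enzyme-constrained model variant.

    Every reaction with a primary catalysis edge in the knowledge graph is
    costed; exchanges, biomass, maintenance and spontaneous reactions carry
    zero cost.  Enzyme masses come from ``masses`` (protein id -> kDa) or are
    computed recursively from the graph.  Reactions with a missing turnover
    (and no applicable default) are listed in the build report and abort the
    build unless whitelisted.
    """
    split, parent = _split_model(model)
    cost: dict = {}
    enzyme_of: dict = {}
    missing = []
    exchange = model.exchange_set
    for split_id, (orig, sign) in parent.items():
        if orig in exchange or orig in model.objective:
            continue
        if orig not in graph.g or not graph.catalysis_edges(orig):
            continue  # spontaneous / maintenance pseudoreaction
        enzyme = select_catalytic_enzyme(graph, orig, abundance)
        direction = "fwd" if sign > 0 else "rev"
        kcat = turnovers.get(orig, direction)
        if kcat is None:
            if orig in uncosted_whitelist:
                continue
            missing.append((orig, direction))
            continue
        M = masses[enzyme] if masses else protein_mass(graph, enzyme)
        n_sub = 1 if turnovers.subunit_multiplier_applied else polypeptide_count(
            graph, enzyme
        )
        cost[split_id] = compute_enzyme_cost(M, kcat, sigma, n_sub)
        enzyme_of[split_id] = enzyme
    if missing:
        raise ECModelBuildError(
            f"missing turnover numbers (not whitelisted): {sorted(missing)}"
        )
    return ECModel(
        split, cost, float(etot), float(sigma), enzyme_of, parent,
        build_report={"uncosted": sorted(set(uncosted_whitelist))},
    )


def predict_allocation(ec: ECModel, growth_rate: float) -> dict:
    """Minimal enzyme allocation (g/gDW per enzyme) at a fixed growth rate.

    Fixes the biomass flux and minimises total enzyme cost ``sum a_i v_i``;
    returns e_i = a_i v_i aggregated per enzyme.  Raises if the growth rate
    is infeasible, reporting the maximum feasible growth.
    """
    work = ec.copy()
    (biomass_id,) = work.base.objective
    j = work.base.reaction_index(biomass_id)
    if growth_rate > work.base.upper_bound[j] + 1e-12:
        work.base.upper_bound[j] = growth_rate
    work.base.lower_bound[j] = work.base.upper_bound[j] = growth_rate
    a = work.cost_vector()
    A, b = work.pool_row()
    cost_model = work.base.copy()
    cost_model.objective = {
        r: a[i] for i, r in enumerate(work.base.reaction_ids) if a[i]
    } or {biomass_id: 0.0}
    sol = solve_fba(cost_model, sense="min", extra_A_ub=A, extra_b_ub=b)
    if sol.status != OPTIMAL:
        cap = ec.solve()
        maxg = cap.objective_value if cap.status == OPTIMAL else float("nan")
        raise ValueError(
            f"growth rate {growth_rate} infeasible (max feasible ~ {maxg:.6g})"
        )
    allocation: dict = {}
    for rxn, ai in ec.cost.items():
        e = ai * sol.values[rxn]
        enzyme = ec.enzyme_of[rxn]
        allocation[enzyme] = allocation.get(enzyme, 0.0) + e
    return allocation


def fit_saturation(predicted: dict, measured: dict) -> float:
    """Average saturation sigma = (sum of predicted) / (total measured).

    The sum runs over enzymes present in both mappings; dividing the
    predictions by sigma makes their total match the measured total.
    """
    overlap = sorted(set(predicted) & set(measured))
    if not overlap:
        raise ValueError("no overlap between predicted and measured enzymes")
    total_measured = sum(measured[e] for e in overlap)
    if total_measured <= 0:
        raise ValueError("total measured abundance is zero")
    return sum(predicted[e] for e in overlap) / total_measured


def rmse_log10(predicted: dict, measured: dict) -> float:
    """log10 RMSE between predictions and measurements.

    Enzymes with zero (or missing) predicted abundance are excluded, as are
    zero measurements (log undefined).
    """
    res = [
        np.log10(predicted[e]) - np.log10(measured[e])
        for e in measured
        if predicted.get(e, 0.0) > 0 and measured[e] > 0
    ]
    if not res:
        raise ValueError("no comparable enzyme pairs with positive values")
    return float(np.sqrt(np.mean(np.square(res))))
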