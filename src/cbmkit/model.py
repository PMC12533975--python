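"""Stoichiometric model representation, I/O and basic constraint-based solvers.

The central object is :class:`MetabolicModel`, a plain dense stoichiometric
matrix ``S`` (metabolites x reactions) with per-reaction flux bounds and a
linear objective.  Fluxes follow the usual COBRA conventions: units of
mmol/gDW/h, the biomass reaction in 1/h, and exchange reactions written so
that uptake is a *negative* flux.

All linear programs are solved with the HiGHS backend of
:func:`scipy.optimize.linprog`.  SBML (Level 3 + FBC) and COBRA-style JSON
input/output are delegated to cobrapy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "MetabolicModel",
    "FluxDistribution",
    "ProductionEnvelope",
    "ModelValidationError",
    "FormatError",
    "load_model",
    "save_model",
    "solve_fba",
    "solve_pfba",
    "production_envelope",
    "set_condition",
    "lump_equivalent_biomass",
    "LumpedBiomass",
]

#: absolute LP feasibility / mass-balance tolerance
LP_TOL = 1e-9
#: relative threshold below which a flux is considered zero (support detection)
ZERO_FLUX_REL = 1e-9

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"


class ModelValidationError(ValueError):
    """A model violates a structural invariant (e.g. an all-zero reaction)."""


class FormatError(ValueError):
    """A file could not be parsed in the requested format."""


@dataclass
class MetabolicModel:
    """A stoichiometric metabolic network.

    Parameters
    ----------
    metabolite_ids :
        Metabolite identifiers (with compartment suffix, e.g. ``glc__D_c``).
    reaction_ids :
        Reaction identifiers; columns of ``S`` in the same order.
    S :
        Dense stoichiometric matrix, shape (n_metabolites, n_reactions).
    lower_bound, upper_bound :
        Per-reaction flux bounds (mmol/gDW/h).
    objective :
        Mapping reaction id -> objective coefficient.
    annotations :
        Optional mapping id -> external database references.
    """

    metabolite_ids: list
    reaction_ids: list
    S: np.ndarray
    lower_bound: np.ndarray
    upper_bound: np.ndarray
    objective: dict
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lower_bound = np.asarray(self.lower_bound, dtype=float)
        self.upper_bound = np.asarray(self.upper_bound, dtype=float)

    # -- indexing helpers -------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def reaction_index(self, rxn_id: str) -> int:
        try:
            return self.reaction_ids.index(rxn_id)
        except ValueError:
            raise KeyError(f"unknown reaction id: {rxn_id!r}") from None

    def metabolite_index(self, met_id: str) -> int:
        try:
            return self.metabolite_ids.index(met_id)
        except ValueError:
            raise KeyError(f"unknown metabolite id: {met_id!r}") from None

    @property
    def exchange_set(self) -> set:
        """Reactions with exactly one nonzero stoichiometric entry."""
        nnz = np.count_nonzero(self.S, axis=0)
        return {r for r, k in zip(self.reaction_ids, nnz) if k == 1}

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            list(self.metabolite_ids),
            list(self.reaction_ids),
            self.S.copy(),
            self.lower_bound.copy(),
            self.upper_bound.copy(),
            dict(self.objective),
            dict(self.annotations),
        )

    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on structural invariant violations."""
        if self.S.shape != (self.n_metabolites, self.n_reactions):
            raise ModelValidationError(
                f"S has shape {self.S.shape}, expected "
                f"({self.n_metabolites}, {self.n_reactions})"
            )
        empty = [r for r, col in zip(self.reaction_ids, self.S.T) if not np.any(col)]
        if empty:
            raise ModelValidationError(f"reactions with all-zero stoichiometry: {empty}")
        bad = [
            r
            for r, lo, hi in zip(self.reaction_ids, self.lower_bound, self.upper_bound)
            if lo > hi
        ]
        if bad:
            raise ModelValidationError(f"lower bound exceeds upper bound for: {bad}")
        unknown = set(self.objective) - set(self.reaction_ids)
        if unknown:
            raise ModelValidationError(f"objective references unknown reactions: {unknown}")

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(self.n_reactions)
        for rxn, coef in self.objective.items():
            c[self.reaction_index(rxn)] = coef
        return c


@dataclass
class FluxDistribution:
    """A steady-state flux vector with its objective value and solver status."""

    values: dict
    objective_value: float
    status: str

    def __getitem__(self, rxn_id: str) -> float:
        return self.values[rxn_id]

    def vector(self, model: MetabolicModel) -> np.ndarray:
        return np.array([self.values.get(r, 0.0) for r in model.reaction_ids])

    def support(self, threshold_rel: float = ZERO_FLUX_REL) -> frozenset:
        vmax = max((abs(v) for v in self.values.values()), default=0.0)
        cut = threshold_rel * max(vmax, 1.0)
        return frozenset(r for r, v in self.values.items() if abs(v) > cut)


@dataclass
class ProductionEnvelope:
    """Discretised projection of the flux space onto (production, growth).

    ``grid`` holds (production flux, min growth, max growth) triples for the
    feasible grid points; infeasible interior points are recorded as absent.
    """

    target_reaction: str
    grid: list


# ---------------------------------------------------------------------------
# I/O (delegated to cobrapy)
# ---------------------------------------------------------------------------


def _from_cobra(cm) -> MetabolicModel:
    met_ids = [m.id for m in cm.metabolites]
    rxn_ids = [r.id for r in cm.reactions]
    midx = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(rxn_ids)))
    lb = np.zeros(len(rxn_ids))
    ub = np.zeros(len(rxn_ids))
    objective = {}
    annotations = {}
    for j, r in enumerate(cm.reactions):
        for met, coef in r.metabolites.items():
            S[midx[met.id], j] = coef
        lb[j], ub[j] = r.lower_bound, r.upper_bound
        if r.objective_coefficient:
            objective[r.id] = float(r.objective_coefficient)
        if r.annotation:
            annotations[r.id] = dict(r.annotation)
    model = MetabolicModel(met_ids, rxn_ids, S, lb, ub, objective, annotations)
    model.validate()
    return model


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model("cbmkit_model")
    mets = {m: cobra.Metabolite(m, compartment=m.rsplit("_", 1)[-1] or "c")
            for m in model.metabolite_ids}
    rxns = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        rxn.lower_bound = float(model.lower_bound[j])
        rxn.upper_bound = float(model.upper_bound[j])
        rxns.append(rxn)
    cm.add_metabolites(list(mets.values()))
    cm.add_reactions(rxns)
    for j, rid in enumerate(model.reaction_ids):
        rxn = cm.reactions.get_by_id(rid)
        coeffs = {
            mets[m]: model.S[i, j]
            for i, m in enumerate(model.metabolite_ids)
            if model.S[i, j] != 0.0
        }
        rxn.add_metabolites(coeffs)
        if rid in model.annotations:
            rxn.annotation = dict(model.annotations[rid])
    cm.objective = {
        cm.reactions.get_by_id(r): coef for r, coef in model.objective.items()
    }
    return cm


def _infer_format(path: str, fmt) -> str:
    if fmt is not None:
        return fmt
    p = str(path).lower()
    if p.endswith(".json"):
        return "json"
    if p.endswith((".xml", ".sbml")):
        return "sbml"
    raise FormatError(f"cannot infer model format from path {path!r}")


def load_model(path, format=None) -> MetabolicModel:
    """Load a metabolic model from COBRA JSON or SBML (Level 3 + FBC).

    Raises :class:`FormatError` on parse failure and
    :class:`ModelValidationError` for structurally invalid models (for
    instance a reaction with all-zero stoichiometry).
    """
    import cobra.io

    fmt = _infer_format(path, format)
    try:
        if fmt == "json":
            cm = cobra.io.load_json_model(str(path))
        elif fmt == "sbml":
            cm = cobra.io.read_sbml_model(str(path))
        else:
            raise FormatError(f"unknown model format: {fmt!r}")
    except (ModelValidationError, FormatError):
        raise
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    return _from_cobra(cm)


def save_model(model: MetabolicModel, path, format=None) -> None:
    """Write a model as COBRA JSON or SBML; round-trips stoichiometry exactly."""
    import cobra.io

    fmt = _infer_format(path, format)
    cm = _to_cobra(model)
    if fmt == "json":
        cobra.io.save_json_model(cm, str(path))
    elif fmt == "sbml":
        cobra.io.write_sbml_model(cm, str(path))
    else:
        raise FormatError(f"unknown model format: {fmt!r}")


# ---------------------------------------------------------------------------
# LP solvers
# ---------------------------------------------------------------------------


def _solve_lp(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None):
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": LP_TOL,
                 "dual_feasibility_tolerance": LP_TOL},
    )
    return res


def _status_of(res) -> str:
    if res.status == 0:
        return OPTIMAL
    if res.status == 3:
        return UNBOUNDED
    return INFEASIBLE


def solve_fba(
    model: MetabolicModel,
    sense: str = "max",
    extra_A_ub=None,
    extra_b_ub=None,
) -> FluxDistribution:
    """Flux balance analysis: optimise ``c^T v`` s.t. ``S v = 0`` and bounds.

    ``extra_A_ub``/``extra_b_ub`` append inequality rows (used internally for
    the enzyme-pool constraint of enzyme-constrained models).
    """
    if not model.objective:
        raise ValueError("model has an empty objective")
    c = model.objective_vector()
    sign = -1.0 if sense == "max" else 1.0
    bounds = list(zip(model.lower_bound, model.upper_bound))
    res = _solve_lp(sign * c, A_ub=extra_A_ub, b_ub=extra_b_ub,
                    A_eq=model.S, b_eq=np.zeros(model.n_metabolites), bounds=bounds)
    status = _status_of(res)
    if status != OPTIMAL:
        return FluxDistribution({}, math.nan, status)
    v = res.x
    return FluxDistribution(dict(zip(model.reaction_ids, v)), float(c @ v), OPTIMAL)


def solve_pfba(
    model: MetabolicModel,
    sense: str = "max",
    extra_A_ub=None,
    extra_b_ub=None,
) -> FluxDistribution:
    """Parsimonious FBA: among optima of the objective, minimise total |flux|.

    Implemented as a two-stage LP: the optimum is fixed (within a 1e-9 slack)
    and the sum of absolute fluxes is minimised via variable splitting.
    """
    fba = solve_fba(model, sense=sense, extra_A_ub=extra_A_ub, extra_b_ub=extra_b_ub)
    if fba.status != OPTIMAL:
        return fba
    n = model.n_reactions
    lb, ub = model.lower_bound, model.upper_bound
    # v = p - q with p, q >= 0
    p_bounds = [(max(lo, 0.0), max(hi, 0.0)) for lo, hi in zip(lb, ub)]
    q_bounds = [(max(-hi, 0.0), max(-lo, 0.0)) for lo, hi in zip(lb, ub)]
    A_eq = np.hstack([model.S, -model.S])
    b_eq = np.zeros(model.n_metabolites)
    c_obj = model.objective_vector()
    sign = 1.0 if sense == "max" else -1.0
    # sign * c^T v >= sign * z* - slack
    rows = [np.concatenate([-sign * c_obj, sign * c_obj])]
    rhs = [-(sign * fba.objective_value - 1e-9)]
    if extra_A_ub is not None:
        A = np.atleast_2d(extra_A_ub)
        rows.extend(np.hstack([A, -A]))
        rhs.extend(np.atleast_1d(extra_b_ub))
    res = _solve_lp(
        np.ones(2 * n),
        A_ub=np.vstack(rows),
        b_ub=np.array(rhs),
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=p_bounds + q_bounds,
    )
    if res.status != 0:
        return FluxDistribution({}, math.nan, INFEASIBLE)
    v = res.x[:n] - res.x[n:]
    return FluxDistribution(dict(zip(model.reaction_ids, v)), float(c_obj @ v), OPTIMAL)


def _flux_range(model: MetabolicModel, rxn: str):
    """Min and max achievable flux of one reaction (flux variability bounds)."""
    j = model.reaction_index(rxn)
    c = np.zeros(model.n_reactions)
    c[j] = 1.0
    bounds = list(zip(model.lower_bound, model.upper_bound))
    out = []
    for sign in (1.0, -1.0):
        res = _solve_lp(sign * c, A_eq=model.S,
                        b_eq=np.zeros(model.n_metabolites), bounds=bounds)
        if res.status != 0:
            raise RuntimeError(
                f"flux range of {rxn!r} could not be computed (status {res.status})"
            )
        out.append(float(res.x[j]))
    return out[0], out[1]  # (min, max)


def production_envelope(
    model: MetabolicModel, target: str, n_points: int
) -> ProductionEnvelope:
    """Growth envelope over an equally spaced grid of target production fluxes.

    At each grid point the target flux is fixed and growth is minimised and
    maximised.  Grid points that turn out infeasible (numerically) are
    recorded as absent rather than failing the whole envelope.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    j = model.reaction_index(target)
    tmin, tmax = _flux_range(model, target)
    grid_vals = np.linspace(tmin, tmax, n_points)
    triples = []
    work = model.copy()
    for t in grid_vals:
        work.lower_bound[j] = work.upper_bound[j] = t
        lo = solve_fba(work, sense="min")
        hi = solve_fba(work, sense="max")
        if lo.status == OPTIMAL and hi.status == OPTIMAL:
            triples.append((float(t), lo.objective_value, hi.objective_value))
    return ProductionEnvelope(target, triples)


def set_condition(
    model: MetabolicModel,
    carbon_exchange: str,
    uptake_bound: float,
    aerobic: bool,
    maintenance_bound: float = 6.86,
    oxygen_exchange: str = "EX_o2_e",
    maintenance_reaction: str = "ATPM",
) -> MetabolicModel:
    """Return a copy of the model configured for one growth condition.

    Uptake is a negative exchange flux, so the carbon exchange lower bound is
    set to ``-uptake_bound``.  Oxygen uptake is blocked for the anaerobic
    scenario; the maintenance reaction (ATP hydrolysis) gets
    ``maintenance_bound`` as its lower bound (default 6.86 mmol/gDW/h, the
    iML1515 value).  Pass ``oxygen_exchange=None`` / ``maintenance_reaction=None``
    for models lacking these reactions.
    """
    out = model.copy()
    j = out.reaction_index(carbon_exchange)
    out.lower_bound[j] = -uptake_bound
    if oxygen_exchange is not None:
        k = out.reaction_index(oxygen_exchange)
        if aerobic:
            out.lower_bound[k] = min(out.lower_bound[k], -1000.0)
        else:
            out.lower_bound[k] = 0.0
    if maintenance_reaction is not None:
        m = out.reaction_index(maintenance_reaction)
        out.lower_bound[m] = maintenance_bound
    return out


@dataclass
class LumpedBiomass:
    """An equivalent biomass reaction over a retained metabolite set.

    ``stoichiometry`` maps each retained metabolite to its net coefficient per
    unit biomass flux; ``lumped_reactions`` lists the reactions summarised by
    the equivalent reaction.
    """

    stoichiometry: dict
    lumped_reactions: list
    biomass_flux: float


def lump_equivalent_biomass(
    extended_model: MetabolicModel,
    reference_flux: FluxDistribution,
    retained_metabolites,
) -> LumpedBiomass:
    """Collapse the non-retained subnetwork into one equivalent biomass reaction.

    The lumped subnetwork consists of the biomass reaction plus every reaction
    that carries flux in the reference solution and touches a non-retained
    metabolite.  The equivalent reaction's coefficient for each retained
    metabolite is the net production of that metabolite by the lumped
    subnetwork at the reference flux, scaled to unit biomass flux.  Replacing
    the lumped subnetwork with this reaction preserves the reference growth
    rate.
    """
    retained = set(retained_metabolites)
    unknown = retained - set(extended_model.metabolite_ids)
    if unknown:
        raise KeyError(f"retained metabolites not in model: {sorted(unknown)}")
    v = reference_flux.vector(extended_model)
    imbalance = np.max(np.abs(extended_model.S @ v)) if v.size else 0.0
    if imbalance > 1e-6:
        raise ValueError(f"reference flux violates mass balance (|S v| = {imbalance:.2e})")
    if len(extended_model.objective) != 1:
        raise ValueError("extended model must have a single biomass objective reaction")
    (biomass_id,) = extended_model.objective
    v_bm = reference_flux.values.get(biomass_id, 0.0)
    if abs(v_bm) < 1e-12:
        raise ValueError("biomass flux is zero in the reference solution; cannot scale")

    vmax = np.max(np.abs(v))
    cut = ZERO_FLUX_REL * max(vmax, 1.0)
    non_retained_rows = [
        i for i, m in enumerate(extended_model.metabolite_ids) if m not in retained
    ]
    lumped = []
    for j, rid in enumerate(extended_model.reaction_ids):
        if rid == biomass_id:
            lumped.append(j)
        elif abs(v[j]) > cut and any(
            extended_model.S[i, j] != 0.0 for i in non_retained_rows
        ):
            lumped.append(j)
    stoich = {}
    for m in retained:
        i = extended_model.metabolite_index(m)
        coef = sum(extended_model.S[i, j] * v[j] for j in lumped) / v_bm
        if abs(coef) > 1e-12:
            stoich[m] = coef
    return LumpedBiomass(
        stoich, [extended_model.reaction_ids[j] for j in lumped], float(v_bm)
    )
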