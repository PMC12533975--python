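"""Elementary flux mode enumeration, filtering and growth/yield scoring.

Elementary flux modes (EFMs) are the support-minimal steady-state flux
vectors of ``{v : S v = 0, v_irrev >= 0}``; any feasible steady-state flux
is a conic combination of them.  Enumeration proceeds by direction-splitting
reversible reactions (making the cone pointed) and running the double
description method with a bit-pattern adjacency test; the combinatorial
futile fwd+rev two-cycles created by splitting are removed afterwards.  A
reversible pathway usable in both directions yields two modes (one per
direction).

A definition-level brute-force enumerator over support subsets is provided
as an independent oracle for small networks.

Each mode can be scored with a biomass yield (v_BM / |v_uptake|, in
gDW/mmol) and an achievable growth rate

    mu = f_enz * v_BM / c_enz,   c_enz = sum_i a_i |v_i|

where ``f_enz`` is the enzyme mass fraction of cell dry weight available to
metabolism (default 0.285 g/gDW) — both quantities invariant under scaling
of the mode.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .model import MetabolicModel

__all__ = [
    "FluxMode",
    "enumerate_efms",
    "brute_force_efms",
    "filter_modes",
    "score_mode",
    "pareto_front",
    "scale_oxygen_cost",
    "is_elementary_support",
]

DEFAULT_F_ENZ = 0.285  # g enzyme per gDW available to metabolic flux
_ZERO = 1e-10


@dataclass
class FluxMode:
    """An elementary flux vector (canonically scaled to max |flux| = 1)."""

    flux: dict
    support: frozenset
    yield_biomass: float | None = None
    enzyme_cost: float | None = None
    growth_estimate: float | None = None

    def vector(self, model: MetabolicModel) -> np.ndarray:
        return np.array([self.flux.get(r, 0.0) for r in model.reaction_ids])


def _canonical(model: MetabolicModel, v: np.ndarray) -> FluxMode | None:
    vmax = np.max(np.abs(v))
    if vmax < _ZERO:
        return None
    v = v / vmax
    v[np.abs(v) < _ZERO] = 0.0
    flux = {r: float(x) for r, x in zip(model.reaction_ids, v) if x != 0.0}
    return FluxMode(flux, frozenset(flux))


def _mode_key(mode: FluxMode):
    return tuple(sorted((r, round(x, 8)) for r, x in mode.flux.items()))


def _split_columns(model: MetabolicModel):
    """Columns of the fully irreversible split system plus back-mapping."""
    cols, back = [], []  # back[j] = (orig index, sign)
    for j in range(model.n_reactions):
        lo, hi = model.lower_bound[j], model.upper_bound[j]
        fwd = hi > 0
        rev = lo < 0
        if fwd:
            cols.append(model.S[:, j])
            back.append((j, 1.0))
        if rev:
            cols.append(-model.S[:, j])
            back.append((j, -1.0))
        if not fwd and not rev:
            # blocked reaction: keep forward column so the id exists but it
            # can never enter a mode (handled by zero ray weight)
            pass
    return (np.column_stack(cols) if cols else np.zeros((model.n_metabolites, 0)), back)


def enumerate_efms(
    model: MetabolicModel, max_reactions: int = 40, allow_large: bool = False
) -> list:
    """Complete, duplicate-free enumeration of elementary flux modes.

    Guarded at ``max_reactions`` columns by default (double description cost
    grows combinatorially); pass ``allow_large=True`` to override.
    """
    if model.n_reactions > max_reactions and not allow_large:
        raise ValueError(
            f"model has {model.n_reactions} reactions (> {max_reactions}); "
            "pass allow_large=True to enumerate anyway"
        )
    S, back = _split_columns(model)
    n = S.shape[1]
    if n == 0:
        return []
    # double description on {x >= 0, S x = 0}: start from the unit rays of the
    # nonnegative orthant and intersect with each mass-balance hyperplane.
    rays = [np.eye(n)[i] for i in range(n)]
    zerosets = [frozenset(range(n)) - {i} for i in range(n)]
    for row in S:
        if not np.any(row):
            continue
        vals = np.array([row @ r for r in rays])
        keep_idx = [i for i, v in enumerate(vals) if abs(v) <= _ZERO]
        pos = [i for i, v in enumerate(vals) if v > _ZERO]
        neg = [i for i, v in enumerate(vals) if v < -_ZERO]
        new_rays = [rays[i] for i in keep_idx]
        new_zero = [zerosets[i] for i in keep_idx]
        for ip, im in itertools.product(pos, neg):
            common = zerosets[ip] & zerosets[im]
            # adjacency: no third ray's zero set contains the intersection
            adjacent = not any(
                k != ip and k != im and common <= zerosets[k]
                for k in range(len(rays))
            )
            if not adjacent:
                continue
            r = vals[ip] * rays[im] - vals[im] * rays[ip]
            r = r / np.max(np.abs(r))
            r[np.abs(r) < _ZERO] = 0.0
            new_rays.append(r)
            new_zero.append(frozenset(np.flatnonzero(r == 0.0)))
        rays, zerosets = new_rays, new_zero
    # map split rays back to net fluxes; drop futile two-cycles and duplicates
    modes, seen = [], set()
    for ray in rays:
        v = np.zeros(model.n_reactions)
        for x, (j, sign) in zip(ray, back):
            v[j] += sign * x
        mode = _canonical(model, v)
        if mode is None:
            continue
        key = _mode_key(mode)
        if key not in seen:
            seen.add(key)
            modes.append(mode)
    return modes


def brute_force_efms(model: MetabolicModel, max_reactions: int = 15) -> list:
    """Definition-level EFM oracle: scan all support subsets.

    A support is kept when its restricted null space is one-dimensional,
    the basis vector has full support and feasible signs, and the support is
    inclusion-minimal among feasible supports.  Intended as an independent
    cross-check for :func:`enumerate_efms` on small networks.
    """
    n = model.n_reactions
    if n > max_reactions:
        raise ValueError(f"brute force limited to {max_reactions} reactions")
    irreversible_fwd = model.lower_bound >= 0
    irreversible_rev = model.upper_bound <= 0
    accepted_supports: list = []
    modes, seen = [], set()
    for size in range(1, n + 1):
        for subset in itertools.combinations(range(n), size):
            sset = set(subset)
            if any(acc < sset for acc in accepted_supports):
                continue
            ns = null_space(model.S[:, subset])
            if ns.shape[1] != 1:
                continue
            basis = ns[:, 0]
            if np.min(np.abs(basis)) < 1e-9:
                continue  # support not fully used: not this subset's mode
            for direction in (1.0, -1.0):
                v = np.zeros(n)
                v[list(subset)] = direction * basis
                ok = all(
                    not (irreversible_fwd[j] and v[j] < -_ZERO)
                    and not (irreversible_rev[j] and v[j] > _ZERO)
                    for j in subset
                )
                if not ok:
                    continue
                mode = _canonical(model, v)
                if mode is None:
                    continue
                key = _mode_key(mode)
                if key not in seen:
                    seen.add(key)
                    modes.append(mode)
                    if sset not in accepted_supports:
                        accepted_supports.append(sset)
    return modes


def filter_modes(
    modes,
    aerobic: bool,
    biomass: str,
    oxygen_uptake: str | None = None,
    excluded_reactions=(),
) -> list:
    """Physiological mode filter.

    Keeps modes with positive biomass flux; aerobic filtering additionally
    requires nonzero oxygen uptake (a negative exchange flux) and zero flux
    through each excluded reaction (e.g. fermentation enzymes known to be
    inactive aerobically).  Anaerobic filtering ignores the exclusion list.
    """
    kept = []
    for m in modes:
        if m.flux.get(biomass, 0.0) <= _ZERO:
            continue
        if aerobic:
            if oxygen_uptake is not None and m.flux.get(oxygen_uptake, 0.0) >= -_ZERO:
                continue
            if any(abs(m.flux.get(r, 0.0)) > _ZERO for r in excluded_reactions):
                continue
        kept.append(m)
    return kept


def score_mode(
    mode: FluxMode,
    cost: dict,
    substrate_uptake: str,
    biomass: str,
    f_enz: float = DEFAULT_F_ENZ,
) -> tuple:
    """Attach (biomass yield, achievable growth rate) to a mode.

    Both quantities are invariant under rescaling of the mode.  A zero
    substrate uptake raises; zero enzyme cost with positive biomass flags an
    unbounded growth estimate.
    """
    v_up = abs(mode.flux.get(substrate_uptake, 0.0))
    if v_up <= _ZERO:
        raise ValueError(f"mode has zero flux through {substrate_uptake!r}; yield undefined")
    v_bm = mode.flux.get(biomass, 0.0)
    c_enz = sum(a * abs(mode.flux.get(r, 0.0)) for r, a in cost.items())
    y = v_bm / v_up
    mu = float("inf") if c_enz <= 0 else f_enz * v_bm / c_enz
    mode.yield_biomass = y
    mode.enzyme_cost = c_enz
    mode.growth_estimate = mu
    return y, mu


def pareto_front(scored_modes) -> list:
    """Modes not dominated in (yield, growth rate), sorted by yield descending."""
    front = []
    for m in scored_modes:
        dominated = any(
            (o.yield_biomass >= m.yield_biomass and o.growth_estimate >= m.growth_estimate)
            and (o.yield_biomass > m.yield_biomass or o.growth_estimate > m.growth_estimate)
            for o in scored_modes
            if o is not m
        )
        if not dominated:
            front.append(m)
    return sorted(front, key=lambda m: -m.yield_biomass)


def scale_oxygen_cost(cost: dict, oxygen_reactions, factor: float) -> dict:
    """Scale the per-flux cost of oxygen-consuming reactions (low-O2 scenario)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    out = dict(cost)
    for r in oxygen_reactions:
        if r not in out:
            raise KeyError(f"unknown costed reaction {r!r}")
        out[r] = out[r] * factor
    return out


def is_elementary_support(model: MetabolicModel, support) -> bool:
    """Rank test: a flux support is elementary iff its restricted null space
    is one-dimensional."""
    idx = [model.reaction_index(r) for r in support]
    if not idx:
        return False
    return null_space(model.S[:, idx]).shape[1] == 1
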