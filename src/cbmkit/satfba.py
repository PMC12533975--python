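"""Saturation FBA: growth maximisation with a concentration-dependent
transporter efficiency.

All reactions keep a fixed enzyme cost per unit flux (at the fitted average
saturation), except the designated substrate transporter, whose saturation
follows irreversible Michaelis-Menten kinetics in the external substrate
concentration:

    sigma_up = c / (Km + c)

Screening the external concentration traces a Monod-type growth curve;
without auxiliary flux bounds each optimum is an elementary flux mode, so
the biomass yield is piecewise constant in the concentration with downward
jumps at mode switches.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import OPTIMAL, FluxDistribution
from .ec import ECModel
from .efm import is_elementary_support

__all__ = [
    "SatFBAResult",
    "transporter_saturation",
    "solve_satfba",
    "screen_concentrations",
    "DEFAULT_KM_MM",
]

#: Michaelis constant of the glucose transporter (mM)
DEFAULT_KM_MM = 0.116
_ZERO = 1e-9


def transporter_saturation(c: float, Km: float = DEFAULT_KM_MM) -> float:
    """Michaelis-Menten transporter saturation c/(Km+c), in [0, 1)."""
    if c < 0:
        raise ValueError("substrate concentration must be nonnegative")
    if Km <= 0:
        raise ValueError("Km must be positive")
    return c / (Km + c)


@dataclass
class SatFBAResult:
    concentration: float
    sigma_up: float
    growth: float
    fluxes: FluxDistribution
    yield_biomass: float
    support_signature: frozenset
    elementary: bool


def solve_satfba(
    ec: ECModel,
    transporter: str,
    c: float,
    Km: float = DEFAULT_KM_MM,
) -> SatFBAResult:
    """Growth-maximising EC-FBA with the transporter cost rescaled to its
    concentration-dependent saturation.

    The transporter's cost (built at the fitted average saturation
    ``ec.sigma``) is replaced by its sigma=1 cost divided by ``sigma_up(c)``;
    at zero concentration the result reports zero growth rather than raising.
    """
    if transporter not in ec.cost:
        raise KeyError(f"transporter {transporter!r} is not costed in the model")
    sigma_up = transporter_saturation(c, Km)
    if sigma_up == 0.0:
        empty = FluxDistribution({}, 0.0, OPTIMAL)
        return SatFBAResult(c, 0.0, 0.0, empty, 0.0, frozenset(), False)
    work = ec.copy()
    work.cost[transporter] = ec.cost[transporter] * ec.sigma / sigma_up
    sol = work.solve(parsimonious=True)
    if sol.status != OPTIMAL:
        empty = FluxDistribution({}, 0.0, sol.status)
        return SatFBAResult(c, sigma_up, 0.0, empty, 0.0, frozenset(), False)
    net = work.net_fluxes(sol)
    vmax = max((abs(v) for v in net.values()), default=0.0)
    support = frozenset(r for r, v in net.items() if abs(v) > _ZERO * max(vmax, 1.0))
    v_up = abs(net.get(ec.parent[transporter][0], 0.0))
    growth = sol.objective_value
    yld = growth / v_up if v_up > 0 else 0.0
    elementary = _net_support_elementary(work, support)
    return SatFBAResult(c, sigma_up, growth, sol, yld, support, elementary)


def _net_support_elementary(ec: ECModel, support) -> bool:
    """Run the EFM rank test on the net support in original-reaction space."""
    import numpy as np

    from .model import MetabolicModel

    # rebuild the original model columns from the split ones
    orig_ids = []
    cols = {}
    for split_id, (orig, sign) in ec.parent.items():
        if orig not in cols:
            orig_ids.append(orig)
            j = ec.base.reaction_index(split_id)
            cols[orig] = sign * ec.base.S[:, j]
    S = np.column_stack([cols[r] for r in orig_ids])
    m = MetabolicModel(
        list(ec.base.metabolite_ids),
        orig_ids,
        S,
        np.full(len(orig_ids), -1.0),
        np.full(len(orig_ids), 1.0),
        {},
    )
    return is_elementary_support(m, support) if support else False


def screen_concentrations(
    ec: ECModel,
    transporter: str,
    grid,
    Km: float = DEFAULT_KM_MM,
) -> list:
    """satFBA over an ascending concentration grid, with switch detection.

    Returns one :class:`SatFBAResult` per grid point; a switch is where the
    optimal support signature changes between consecutive points (robust to
    float noise in the yield trace).
    """
    grid = list(grid)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("concentration grid must be sorted ascending")
    results = [solve_satfba(ec, transporter, c, Km) for c in grid]
    return results


def switch_points(results) -> list:
    """Indices i where the optimal support changes between i-1 and i."""
    return [
        i
        for i in range(1, len(results))
        if results[i].support_signature != results[i - 1].support_signature
    ]
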