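"""Probabilistic max-min driving force (MDF) and flux-force efficacy.

Standard transformed reaction Gibbs energies are treated as a multivariate
normal random vector with mean ``drG0`` and covariance ``Sigma`` (kJ/mol;
the vector covers balanced metabolic reactions only, never exchange or
biomass pseudoreactions).  Writing ``Sigma = Q Q^T`` with ``Q`` an N x q
square-root factor of rank q, any realisation inside the alpha-level
confidence region is ``drG0_mean + Q m`` with ``||m||^2 <= chi2_{q;alpha}``.
The probabilistic MDF maximises the minimum driving force b over the free
parameters m, the log metabolite concentrations c (bounded to a plausible
range) and b:

    max b   s.t.  drG' = drG0_mean + Q m + RT S^T c
                  -sign(v_i) drG'_i >= b   for every flux-carrying reaction
                  ||m||^2 <= chi2_{q;alpha},  ln cmin <= c <= ln cmax

Correlated uncertainty matters: perfectly anti-correlated errors along a
pathway cancel and leave the MDF at its deterministic value, while
independent errors can be exploited in the favourable direction.

The flux-force efficacy eta = tanh(-drG'/(2RT)) is the net-to-total flux
ratio of a reaction at thermodynamic force drG'.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .model import MetabolicModel, FluxDistribution

__all__ = [
    "ThermoParameterSet",
    "ThermodynamicState",
    "factor_covariance",
    "solve_probabilistic_mdf",
    "flux_force_efficacy",
    "efficacy_threshold",
    "group_by_efficacy",
    "GAS_CONSTANT_KJ",
    "DEFAULT_TEMPERATURE_K",
]

GAS_CONSTANT_KJ = 8.314e-3  # kJ / (mol K)
DEFAULT_TEMPERATURE_K = 310.15
DEFAULT_CONC_BOUNDS_M = (1e-6, 1e-2)  # physiologically plausible range, molar
_RANK_CUTOFF = 1e-9


def factor_covariance(covariance: np.ndarray):
    """Eigendecomposition-based square-root factor of a PSD covariance.

    Returns (Q, q) with ``Q @ Q.T`` reconstructing the matrix within 1e-8 and
    q its numerical rank (eigenvalues above ``1e-9 * lambda_max`` retained).
    Raises on asymmetric input or significantly negative eigenvalues.
    """
    cov = np.asarray(covariance, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if cov.size and np.max(np.abs(cov - cov.T)) > 1e-8:
        raise ValueError("covariance must be symmetric (within 1e-8)")
    if not cov.size or not np.any(cov):
        return np.zeros((cov.shape[0], 0)), 0
    w, V = np.linalg.eigh((cov + cov.T) / 2.0)
    lam_max = float(np.max(w))
    if np.min(w) < -1e-6 * max(lam_max, 1.0):
        raise ValueError("covariance is not positive semidefinite")
    keep = w > _RANK_CUTOFF * max(lam_max, 1e-300)
    Q = V[:, keep] * np.sqrt(w[keep])
    return Q, int(np.count_nonzero(keep))


@dataclass
class ThermoParameterSet:
    """Mean standard reaction Gibbs energies with correlated uncertainty."""

    reaction_index: list
    mean: np.ndarray
    covariance: np.ndarray
    Q: np.ndarray = field(default=None)
    q: int = field(default=None)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.Q is None or self.q is None:
            self.Q, self.q = factor_covariance(self.covariance)
        recon = self.Q @ self.Q.T
        if self.covariance.size and np.max(np.abs(recon - self.covariance)) > 1e-8:
            raise ValueError("Q is not a square root of the covariance (within 1e-8)")


@dataclass
class ThermodynamicState:
    """A feasible thermodynamic state returned by the MDF program."""

    log_concentration: dict
    drG_prime: dict
    m: np.ndarray
    b: float
    alpha: float
    status: str
    violated_reactions: list = field(default_factory=list)


def solve_probabilistic_mdf(
    model: MetabolicModel,
    flux: FluxDistribution,
    params: ThermoParameterSet,
    alpha: float = 0.9,
    conc_bounds=DEFAULT_CONC_BOUNDS_M,
    conc_overrides: dict | None = None,
    T: float = DEFAULT_TEMPERATURE_K,
    exempt=(),
) -> ThermodynamicState:
    """Maximise the minimum driving force over the confidence region.

    Every flux-carrying reaction present in ``params.reaction_index`` (and
    not exempted) contributes a sign constraint; reactions absent from the
    parameter set are exempted with a warning, mirroring partial coverage of
    real parameter sets.  ``conc_bounds`` are molar; per-metabolite
    (min, max) overrides via ``conc_overrides``.
    """
    RT = GAS_CONSTANT_KJ * T
    ridx = {r: i for i, r in enumerate(params.reaction_index)}
    vmax = max((abs(v) for v in flux.values.values()), default=0.0)
    cut = 1e-9 * max(vmax, 1.0)
    active, signs = [], []
    for r, v in flux.values.items():
        if abs(v) <= cut or r in exempt:
            continue
        if r not in ridx:
            if r not in model.exchange_set and r not in model.objective:
                warnings.warn(
                    f"reaction {r!r} carries flux but has no thermodynamic "
                    "parameters; exempted from sign constraints",
                    stacklevel=2,
                )
            continue
        active.append(r)
        signs.append(1.0 if v > 0 else -1.0)
    n_met = model.n_metabolites
    q = params.q
    radius2 = float(chi2.ppf(alpha, q)) if (q > 0 and alpha > 0) else 0.0
    use_m = q > 0 and radius2 > 0

    # stoichiometry of active reactions (columns) over all metabolites
    cols = np.column_stack(
        [model.S[:, model.reaction_index(r)] for r in active]
    ) if active else np.zeros((n_met, 0))
    mean_a = np.array([params.mean[ridx[r]] for r in active])
    Q_a = params.Q[[ridx[r] for r in active], :] if use_m else np.zeros((len(active), 0))
    s = np.array(signs)

    lo, hi = conc_bounds
    ln_lo = np.full(n_met, math.log(lo))
    ln_hi = np.full(n_met, math.log(hi))
    if conc_overrides:
        for met, (mlo, mhi) in conc_overrides.items():
            i = model.metabolite_index(met)
            ln_lo[i], ln_hi[i] = math.log(mlo), math.log(mhi)

    nm = Q_a.shape[1] if use_m else 0

    def drg(x):
        m = x[:nm]
        c = x[nm:nm + n_met]
        return mean_a + (Q_a @ m if nm else 0.0) + RT * (cols.T @ c)

    def neg_b(x):
        return -x[-1]

    def neg_b_grad(x):
        g = np.zeros_like(x)
        g[-1] = -1.0
        return g

    cons = []
    if active:
        def force_con(x):
            return -s * drg(x) - x[-1]

        def force_jac(x):
            J = np.zeros((len(active), nm + n_met + 1))
            if nm:
                J[:, :nm] = -(s[:, None] * Q_a)
            J[:, nm:nm + n_met] = -(s[:, None] * (RT * cols.T))
            J[:, -1] = -1.0
            return J

        cons.append({"type": "ineq", "fun": force_con, "jac": force_jac})
    if nm:
        cons.append(
            {
                "type": "ineq",
                "fun": lambda x: radius2 - float(x[:nm] @ x[:nm]),
                "jac": lambda x: np.concatenate(
                    [-2.0 * x[:nm], np.zeros(n_met + 1)]
                ),
            }
        )
    bounds = (
        [(None, None)] * nm
        + list(zip(ln_lo, ln_hi))
        + [(None, None)]
    )
    x0 = np.concatenate([np.zeros(nm), (ln_lo + ln_hi) / 2.0, [0.0]])
    if active:
        x0[-1] = float(np.min(-s * drg(x0)))
    res = minimize(
        neg_b,
        x0,
        jac=neg_b_grad,
        method="SLSQP",
        bounds=bounds,
        constraints=cons,
        options={"maxiter": 1000, "ftol": 1e-12},
    )
    x = res.x
    m = x[:nm]
    c = x[nm:nm + n_met]
    drg_vals = drg(x)
    b = float(np.min(-s * drg_vals)) if active else float("inf")
    status = "optimal"
    violated = []
    if active and (not res.success or b < x[-1] - 1e-6):
        # report the reactions pinning the infeasibility / failure
        order = np.argsort(-s * drg_vals)
        violated = [active[i] for i in order[:3]]
        if not res.success:
            status = "failed" if b > -np.inf else "infeasible"
    m_full = np.zeros(params.q)
    if nm:
        m_full[: len(m)] = m
    return ThermodynamicState(
        dict(zip(model.metabolite_ids, c)),
        dict(zip(active, drg_vals)),
        m_full,
        b,
        alpha,
        status,
        violated,
    )


def flux_force_efficacy(drG_prime, T: float = DEFAULT_TEMPERATURE_K):
    """Flux-force efficacy eta = tanh(-drG'/(2RT)), the net/total flux ratio."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    RT = GAS_CONSTANT_KJ * T
    return np.tanh(-np.asarray(drG_prime, dtype=float) / (2.0 * RT))


def efficacy_threshold(eta: float, T: float = DEFAULT_TEMPERATURE_K) -> float:
    """Invert the flux-force relation: the drG' (kJ/mol) at which the
    efficacy equals ``eta``."""
    if not -1.0 < eta < 1.0:
        raise ValueError("eta must lie strictly inside (-1, 1)")
    RT = GAS_CONSTANT_KJ * T
    return -2.0 * RT * math.atanh(eta)


def group_by_efficacy(
    state: ThermodynamicState,
    flux: FluxDistribution,
    reference_uptake: str,
    flux_fraction: float = 0.025,
    eta_threshold: float = 0.5,
    exclude=(),
    T: float = DEFAULT_TEMPERATURE_K,
):
    """Split flux-carrying reactions into low/high flux-force efficacy groups.

    Reactions carrying at least ``flux_fraction`` of the reference uptake
    flux (default 2.5%) are pooled into eta < threshold (low) and
    eta >= threshold (high) groups; transport/spontaneous reactions can be
    excluded by id.
    """
    v_ref = abs(flux.values.get(reference_uptake, 0.0))
    if v_ref <= 0:
        raise ValueError(f"reference uptake {reference_uptake!r} carries zero flux")
    low, high = [], []
    for r, drg in state.drG_prime.items():
        if r in exclude:
            continue
        if abs(flux.values.get(r, 0.0)) < flux_fraction * v_ref:
            continue
        eta = float(flux_force_efficacy(drg, T))
        (high if eta >= eta_threshold else low).append(r)
    return low, high
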