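# Methods

This note records the models and numerical procedures implemented in
cbmkit, the choices made where the design was genuinely open, and what the
synthetic fixtures do and do not establish.

## Stoichiometric core

Models are dense stoichiometric matrices with per-reaction bounds in
mmol/gDW/h (biomass in 1/h); exchange reactions have a single nonzero
stoichiometric entry and uptake is a negative exchange flux, so configuring
a condition sets the carbon exchange lower bound to `-uptake`. All linear
programs are solved with HiGHS (`scipy.optimize.linprog`) at a feasibility
tolerance of 1e-9; a flux is treated as zero below 1e-9 relative to the
largest flux in the distribution. pFBA is a two-stage LP: the first-stage
optimum is fixed (with a 1e-9 slack) and `Σ|v|` is minimised via variable
splitting `v = p - q`, `p, q ≥ 0`. Production envelopes discretise the
achievable range of a target flux into an equally spaced grid, minimising
and maximising growth with the target fixed; a numerically infeasible
interior point is dropped from the grid rather than failing the envelope.

Equivalent-biomass lumping collapses the biomass reaction plus every
flux-carrying reaction that touches a non-retained metabolite into one
reaction whose coefficients are the net production of each retained
metabolite at the reference flux, scaled to unit biomass flux. This
preserves the reference growth rate by construction (checked by LP on both
models). The scaling convention — per unit biomass flux, with the reference
taken from pFBA — is our reading; other scalings differing by a positive
factor would be equivalent for feasibility purposes.

## Knowledge graph

The graph is a typed `networkx.MultiDiGraph`. Catalysis edges run
protein→reaction and default to class *primary* when uncurated; subunit
edges carry integer stoichiometry ≥ 1 and must be acyclic; coding edges run
gene→polypeptide. Regulation and modification edges are stored and
round-tripped (GML) but deliberately take no part in knockout logic: only
catalytic, subunit and coding requirements are propagated. GPR rules are
sympy Boolean expressions — OR over catalysing proteins of the AND over
their recursive components, with a polypeptide requirement satisfied by any
of its coding genes; orphan/spontaneous reactions yield constant true and
are skipped in disruption analysis. Knockout propagation and GPR evaluation
are two independent code paths and are required (by test) to agree on
exhaustive truth tables.

Essentiality uses the threshold growth < 1e-6 × wild type; the exact
cut-off is unstated in the literature the contract follows, and any value
comfortably below measurable growth behaves identically on the fixtures.
Known false-essential reactions are handled as a caller-supplied exclusion
list, not hard-coded ids. Complex abundances solve
`min ‖P e − p‖₂, e ≥ 0` with `scipy.optimize.nnls` per condition; in
degenerate (non-identifiable) fits NNLS returns one KKT point — the KKT
residual, not uniqueness, is what the tests assert.

## Enzyme-constrained model

Costs follow `a_i = M_i / (k_cat,i · n_sub · 3600 · σ)`: masses in kDa are
read as g/mmol, turnovers converted from 1/s to 1/h exactly once at build
time, and the per-polypeptide turnover convention is corrected by the
enzyme's total polypeptide count, tracked by a flag on the turnover table
so the multiplier is never applied twice. Reversible reactions are split
into `<id>_fwd`/`<id>_rev` copies; reports re-aggregate to net fluxes.
Exchanges, biomass, maintenance and reactions without catalysis edges carry
zero cost. The pool constraint is one inequality row `a^T v ≤ e_tot`
appended to the LP — algebraically identical to the pseudometabolite +
supply-pseudoreaction encoding, and easier to keep exact. A single global σ
per condition is used; transporters without measured turnover default to
65 1/s. Enzyme selection discards secondary catalysis edges and breaks
primary-isozyme ties by measured abundance, falling back (documented) to
the lexicographically smallest id.

## Turnover adjustment

With reference fluxes frozen, the predicted abundance of an enzyme is
`ê = Σ_j t_j 10^{-u_j} / σ_c` with `t_j = a_j(σ=1) v_j^ref`, so each log10
residual is affine in `(u, log10 σ_c)` whenever an enzyme maps to one
flux-carrying reaction. The fit is therefore solved exactly as
bound-constrained ridge least squares (`scipy.optimize.lsq_linear`,
`u ∈ [-2, 2]` by default, ridge weight ρ = 1 by default, σ_c free); the
rare multi-reaction-enzyme case is refined by bounded L-BFGS-B from the
linear solution. Zero measured abundances are dropped (log undefined) with
a count reported. Reactions with zero reference flux everywhere cannot be
adjusted and keep `u = 0`.

Identifiability: because σ_c is free, adding a constant to every `u` in a
connected block of conditions while subtracting it from the block's
`log10 σ_c` leaves all residuals unchanged — the data determine `u` only up
to this gauge, which the ridge resolves toward the minimum-norm adjustment.
The synthetic generator therefore centres its ground-truth adjustments to
zero mean over costed reactions; recovery tests compare on the reference
support. Leave-one-out cross-validation refits without one condition and
predicts it with the held-out scaling chosen by least squares in log space
(the same criterion as training), which makes duplicated conditions an
exact fixed point. Re-estimating reference fluxes with adjusted parameters
(an alternating scheme) is intentionally out of scope.

## Elementary flux modes

Enumeration splits reversible reactions (pointed cone `{x ≥ 0, S x = 0}`)
and runs double description: starting from the unit rays of the orthant,
each mass-balance hyperplane is intersected, combining adjacent
positive/negative ray pairs; adjacency uses the standard zero-set inclusion
test on bit patterns. Back-mapping removes the futile fwd+rev two-cycles
that splitting creates. Modes are canonically scaled to max |flux| = 1 and
deduplicated at 1e-8; a reversible pathway usable in both directions counts
as two modes. A size guard (40 reactions) refuses accidental large inputs;
enumeration at genome scale is explicitly out of scope. The brute-force
oracle scans support subsets (restricted null space one-dimensional, full
support, feasible signs, inclusion-minimal) and is the independent
ground truth for set-equality tests up to 15 reactions.

Mode scoring uses `yield = v_BM/|v_uptake|` and `μ = f_enz v_BM / c_enz`
with `c_enz = Σ a_i |v_i|`; both are scale-invariant, so no normalisation
convention is needed beyond the canonical one. `f_enz` defaults to
0.285 g/gDW (the metabolic enzyme mass fraction for a glucose-grown
reference condition) and is overridable. Low-oxygen scenarios scale the
cost of oxygen-consuming reactions by a configurable factor (1000-fold in
the reference analysis); the oxygen-reaction and aerobic exclusion lists
are configuration, not hard-coded.

## Saturation FBA

Only the designated transporter's cost varies: it is reset to its σ=1 cost
divided by `σ_up = c/(Km + c)` (Km default 0.116 mM); all other costs stay
at the fitted condition σ. The growth-maximising LP is solved
parsimoniously so the reported support is minimal. Switches are detected by
changes in the support signature (fluxes above 1e-9 relative), which is
robust to float noise where yield deltas are not. Elementarity of each
optimum is verified by the rank test (restricted null space dimension 1) on
the net-flux support; with a positive maintenance bound optima become
mixtures and the test correctly fails.

## Probabilistic MDF

The covariance is factored by symmetric eigendecomposition, keeping
eigenvalues above 1e-9 × λ_max (numerical rank q); a significantly negative
eigenvalue (< −1e-6 × λ_max) is rejected. The program maximises b over
(m, c, b) with `Δ_r G' = mean + Q m + RT S^T c`, sign constraints for
flux-carrying covered reactions, `‖m‖² ≤ χ²_{q;α}` and log-concentration
bounds (defaults 1 μM–10 mM; per-metabolite overrides supported). R = 8.314
J/mol/K and T = 310.15 K unless overridden. It is solved with SLSQP
(analytic Jacobians, ftol 1e-12) — the problem is convex (linear objective
and constraints plus one ball constraint) and tiny at the intended scale;
solutions are validated against closed forms: the single-reaction optimum
`b = −ΔG° + RT ln(c_max/c_min)`, the α→0 deterministic limit, the
independent-uncertainty gain `√(χ²_{1;α} σ²)`, and exact cancellation of
perfectly anti-correlated pathway errors. The strict inequality of the
min-driving-force definition is implemented as ≥ (an LP/QCP cannot express
strictness; the optimum is unchanged). Reactions carrying flux but missing
from the parameter set are exempted with a warning, mirroring the partial
coverage of real thermodynamic parameter sets. The mixed-integer estimation
of the thermodynamic state itself is out of scope: the toolkit analyses a
state (flux-force efficacies, low/high-efficacy grouping at a 2.5% flux
share and η = 0.5 by default), it does not infer one.

## Synthetic fixtures

The three toy worlds use small-integer stoichiometries so brute-force
oracles are exact, and every random table draws from its own named
generator derived from one seed, so adding a fixture never perturbs
existing ones. The respirofermentative world is the minimal overflow
topology (respiration: 1 glc + 2 O₂ → 10 ATP with a 1 1/s three-subunit
complex; fermentation: 1 glc → 2 ATP + 2 acetate with a 200 1/s monomer;
biomass: 50 ATP), chosen so the growth/yield front has both modes and the
saturation-FBA switch falls inside the screened 1e-4–10 mM range. Simulated
proteomics uses eight pathway-forcing conditions (acetate export blocked /
anaerobic, four growth rates each) whose reference fluxes are unique and
hence independent of the turnover parameters — this isolates the estimator
from LP degeneracy; condition saturations are drawn log-normally around
0.5, and noise is multiplicative log10-normal.

What passing tests show — and do not. The fixtures establish correctness
of the algorithms (oracle equivalence, closed forms, exact recovery under
the generating model), not predictive performance on real proteomes: real
data violate the constant-saturation assumption, real networks have
degenerate optimal flux distributions, isozyme mappings are not one-to-one,
and measured abundances carry structured (not i.i.d. log-normal) error.
Growth rates and yields of the toys are in model units and are not
calibrated to measured physiology. Problem sizes throughout (≤ 10 reactions
for oracles, 40-point concentration screens, 8 fitting conditions) were
chosen as the smallest at which every qualitative regime of the methods is
exercised.
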