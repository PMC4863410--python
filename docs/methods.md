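# Methods

## Model class and assumptions

A model is an autonomous ODE system ẋ = f(x, p) = S·F(x, p): S is the N×M
integer stoichiometry matrix, F the flux vector.  Three structural
assumptions are required throughout:

1. **Factored fluxes.** Every flux is Fₗ = kₗ·Gₗ(x, q) with a designated
   rate constant kₗ and a factor Gₗ that is strictly positive whenever all
   states and auxiliary parameters q are positive.  All standard rate laws
   (mass action, production, degradation, binding, inhibition `k·B/(q+C)`,
   Michaelis–Menten `k·B/(q+B)`, Hill `k·B^q2/(q1^q2+B^q2)`, power law)
   have this form.  The parser identifies kₗ as the unique `k`-prefixed
   symbol of the flux expression, overridable with a `param=NAME`
   annotation; arbitrary rational fluxes are accepted as kind `custom`,
   with positivity checked by sampling rather than proof.
2. **Self-damping outfluxes.** Every consumed species appears in its own
   outflux factor (the flux vanishes as the species goes to zero).  The
   parser rejects models violating this.
3. **Strictly positive steady states.** Divisions by state values assume a
   positive steady state.  A state without any influx only admits the zero
   steady state; the solver reports this as unsolvable rather than emit
   expressions with poles.

All sympy symbols carry the `positive=True` assumption.  This is not
cosmetic: the assumption system is how the solver *proves* each emitted
expression non-negative (structural subtraction-freeness), with numeric
sampling used only as an independent check in the test suite.

## Conserved quantities

Coefficient-constant conserved quantities (CQs) are an integer-scaled basis
of the left null space of S (coprime coefficients, first non-zero
positive); their number is N − rank(S).  Additional CQs with parameter- or
state-dependent coefficients are found by rewriting ẋ = C(p, x)·x — each
flux term is attributed to the column of the first state (network order)
that divides it, and constant production terms to an appended pseudo-state
that is identically one — and searching for linear dependencies among the
rows of C: all symbols are replaced by random values drawn uniformly from
[0.5, 2], a QR decomposition of Cᵀ locates the first (near-)zero diagonal
entry (tolerance 10⁻⁸ relative to the largest diagonal magnitude), the
triangular dependence is resolved symbolically by a nullspace computation
over the rational-function field, the dependent row is removed and the
search repeats.  A dependence is accepted only when several independent
draws (default 3) agree, and every candidate must pass the symbolic
verification d/dt Σ aⱼ(x,p)·xⱼ ≡ 0 before it is reported — numeric
detection alone is never trusted.  User-declared CQs are parsed, required
to be linear in the states, and verified the same way.

## The cycle-splitting solver

Per-state steady-state equations are kept in cleared-numerator form; the
additive terms are grouped by rate constant (so partially cancelling
appearances of one parameter form a single sign-definite term — essential
after substitution rounds) and split into influxes (positive terms) and
outfluxes (negative terms).  The *dimension* of a state is
min(#influxes, #outfluxes).  Head sets are read off the simplified
quotient xᵢ = Σin/Σout — simplification first, so cancelled appearances do
not create spurious edges.  Elementary cycles (self-loops included) are
enumerated with networkx, capped at 10⁴ with a hard error.

Moves, in preference order, on the shortest cycle (lexicographic
tie-break):

* **Type 0**: a cycle state occurs in an unused CQ → the state becomes a
  free variable, its equation is dropped, the CQ is marked used (each CQ
  can be spent once).
* **Type 1**: a rate constant with a single appearance that is alone on
  its side → direct solve, subtraction-free by construction.
* **Type 2**: single appearance, but same-side siblings whose parameters
  also appear only here → the sibling fluxes are replaced by their ratios
  r_z to the chosen flux; the chosen parameter becomes
  Σ(other side)/(G·(1+Σr_z)) and each sibling
  Σ(other side)·r_z/(G_z·(1+Σr_z)).  No substitution elsewhere is needed.
* **Type 3**: otherwise — the cycle state of minimal dimension is
  transformed the same way on its minimal side, and the moved parameters'
  expressions are substituted into every other active equation, which may
  create new cycles.

A note on the classification: a parameter with a single appearance whose
equation has dimension > 1 is only a "free" Type-2 move when its *sibling*
parameters also have single appearances; otherwise the ratio replacements
force substitutions and the move is a Type 3.  The implementation uses this
operational classification.

Tie-breaks (the formalism does not fix them): among same-type candidates,
network state order first, then influx side before outflux, then lowest
appearance count, then stoichiometry column.  Ratio parameters are named
r1, r2, … in global order of introduction.  The loop is bounded at 10·N
passes; exhaustion, a term with no provable sign, or a sibling flux whose
parameter was already fixed raise `NoPositiveSolutionError` — the known
failure mode for large models whose in/outflux parameters are shared
across many states.

Once the graph is tree-like, roots (states whose quotient contains no
active state) are assigned via xᵢ = Σin/Σout and removed, repeatedly.  The
solver's native output order may reference later-fixed targets;
`back_substitute` iterates the substitution map to a fixed point (cycle
detection guards against solver defects) to produce the independent form.
Contract checks: substituting the independent form into S·F must simplify
to the zero vector, and (#assignments − #ratio definitions) must equal the
number of independent constraints, rank(S) when all CQs are stoichiometric.

## Elimination degree (hardness witness)

To certify what a state-space solve would face, the steady-state system is
reduced to a univariate polynomial: conservation relations substitute one
participating state each (total − rest); then, repeatedly, the lowest-index
remaining equation that is linear in the next state to eliminate is solved
and substituted.  The primitive part of the final numerator is returned as
a polynomial in the kept state.  The elimination order is fixed (network
state order) for determinism; other orders can in principle produce
different spurious factors, which is why the primitive part, not the raw
numerator, is reported.  On the six-state example the degree is 6; on the
three-state feedback loop it is 2 (two steady-state branches); on the open
four-state chain it is 1 (unique steady state).

## Numeric steady states

`newton_steady_state` is a damped Newton iteration on f(x, p) = 0: full
steps, halved up to 20 times when the ∞-norm residual fails to decrease;
tolerance 10⁻¹⁰, at most 100 iterations, default start at the all-ones
vector.  No positivity projection is applied — like any root finder it can
return negative or unstable roots, which is exactly the behaviour the
benchmark's "numeric" baseline needs to exhibit.  Steady-state
sensitivities use the implicit function theorem,
∂x₀/∂p = −(∂f/∂x)⁻¹·∂f/∂p; singular Jacobians are reported, not masked.
Stability is classified by the maximal real part of the state-Jacobian
eigenvalues (|·| < 10⁻⁸ → marginal).  `positive_steady_states` runs Newton
from 50 log-uniform guesses and deduplicates, giving a cheap enumeration
of positive roots with stability labels.  ODE integration for flatness and
conservation checks uses LSODA with rtol 10⁻⁸ / atol 10⁻¹⁰.

`verify_solution` validates a parameterization numerically: free symbols
are drawn log-uniformly from [0.1, 10] (200 draws by default); fixed
targets are evaluated and checked for strict positivity, the rhs residual
‖S·F‖∞ at the implied point must stay below 10⁻⁹, and for the first few
draws the trajectory integrated from the implied state must stay flat to
10⁻⁶ relative.

## Benchmark design

Two simulation studies compare steady-state parameterizations in
multi-start fitting.  Protocol (per case): initialize at the stable
positive steady state of the true parameters, displace species A by
d ∈ {1, 2, 4} at t = 30 (one condition per displacement), observe all
states at 16 (four-state case) or 8 (three-state case) time points — two
pre-stimulus baseline points and the rest spanning [32, 60] to resolve the
response — with Gaussian noise of sd = max(5% of the state's dynamic
range, 0.01).  Fits minimize the weighted least-squares negative
log-likelihood in natural-log parameter space with scipy's trust-region
reflective `least_squares`, analytic Jacobians from forward sensitivity
equations (the augmented ODE ṡ = J_x·s + J_p·(∂p/∂θ), initialized with the
variant's ∂x₀/∂θ), 200 starts drawn log-uniformly from [10⁻², 10²] per
fitted parameter.

True parameters are order-one rate constants chosen so the phenomenon under
study is expressed: the four-state chain uses k0 = 2 > k1 = 1 (positive
steady state with a nearby sign-flip border), the feedback loop uses
k1 = k4 = k6 = 2, others 1, giving discriminant k1²k4k6·(k1²k4k6 −
4k0k2k3k5) = 16·12 > 0 with stable root A ≈ 0.54 and unstable root
A ≈ 7.46 — far enough apart that the largest displacement stays inside the
stable basin.

Abort semantics mirror how steady-state parameterizations actually fail: a
point where the parameterization itself is **undefined** — negative
discriminant, no stable closed-form branch, Newton non-convergence — aborts
the fit (this is the border behaviour that kills sign-indefinite
parameterizations); a plain *integration* failure at a trial step is
treated as an infinitely bad step — the trust region rejects it and
shrinks — while an integration failure at the starting point aborts.  A fit
counts as "global" when its final objective is within 0.5
negative-log-likelihood units of the best converged objective across all
variants on the shared dataset; "aborted" covers optimizer errors,
integration failures and non-finite objectives; everything else is
"local".  Waterfall plateaus are clusters of sorted objectives separated
by more than the same tolerance.

Problem sizes: the headline three-state benchmark uses the full 200 starts
per variant; the ordinal robustness check (non-negative ≥ state-solved ≥
Newton, across ten experiment seeds) uses 40–50 starts per seed and
variant,
and the four-state study is reported at reduced start counts — these sizes
keep a complete replication in the tens of minutes on a single core while
leaving the qualitative and quantitative conclusions unchanged at the
stated tolerances.  Integration tolerances during fitting are rtol 10⁻⁶ /
atol 10⁻⁸ (data are simulated at 10⁻¹⁰/10⁻¹²); at these tolerances the
objective is resolved far below the 0.5-unit plateau scale.

### What the synthetic data do and do not emulate

The generator reproduces the structure of stimulus-response experiments:
steady-state initialization, a step displacement of one species, several
stimulation strengths, homoscedastic-per-state Gaussian noise, and full
observation of all states.  It does **not** emulate partial observability,
observation scaling/offset parameters, non-Gaussian or multiplicative
noise, measurement-replicate structure, or model misspecification — so
passing benchmarks demonstrate the optimization geometry induced by the
steady-state parameterization, not robustness to realistic measurement
models.  Absolute success rates depend on the unpublished details of any
particular study (sampling ranges, noise level, true parameters); the
mechanisms — aborts at infeasibility borders, aborts on the unstable
branch, and the non-negative parameterization's freedom from both — are
the reproducible content, and the ordinal comparison is the robust summary
of it.

### Random fixture networks

`generate_random_network` builds property-test fixtures around a flow
backbone — one true source reaction, a conversion chain visiting every
state in random order, a terminal degradation — so every state has influx
and outflux and a strictly positive steady state is plausible; remaining
reaction slots draw random influx/outflux templates from the standard rate
laws (needs n_reactions ≥ n_states + 1).  Backbone-free random wiring
almost always produces states whose only steady state is zero, which the
formalism deliberately rejects.  Identical seeds give identical networks.

## Known limitations

* Models in which several in/outflux parameters contribute to many states
  can exhaust the pass bound without reaching a tree-like graph; the solver
  raises rather than emit a sign-indefinite solution.
* The solver targets strictly positive steady states; boundary steady
  states (a species at zero) are reported as unsolvable.
* The stoichiometry-matrix row-combination simplification (choosing a
  matrix M to make S̃ = M·S sparser before solving) is acknowledged but not
  implemented (`conserved` works on S as given).
* Rate constants shared across reactions (one symbol scaling two columns)
  are not supported; each column needs its own flux parameter.
* The elimination-degree witness requires each eliminated state to appear
  linearly in some remaining equation; models where every equation is
  non-linear in every state would need a resultant or Gröbner fallback,
  which is not implemented.
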