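"""Cycle-splitting derivation of non-negative steady-state constraints.

The algorithm iterates over the cycles of the steady-state graph and removes
one cycle per pass:

* **Type 0** — a cycle state occurs in an unused conserved quantity; the
  state is released as a free variable and its equation dropped.
* **Type 1** — a flux parameter appearing in a single equation is the only
  flux on its side of that equation; solving for it is a sign-safe division.
* **Type 2** — a flux parameter and all its same-side siblings appear in a
  single equation each; the siblings are replaced by flux ratios r_z (fresh
  free parameters), which keeps every expression subtraction-free without
  touching the rest of the system.
* **Type 3** — otherwise: the equation of the cycle state with minimal
  dimension is solved on its minimal side, ratios are introduced as in
  Type 2, and all further appearances of the moved parameters are
  substituted, which may create new edges and cycles.

Once the graph is tree-like the remaining states are assigned root-first
via x_i = Σ in_i ∕ Σ out_i.  Every produced expression is a composition of
sums, products and quotients of positive quantities, so the parameterization
is non-negative by construction, and every equation solved is linear in its
unknown, so no solution branches are ever created.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import sympy as sp

from .conserved import ConservedQuantity, find_conserved_quantities
from .graph import (
    FluxTerm,
    PairClass,
    PairType,
    StateEquation,
    SteadyStateGraph,
    build_graph,
    find_cycles,
    n_k,
)
from .model import ReactionNetwork, positive_symbol

__all__ = [
    "Provenance",
    "Assignment",
    "LoopRecord",
    "SteadyStateSolution",
    "NoPositiveSolutionError",
    "solve_flux_parameter",
    "ratio_transform",
    "split_cycle_type0",
    "solve_tree",
    "solve_steady_state",
    "back_substitute",
    "classify_move",
    "eliminate_to_univariate",
]


class NoPositiveSolutionError(RuntimeError):
    """The algorithm could not produce a strictly sign-safe parameterization
    (known limitation for large models whose in/outflux parameters are shared
    across many states)."""


class Provenance(enum.Enum):
    TYPE0_FREE_STATE = "type0_free_state"
    TYPE1_SOLVE = "type1_solve"
    TYPE2_TRANSFORM = "type2_transform"
    TYPE3_TRANSFORM = "type3_transform"
    TREE_SOLVE = "tree_solve"
    RATIO_DEFINITION = "ratio_definition"


@dataclass(frozen=True)
class Assignment:
    """target := expression; the expression is non-negative whenever its free
    symbols are positive."""

    target: sp.Symbol
    expression: sp.Expr
    provenance: Provenance

    def __str__(self) -> str:
        return f"{self.target} = {self.expression}"


@dataclass
class LoopRecord:
    """One pass of the cycle-splitting loop (the per-loop trace)."""

    loop: int
    cycle: list[sp.Symbol]
    pair_type: PairType
    state: sp.Symbol
    solved: list[sp.Symbol] = field(default_factory=list)
    consumed_cq: ConservedQuantity | None = None

    def __str__(self) -> str:
        cyc = "[" + ", ".join(str(s) for s in self.cycle) + "]"
        if self.pair_type is PairType.TYPE0:
            return (
                f"loop {self.loop}: cycle {cyc}; Type 0; "
                f"{self.state} is part of CQ {self.consumed_cq}"
            )
        targets = ", ".join(str(t) for t in self.solved)
        return (
            f"loop {self.loop}: cycle {cyc}; Type {int(self.pair_type)}; "
            f"solve equation of {self.state} for {targets}"
        )


@dataclass
class SteadyStateSolution:
    """Ordered steady-state assignments produced by the solver.

    Later entries may reference earlier targets (the solver's native output
    order); :func:`back_substitute` produces the fully independent form.
    """

    network: ReactionNetwork
    assignments: list[Assignment]
    ratio_parameters: list[sp.Symbol]
    free_states: list[sp.Symbol]
    conserved: list[ConservedQuantity]
    trace: list[LoopRecord]
    independent_form: list[Assignment] | None = None

    @property
    def fixed_targets(self) -> list[sp.Symbol]:
        return [a.target for a in self.assignments]

    @property
    def n_fixed(self) -> int:
        return len(self.assignments)

    @property
    def n_ratio_definitions(self) -> int:
        return sum(
            1 for a in self.assignments if a.provenance is Provenance.RATIO_DEFINITION
        )

    def free_symbols(self) -> set[sp.Symbol]:
        """Symbols the parameterization leaves free."""
        fixed = set(self.fixed_targets)
        free: set[sp.Symbol] = set(self.free_states) | set(self.ratio_parameters)
        for a in self.independent_form or self.assignments:
            free |= a.expression.free_symbols
        return free - fixed

    def substitution_map(self) -> dict[sp.Symbol, sp.Expr]:
        form = self.independent_form
        if form is None:
            form = back_substitute(self).independent_form
        return {a.target: a.expression for a in form}

    def residuals(self) -> list[sp.Expr]:
        """S·F with the independent form substituted (all-zero on success)."""
        subs = self.substitution_map()
        return [
            sp.simplify(sp.cancel(sp.together(expr.subs(subs))))
            for expr in self.network.rhs()
        ]

    def summary(self) -> str:
        lines = [f"steady-state solution for network {self.network.name or '?'}"]
        lines += [f"  {rec}" for rec in self.trace]
        lines.append("assignments:")
        lines += [f"  {a}  [{a.provenance.value}]" for a in self.assignments]
        free = sorted(self.free_symbols(), key=str)
        lines.append("free: " + ", ".join(str(s) for s in free))
        return "\n".join(lines)


def _require_nonnegative(expr: sp.Expr, context: str) -> sp.Expr:
    expr = sp.cancel(sp.together(expr))
    if expr.is_nonnegative:
        return expr
    simplified = sp.simplify(expr)
    if simplified.is_nonnegative:
        return simplified
    raise NoPositiveSolutionError(
        f"{context}: expression {expr} is not provably non-negative"
    )


def solve_flux_parameter(
    equation: StateEquation,
    flux_parameter: sp.Symbol,
    provenance: Provenance = Provenance.TYPE1_SOLVE,
) -> Assignment:
    """Solve 0 = Σ in − Σ out for a parameter that is alone on its side.

    The result −(1/(S_il·G_l))·Σ_{j≠l} S_ij·k_j·G_j is then a quotient of
    same-sign sums and therefore subtraction-free.
    """
    term = equation.term_for(flux_parameter)
    same_side = equation.side(term.sign)
    if len(same_side) != 1:
        raise NoPositiveSolutionError(
            f"{flux_parameter} shares its side of the equation of "
            f"{equation.state} with other fluxes; use ratio_transform"
        )
    other_side = equation.side(-term.sign)
    numerator = sp.Add(*(t.magnitude for t in other_side))
    expr = _require_nonnegative(
        numerator / term.factor, f"solve for {flux_parameter}"
    )
    return Assignment(target=flux_parameter, expression=expr, provenance=provenance)


def ratio_transform(
    equation: StateEquation,
    flux_parameter: sp.Symbol,
    side: str = "auto",
    ratio_namer=None,
    provenance: Provenance = Provenance.TYPE2_TRANSFORM,
) -> list[Assignment]:
    """Solve for a parameter whose side carries several fluxes.

    The sibling fluxes are replaced by their ratios r_z to the chosen flux;
    the chosen parameter becomes (Σ other side)/(G·(1 + Σ r_z)) and each
    sibling parameter (Σ other side)·r_z/(G_z·(1 + Σ r_z)) — all
    subtraction-free.  With a single flux on the side this degenerates to the
    direct solve and introduces no ratios.
    """
    term = equation.term_for(flux_parameter)
    if side != "auto":
        expected = 1 if side == "influx" else -1
        if term.sign != expected:
            raise ValueError(
                f"{flux_parameter} is not on the {side} side of the equation of "
                f"{equation.state}"
            )
    same_side = equation.side(term.sign)
    siblings = [t for t in same_side if t is not term]
    if not siblings:
        return [solve_flux_parameter(equation, flux_parameter, provenance)]
    for sib in siblings:
        if sib.parameter is None:
            raise NoPositiveSolutionError(
                f"sibling flux {sib.magnitude} of {flux_parameter} carries no "
                "free flux parameter (already fixed): cannot form a ratio"
            )
    if ratio_namer is None:
        counter = iter(range(1, len(siblings) + 1))
        ratio_namer = lambda: positive_symbol(f"r{next(counter)}")

    other_side = equation.side(-term.sign)
    other_sum = sp.Add(*(t.magnitude for t in other_side))
    ratios = [ratio_namer() for _ in siblings]
    denom = 1 + sp.Add(*ratios)

    assignments = [
        Assignment(
            target=flux_parameter,
            expression=_require_nonnegative(
                other_sum / (term.factor * denom), f"transform {flux_parameter}"
            ),
            provenance=provenance,
        )
    ]
    for sib, r in zip(siblings, ratios):
        assignments.append(
            Assignment(
                target=sib.parameter,
                expression=_require_nonnegative(
                    other_sum * r / (sib.factor * denom),
                    f"ratio replacement of {sib.parameter}",
                ),
                provenance=Provenance.RATIO_DEFINITION,
            )
        )
    return assignments


def split_cycle_type0(
    cycle: list[sp.Symbol], cqs: list[ConservedQuantity]
) -> tuple[sp.Symbol, ConservedQuantity]:
    """Release a cycle state that occurs in an unused conserved quantity.

    The CQ is marked used (each CQ can split only one cycle).  Raises
    ``LookupError`` when no cycle state occurs in any unused CQ.
    """
    for state in cycle:
        for cq in cqs:
            if not cq.used and cq.involves(state):
                cq.used = True
                return state, cq
    raise LookupError("no cycle state appears in an unused conserved quantity")


def classify_move(
    state: sp.Symbol,
    flux_parameter: sp.Symbol,
    graph: SteadyStateGraph,
    cqs: list[ConservedQuantity],
) -> PairClass:
    """Alias of :func:`crnsteady.graph.classify_pair` (the classification
    the move selection actually uses)."""
    from .graph import classify_pair

    return classify_pair(state, flux_parameter, graph, cqs)


def solve_tree(graph: SteadyStateGraph) -> list[Assignment]:
    """Root-first assignment of a tree-like graph via x_i = Σ in ∕ Σ out."""
    active = list(graph.active_states)
    assignments: list[Assignment] = []
    while active:
        active_set = set(active)
        root = next(
            (s for s in active if not graph.equations[s].heads(active_set)), None
        )
        if root is None:
            raise NoPositiveSolutionError("graph is not tree-like")
        expr = _require_nonnegative(
            graph.equations[root].solved_rhs(), f"tree solve of {root}"
        )
        if expr == 0:
            # a state without influx only admits the zero steady state,
            # which breaks the strictly positive parameterization
            raise NoPositiveSolutionError(
                f"state {root} has no influx: only the zero steady state exists"
            )
        assignments.append(
            Assignment(target=root, expression=expr, provenance=Provenance.TREE_SOLVE)
        )
        active.remove(root)
    return assignments


@dataclass(frozen=True)
class _Candidate:
    state: sp.Symbol
    term: FluxTerm
    n_k: int
    column: int
    alone: bool
    siblings_free: bool


def solve_steady_state(
    network: ReactionNetwork,
    manual_cqs: list[str] | None = None,
    detect_state_dependent_cqs: bool = True,
    max_passes: int | None = None,
    seed: int = 0,
) -> SteadyStateSolution:
    """Run the full cycle-splitting algorithm on a network.

    Returns the ordered assignment list together with the introduced ratio
    parameters, the states released as free variables, and the per-loop
    trace.  Raises :class:`NoPositiveSolutionError` if the pass bound
    (10·N by default) is exhausted or no sign-safe move exists.
    """
    cqs = find_conserved_quantities(
        network,
        manual=manual_cqs,
        detect_state_dependent=detect_state_dependent_cqs,
        seed=seed,
    )
    if max_passes is None:
        max_passes = 10 * network.n_states

    expressions = {s: e for s, e in zip(network.states, network.rhs())}
    active = list(network.states)
    flux_params = network.flux_parameters
    column = {k: i for i, k in enumerate(flux_params)}

    assignments: list[Assignment] = []
    ratio_parameters: list[sp.Symbol] = []
    free_states: list[sp.Symbol] = []
    trace: list[LoopRecord] = []
    ratio_count = 0

    def next_ratio() -> sp.Symbol:
        nonlocal ratio_count
        ratio_count += 1
        r = positive_symbol(f"r{ratio_count}")
        ratio_parameters.append(r)
        return r

    for loop in range(1, max_passes + 1):
        graph = build_graph(
            {s: expressions[s] for s in active}, active, flux_params
        )
        cycles = find_cycles(graph)
        if not cycles:
            assignments.extend(solve_tree(graph))
            break
        cycle = cycles[0]

        # Type 0: split via an unused conserved quantity
        try:
            freed, cq = split_cycle_type0(cycle, cqs)
        except LookupError:
            freed = None
        if freed is not None:
            trace.append(
                LoopRecord(loop, cycle, PairType.TYPE0, freed, consumed_cq=cq)
            )
            active.remove(freed)
            free_states.append(freed)
            del expressions[freed]
            continue

        # candidate (state, parameter) pairs over the cycle
        candidates: list[_Candidate] = []
        for state in cycle:
            eq = graph.equations[state]
            for term in eq.terms():
                if term.parameter is None or term.parameter not in column:
                    continue
                same_side = eq.side(term.sign)
                candidates.append(
                    _Candidate(
                        state=state,
                        term=term,
                        n_k=n_k(term.parameter, graph.equations),
                        column=column[term.parameter],
                        alone=len(same_side) == 1,
                        siblings_free=all(
                            t.parameter is not None
                            for t in same_side
                            if t is not term
                        ),
                    )
                )

        move = _pick_move(candidates, graph, network, cycle)
        if move is None:
            raise NoPositiveSolutionError(
                f"no sign-safe move available for cycle "
                f"{[str(s) for s in cycle]}"
            )
        chosen, pair_type = move
        eq = graph.equations[chosen.state]
        if chosen.alone:
            new_assignments = [
                solve_flux_parameter(
                    eq,
                    chosen.term.parameter,
                    provenance=(
                        Provenance.TYPE1_SOLVE
                        if pair_type is PairType.TYPE1
                        else Provenance.TYPE3_TRANSFORM
                    ),
                )
            ]
        else:
            new_assignments = ratio_transform(
                eq,
                chosen.term.parameter,
                ratio_namer=next_ratio,
                provenance=(
                    Provenance.TYPE2_TRANSFORM
                    if pair_type is PairType.TYPE2
                    else Provenance.TYPE3_TRANSFORM
                ),
            )

        for a in new_assignments:
            if a.target in (x.target for x in assignments):
                raise NoPositiveSolutionError(
                    f"parameter {a.target} was already fixed (substitution conflict)"
                )
        assignments.extend(new_assignments)
        trace.append(
            LoopRecord(
                loop,
                cycle,
                pair_type,
                chosen.state,
                solved=[a.target for a in new_assignments],
            )
        )
        active.remove(chosen.state)
        free_states.append(chosen.state)
        del expressions[chosen.state]
        subs_map = {a.target: a.expression for a in new_assignments}
        for s in active:
            expressions[s] = expressions[s].subs(subs_map)
    else:
        raise NoPositiveSolutionError(
            f"pass bound {max_passes} exhausted without reaching a tree-like graph"
        )

    solution = SteadyStateSolution(
        network=network,
        assignments=assignments,
        ratio_parameters=ratio_parameters,
        free_states=free_states,
        conserved=cqs,
        trace=trace,
    )
    return back_substitute(solution)


def _pick_move(
    candidates: list[_Candidate],
    graph: SteadyStateGraph,
    network: ReactionNetwork,
    cycle: list[sp.Symbol],
) -> tuple[_Candidate, PairType] | None:
    """Deterministic move selection: Type 1, then Type 2, then Type 3 on the
    minimal-dimension cycle state.  Ties break by network state order, then
    influx side before outflux, then lowest n_k, then stoichiometry column
    order."""
    state_order = {s: i for i, s in enumerate(network.states)}

    def sort_key(c: _Candidate):
        return (state_order[c.state], 0 if c.term.sign > 0 else 1, c.n_k, c.column)

    type1 = [c for c in candidates if c.n_k == 1 and c.alone]
    if type1:
        return min(type1, key=sort_key), PairType.TYPE1

    def is_type2(c: _Candidate) -> bool:
        if c.n_k != 1 or not c.siblings_free:
            return False
        eq = graph.equations[c.state]
        return all(
            n_k(t.parameter, graph.equations) == 1
            for t in eq.side(c.term.sign)
            if t is not c.term
        )

    type2 = [c for c in candidates if is_type2(c)]
    if type2:
        return min(type2, key=sort_key), PairType.TYPE2

    # Type 3: minimal-dimension state first (ties by network state order)
    states = sorted(
        {c.state for c in candidates},
        key=lambda s: (graph.equations[s].dimension, state_order[s]),
    )
    for state in states:
        eq = graph.equations[state]
        for sign in (1, -1) if eq.mu <= eq.nu else (-1, 1):
            viable = [
                c
                for c in candidates
                if c.state == state and c.term.sign == sign and (c.alone or c.siblings_free)
            ]
            if viable:
                return min(viable, key=sort_key), PairType.TYPE3
    return None


def back_substitute(solution: SteadyStateSolution) -> SteadyStateSolution:
    """Populate ``independent_form``: no assignment references another's
    target.  Raises on cyclic references (which would indicate a solver
    defect)."""
    mapping = {a.target: a.expression for a in solution.assignments}
    targets = set(mapping)
    for _ in range(len(mapping) + 1):
        dirty = False
        for t, e in mapping.items():
            if e.free_symbols & targets:
                mapping[t] = sp.cancel(sp.together(e.subs(mapping)))
                dirty = True
        if not dirty:
            break
    else:
        raise NoPositiveSolutionError("cyclic references among assignments")
    solution.independent_form = [
        Assignment(a.target, mapping[a.target], a.provenance)
        for a in solution.assignments
    ]
    return solution


# ---------------------------------------------------------------------------
# hardness witness: eliminate to a univariate polynomial in one state
# ---------------------------------------------------------------------------


def eliminate_to_univariate(
    network: ReactionNetwork, target: sp.Symbol
) -> sp.Poly:
    """Reduce the state-solved steady-state system to a polynomial in one
    state.

    Conservation relations first replace one participating state each (the
    last, in network order, substituting total − rest); the remaining states
    are then eliminated one at a time by solving, at each step, the
    lowest-index remaining equation that is linear in the state.  The
    returned polynomial certifies the degree a state-space solve would face.
    """
    from .conserved import stoichiometric_cqs

    equations = [sp.together(e) for e in network.rhs()]
    states = list(network.states)
    if target not in states:
        raise ValueError(f"{target} is not a state of the network")

    replaced: dict[sp.Symbol, sp.Expr] = {}
    drop_rows: set[int] = set()
    for cq in stoichiometric_cqs(network):
        candidates = [
            s for s in states if cq.involves(s) and s != target and s not in replaced
        ]
        if not candidates:
            continue
        s = candidates[-1]
        rest = sp.Add(
            *(a * x for x, a in cq.coefficients.items() if x != s)
        )
        replaced[s] = sp.cancel((cq.total_symbol - rest) / cq.coefficients[s])
        drop_rows.add(states.index(s))
    eqs = [
        sp.cancel(sp.together(e.subs(replaced)))
        for i, e in enumerate(equations)
        if i not in drop_rows
    ]

    to_eliminate = [s for s in states if s != target and s not in replaced]
    for s in to_eliminate:
        solved = None
        for idx, e in enumerate(eqs):
            if s not in e.free_symbols:
                continue
            numerator = sp.fraction(sp.cancel(sp.together(e)))[0]
            try:
                poly = sp.Poly(numerator, s)
            except sp.PolynomialError:
                continue
            if poly.degree() == 1:
                a, b = poly.coeff_monomial(s), poly.coeff_monomial(1)
                solved = (idx, sp.cancel(-b / a))
                break
        if solved is None:
            raise NoPositiveSolutionError(
                f"no remaining equation is linear in {s}; elimination stalled"
            )
        idx, expr = solved
        eqs = [
            sp.cancel(sp.together(e.subs(s, expr)))
            for j, e in enumerate(eqs)
            if j != idx
        ]

    if len(eqs) != 1:
        raise RuntimeError(
            f"elimination left {len(eqs)} equations; expected exactly one"
        )
    numerator = sp.fraction(sp.cancel(sp.together(eqs[0])))[0]
    poly = sp.Poly(sp.expand(numerator), target)
    return poly.primitive()[1]
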