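"""Steady-state equations in influx/outflux form and the steady-state graph.

Each steady-state equation 0 = Σ in_i − x_i·Σ out_i is solved for its state,
x_i = Σ in_i ∕ Σ out_i.  States appearing on the right-hand side of that
quotient are the *heads* of x_i; the directed graph with an edge x_j → x_i
whenever x_j is a head of x_i is the steady-state graph.  A cycle-free
("tree-like") graph can be solved root-first; cycles — including self-loops
from equations non-linear in their own state — are what the solver has to
split.

Pairs (state, flux parameter) are classified into four move types:

* Type 0 — the state appears in an unused conserved quantity; the cycle is
  split for free by releasing the state.
* Type 1 — the parameter appears in a single equation (n_k = 1) and the
  state has dimension one (min(#influxes, #outfluxes) = 1): a direct,
  sign-safe solve.
* Type 2 — n_k = 1 but the dimension exceeds one: solving needs the
  flux-ratio transformation to stay subtraction-free.
* Type 3 — everything else; solving additionally substitutes the parameter's
  expression into its other equations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import sympy as sp

from .conserved import ConservedQuantity
from .model import ReactionNetwork

__all__ = [
    "FluxTerm",
    "StateEquation",
    "SteadyStateGraph",
    "PairType",
    "PairClass",
    "UnsolvableStateError",
    "MixedSignError",
    "CycleExplosionError",
    "state_equation",
    "build_graph",
    "find_cycles",
    "n_k",
    "classify_pair",
]

MAX_CYCLES = 10_000


class UnsolvableStateError(ValueError):
    """The equation has influxes but no outflux: 0 = Σ in_i cannot be solved
    for the state by division."""


class MixedSignError(ValueError):
    """An additive term of a steady-state equation has no definite sign, so
    the influx/outflux split (and the positivity argument) breaks down."""


class CycleExplosionError(RuntimeError):
    """More elementary cycles than the enumeration cap."""


@dataclass(frozen=True)
class FluxTerm:
    """One signed additive term of a steady-state equation.

    ``magnitude`` is the positive part (the term is ``sign*magnitude``);
    ``parameter`` is the free flux parameter scaling the term, if any
    (``magnitude = parameter * factor``).
    """

    sign: int  # +1 influx, -1 outflux
    magnitude: sp.Expr
    parameter: sp.Symbol | None

    @property
    def factor(self) -> sp.Expr:
        if self.parameter is None:
            return self.magnitude
        return sp.cancel(self.magnitude / self.parameter)


@dataclass
class StateEquation:
    """A steady-state equation split into influxes and outfluxes."""

    state: sp.Symbol
    influxes: list[FluxTerm]
    outfluxes: list[FluxTerm]
    expression: sp.Expr  # Σ in − Σ out (the cleared numerator of f_i)

    @property
    def mu(self) -> int:
        return len(self.influxes)

    @property
    def nu(self) -> int:
        return len(self.outfluxes)

    @property
    def dimension(self) -> int:
        return min(self.mu, self.nu)

    @property
    def outflux_factors(self) -> list[sp.Expr]:
        """Each outflux divided by the state (the out_i of the formalism)."""
        return [sp.cancel(t.magnitude / self.state) for t in self.outfluxes]

    def solved_rhs(self) -> sp.Expr:
        """x_i = Σ in_i ∕ Σ out_i; raises if there is no outflux."""
        if not self.outfluxes:
            if not self.influxes:
                return sp.Integer(0)
            raise UnsolvableStateError(
                f"state {self.state}: influxes but no outflux"
            )
        if not self.influxes:
            return sp.Integer(0)
        return sp.cancel(
            sp.Add(*(t.magnitude for t in self.influxes))
            / sp.Add(*self.outflux_factors)
        )

    def heads(self, active: set[sp.Symbol]) -> set[sp.Symbol]:
        """Active states appearing in the simplified solved form."""
        if not self.influxes and not self.outfluxes:
            return set()
        try:
            rhs = self.solved_rhs()
        except UnsolvableStateError:
            rhs = self.expression  # fall back to raw appearance
        return set(rhs.free_symbols) & active

    def terms(self) -> list[FluxTerm]:
        return self.influxes + self.outfluxes

    def side(self, sign: int) -> list[FluxTerm]:
        return self.influxes if sign > 0 else self.outfluxes

    def term_for(self, parameter: sp.Symbol) -> FluxTerm:
        for t in self.terms():
            if t.parameter == parameter:
                return t
        raise KeyError(f"{parameter} does not contribute to equation of {self.state}")


def _signed(expr: sp.Expr) -> tuple[int, sp.Expr] | None:
    """Definite sign of an expression under the positivity assumptions."""
    expr = sp.cancel(sp.together(expr))
    if expr.is_positive:
        return 1, expr
    if expr.is_negative:
        return -1, -expr
    simplified = sp.simplify(expr)
    if simplified.is_positive:
        return 1, simplified
    if simplified.is_negative:
        return -1, -simplified
    if simplified.is_zero:
        return None
    raise MixedSignError(f"term {expr} has no definite sign")


def state_equation(
    source: ReactionNetwork | sp.Expr,
    state: sp.Symbol,
    active: set[sp.Symbol] | None = None,
    flux_parameters: list[sp.Symbol] | None = None,
) -> StateEquation:
    """Build the influx/outflux form of a steady-state equation.

    ``source`` is either a network (the equation is the corresponding row of
    S·F) or an explicit right-hand-side expression.  Denominators (always
    positive here) are cleared; additive terms are grouped by flux parameter,
    so a parameter whose appearances partially cancel is represented by a
    single sign-definite term — essential after substitution rounds.
    """
    if isinstance(source, ReactionNetwork):
        expr = source.rhs()[source.state_index(state)]
        if flux_parameters is None:
            flux_parameters = source.flux_parameters
    else:
        expr = source
        if flux_parameters is None:
            flux_parameters = sorted(
                (s for s in expr.free_symbols if str(s).startswith("k")), key=str
            )

    numerator, denominator = sp.fraction(sp.cancel(sp.together(expr)))
    if denominator.is_negative:
        numerator = -numerator
    expanded = sp.expand(numerator)

    influxes: list[FluxTerm] = []
    outfluxes: list[FluxTerm] = []
    rest = expanded
    for k in flux_parameters:
        if k not in rest.free_symbols:
            continue
        poly_deg = sp.degree(sp.Poly(rest, k))
        if poly_deg != 1:
            raise MixedSignError(
                f"equation of {state} is not linear in flux parameter {k}"
            )
        coeff = rest.coeff(k, 1)
        rest = sp.expand(rest - coeff * k)
        signed = _signed(coeff * k)
        if signed is None:
            continue
        sign, magnitude = signed
        term = FluxTerm(sign=sign, magnitude=magnitude, parameter=k)
        (influxes if sign > 0 else outfluxes).append(term)
    rest = sp.cancel(sp.together(rest))
    if rest != 0:
        for piece in sp.Add.make_args(sp.expand(rest)):
            signed = _signed(piece)
            if signed is None:
                continue
            sign, magnitude = signed
            term = FluxTerm(sign=sign, magnitude=magnitude, parameter=None)
            (influxes if sign > 0 else outfluxes).append(term)

    full = sp.Add(*(t.sign * t.magnitude for t in influxes + outfluxes))
    return StateEquation(
        state=state, influxes=influxes, outfluxes=outfluxes, expression=full
    )


@dataclass
class SteadyStateGraph:
    """Adjacency structure of the steady-state equations over active states."""

    active_states: list[sp.Symbol]
    equations: dict[sp.Symbol, StateEquation]
    adjacency: np.ndarray = field(repr=False)

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(str(s) for s in self.active_states)
        n = len(self.active_states)
        for j in range(n):
            for i in range(n):
                if self.adjacency[j, i]:
                    g.add_edge(str(self.active_states[j]), str(self.active_states[i]))
        return g

    def is_tree_like(self) -> bool:
        return not find_cycles(self)

    def to_dot(self) -> str:
        lines = ["digraph steady_state {"]
        for s in self.active_states:
            lines.append(f'  "{s}";')
        n = len(self.active_states)
        for j in range(n):
            for i in range(n):
                if self.adjacency[j, i]:
                    lines.append(
                        f'  "{self.active_states[j]}" -> "{self.active_states[i]}";'
                    )
        lines.append("}")
        return "\n".join(lines)


def build_graph(
    source: ReactionNetwork | dict[sp.Symbol, sp.Expr],
    active: list[sp.Symbol] | None = None,
    flux_parameters: list[sp.Symbol] | None = None,
) -> SteadyStateGraph:
    """Steady-state graph over the active states (node order = state order).

    ``source`` may be a network or a mapping state → current equation
    expression (as maintained by the solver between substitution rounds).
    """
    if isinstance(source, ReactionNetwork):
        if active is None:
            active = list(source.states)
        expressions = {
            s: source.rhs()[source.state_index(s)] for s in active
        }
        flux_parameters = source.flux_parameters
    else:
        expressions = source
        if active is None:
            active = list(source.keys())

    active = list(active)
    active_set = set(active)
    equations = {
        s: state_equation(expressions[s], s, active_set, flux_parameters)
        for s in active
    }
    n = len(active)
    adjacency = np.zeros((n, n), dtype=int)
    index = {s: i for i, s in enumerate(active)}
    for s in active:
        for head in equations[s].heads(active_set):
            adjacency[index[head], index[s]] = 1
    return SteadyStateGraph(active_states=active, equations=equations, adjacency=adjacency)


def find_cycles(graph: SteadyStateGraph, cap: int = MAX_CYCLES) -> list[list[sp.Symbol]]:
    """All elementary cycles (self-loops included), shortest first, ties
    broken lexicographically by state names."""
    by_name = {str(s): s for s in graph.active_states}
    cycles = []
    for cycle in nx.simple_cycles(graph.digraph()):
        # rotate so the lexicographically smallest node starts the cycle
        start = min(range(len(cycle)), key=lambda i: cycle[i])
        rotated = cycle[start:] + cycle[:start]
        cycles.append([by_name[name] for name in rotated])
        if len(cycles) > cap:
            raise CycleExplosionError(f"more than {cap} elementary cycles")
    cycles.sort(key=lambda c: (len(c), [str(s) for s in c]))
    return cycles


def n_k(
    flux_parameter: sp.Symbol,
    equations: dict[sp.Symbol, StateEquation] | ReactionNetwork,
) -> int:
    """Number of active steady-state equations containing the parameter.

    On the full, unsubstituted system this equals the number of non-zero
    entries in the parameter's stoichiometry column.
    """
    if isinstance(equations, ReactionNetwork):
        network = equations
        if flux_parameter not in network.flux_parameters:
            raise KeyError(f"unknown flux parameter {flux_parameter}")
        col = network.flux_parameters.index(flux_parameter)
        return int(np.count_nonzero(network.stoichiometry[:, col]))
    return sum(
        1 for eq in equations.values() if flux_parameter in eq.expression.free_symbols
    )


class PairType(enum.IntEnum):
    TYPE0 = 0
    TYPE1 = 1
    TYPE2 = 2
    TYPE3 = 3


@dataclass(frozen=True)
class PairClass:
    state: sp.Symbol
    flux_parameter: sp.Symbol | None
    type: PairType
    n_k: int
    dim: int


def classify_pair(
    state: sp.Symbol,
    flux_parameter: sp.Symbol | None,
    graph: SteadyStateGraph,
    cqs: list[ConservedQuantity],
) -> PairClass:
    """Classify a (state, flux parameter) pair into Types 0–3.

    Only *unused* conserved quantities count for Type 0 (each CQ splits at
    most one cycle).  Type 1 requires the parameter to appear in this single
    equation *and* to be the only flux on its side (the sign-safe direct
    solve); Type 2 additionally allows same-side sibling fluxes provided
    each sibling's parameter also appears in this equation only, so the
    ratio replacements trigger no substitutions elsewhere; everything else
    is Type 3.
    """
    equation = graph.equations[state]
    dim = equation.dimension
    if any(not cq.used and cq.involves(state) for cq in cqs):
        return PairClass(state, flux_parameter, PairType.TYPE0, 0, dim)
    if flux_parameter is None:
        raise ValueError("non-Type-0 classification needs a flux parameter")
    term = equation.term_for(flux_parameter)  # raises if not contributing
    appearances = n_k(flux_parameter, graph.equations)
    same_side = equation.side(term.sign)
    if appearances == 1 and len(same_side) == 1:
        t = PairType.TYPE1
    elif appearances == 1 and all(
        s.parameter is not None and n_k(s.parameter, graph.equations) == 1
        for s in same_side
        if s is not term
    ):
        t = PairType.TYPE2
    else:
        t = PairType.TYPE3
    return PairClass(state, flux_parameter, t, appearances, dim)
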