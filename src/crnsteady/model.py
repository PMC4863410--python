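"""Reaction-network models in the stoichiometric decomposition f(x, p) = S·F(x, p).

A network is a list of reactions over N species.  Each reaction carries a flux
of the form F_l = k_l · G_l(x, q): a designated *flux parameter* k_l times a
factor G_l that is strictly positive whenever states and auxiliary parameters
q are strictly positive (mass action, production, inhibition,
Michaelis-Menten, Hill and power-law kinetics all have this form).  The
right-hand side of the ODE is assembled as the matrix product S·F with S the
N×M integer stoichiometry matrix.

All symbols are created with the sympy ``positive=True`` assumption: species
concentrations and kinetic parameters are positive quantities, and the
assumption lets sympy certify positivity of derived steady-state expressions.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

__all__ = [
    "RateLawKind",
    "RateLaw",
    "Reaction",
    "ReactionNetwork",
    "ModelSyntaxError",
    "positive_symbol",
    "parse_expression",
    "parse_network",
    "rhs",
    "validate_network",
    "generate_random_network",
]


def positive_symbol(name: str) -> sp.Symbol:
    """A sympy symbol carrying the positivity assumption."""
    return sp.Symbol(name, positive=True)


_PARSE_NAMESPACE = {
    "Symbol": sp.Symbol,
    "Integer": sp.Integer,
    "Float": sp.Float,
    "Rational": sp.Rational,
}


def parse_expression(text: str) -> sp.Expr:
    """Parse an expression string; every identifier becomes a positive
    symbol (no implicit mathematical constants or functions)."""
    from sympy.parsing.sympy_parser import parse_expr

    expr = parse_expr(text.replace("^", "**"), global_dict=dict(_PARSE_NAMESPACE))
    return expr.subs({s: positive_symbol(s.name) for s in expr.free_symbols})


class RateLawKind(enum.Enum):
    MASS_ACTION = "mass_action"
    PRODUCTION = "production"
    INHIBITION = "inhibition"
    MICHAELIS_MENTEN = "michaelis_menten"
    HILL = "hill"
    POWER_LAW = "power_law"
    CUSTOM = "custom"


@dataclass(frozen=True)
class RateLaw:
    """Flux in the factored form k_l·G_l(x, q).

    ``flux_parameter`` is the designated proportionality constant k_l;
    ``factor`` is G_l, free of k_l and positive for positive arguments;
    ``extra_parameters`` are the auxiliary constants q (Michaelis or Hill
    constants, inhibition constants, power-law exponents).
    """

    kind: RateLawKind
    flux_parameter: sp.Symbol
    factor: sp.Expr
    extra_parameters: tuple[sp.Symbol, ...] = ()

    @property
    def flux(self) -> sp.Expr:
        return self.flux_parameter * self.factor


@dataclass(frozen=True)
class Reaction:
    """One reaction: integer reactant/product stoichiometry plus a rate law.

    ``modifiers`` are species that shape the flux without being consumed or
    produced (e.g. an enzyme mediating a degradation).
    """

    reactants: tuple[tuple[sp.Symbol, int], ...]
    products: tuple[tuple[sp.Symbol, int], ...]
    rate_law: RateLaw
    modifiers: frozenset[sp.Symbol] = frozenset()

    def net_stoichiometry(self) -> dict[sp.Symbol, int]:
        net: dict[sp.Symbol, int] = {}
        for s, c in self.reactants:
            net[s] = net.get(s, 0) - c
        for s, c in self.products:
            net[s] = net.get(s, 0) + c
        return {s: c for s, c in net.items() if c != 0}


@dataclass
class ReactionNetwork:
    """A reaction network with rhs decomposition S·F.

    Invariants: column l of the stoichiometry matrix belongs to exactly one
    flux parameter k_l; the parameter set is the disjoint union of flux
    parameters and extra parameters.
    """

    states: list[sp.Symbol]
    reactions: list[Reaction]
    stoichiometry: np.ndarray = field(repr=False)
    name: str = ""

    def __post_init__(self) -> None:
        self.stoichiometry = np.asarray(self.stoichiometry, dtype=int)
        n, m = self.stoichiometry.shape
        if n != len(self.states) or m != len(self.reactions):
            raise ValueError("stoichiometry shape does not match states/reactions")

    # -- derived views ------------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def flux_parameters(self) -> list[sp.Symbol]:
        return [r.rate_law.flux_parameter for r in self.reactions]

    @property
    def extra_parameters(self) -> set[sp.Symbol]:
        out: set[sp.Symbol] = set()
        for r in self.reactions:
            out.update(r.rate_law.extra_parameters)
        return out

    @property
    def parameters(self) -> list[sp.Symbol]:
        """Flux parameters (in column order) followed by sorted extras."""
        return self.flux_parameters + sorted(self.extra_parameters, key=str)

    @property
    def fluxes(self) -> list[sp.Expr]:
        return [r.rate_law.flux for r in self.reactions]

    def rhs(self) -> list[sp.Expr]:
        return rhs(self)

    def state_index(self, state: sp.Symbol) -> int:
        return self.states.index(state)

    # -- serialization ------------------------------------------------------

    def to_text(self) -> str:
        """Serialize back to the line-based model format (round-trips)."""
        lines = []
        for r in self.reactions:
            lines.append(
                "%s -> %s ; %s ; param=%s"
                % (
                    _side_to_text(r.reactants),
                    _side_to_text(r.products),
                    str(r.rate_law.flux).replace("**", "^"),
                    r.rate_law.flux_parameter,
                )
            )
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "states": [str(s) for s in self.states],
                "flux_parameters": [str(k) for k in self.flux_parameters],
                "extra_parameters": sorted(str(q) for q in self.extra_parameters),
                "stoichiometry": self.stoichiometry.tolist(),
                "fluxes": [str(f) for f in self.fluxes],
                "reactions": self.to_text().splitlines(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ReactionNetwork":
        data = json.loads(text)
        net = parse_network("\n".join(data["reactions"]), name=data.get("name", ""))
        return net


def _side_to_text(side: tuple[tuple[sp.Symbol, int], ...]) -> str:
    if not side:
        return "0"
    parts = []
    for s, c in side:
        parts.append(str(s) if c == 1 else f"{c} {s}")
    return " + ".join(parts)


class ModelSyntaxError(ValueError):
    """Raised when a model file violates the grammar or the flux form."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


_SPECIES_RE = re.compile(r"^(?:(\d+)\s+)?([A-Za-z_]\w*)$")


def _parse_side(text: str, line_no: int) -> list[tuple[str, int]]:
    text = text.strip()
    if text in ("0", "∅", ""):
        return []
    out: list[tuple[str, int]] = []
    for chunk in text.split("+"):
        m = _SPECIES_RE.match(chunk.strip())
        if not m:
            raise ModelSyntaxError(f"cannot parse species term {chunk.strip()!r}", line_no)
        coeff = int(m.group(1)) if m.group(1) else 1
        if coeff <= 0:
            raise ModelSyntaxError("stoichiometric coefficients must be positive", line_no)
        out.append((m.group(2), coeff))
    # merge repeated species ("A + A" == "2 A")
    merged: dict[str, int] = {}
    order: list[str] = []
    for name, c in out:
        if name not in merged:
            order.append(name)
            merged[name] = 0
        merged[name] += c
    return [(name, merged[name]) for name in order]


def _split_flux(flux: sp.Expr, declared: str | None, line_no: int) -> tuple[sp.Symbol, sp.Expr]:
    """Identify k_l and G_l in a flux expression.

    The flux parameter is the explicitly declared symbol, or else the unique
    free symbol whose name starts with "k".
    """
    symbols = flux.free_symbols
    if declared is not None:
        k = positive_symbol(declared)
        if k not in symbols:
            raise ModelSyntaxError(f"declared parameter {declared!r} absent from flux", line_no)
    else:
        candidates = sorted((s for s in symbols if str(s).startswith("k")), key=str)
        if len(candidates) != 1:
            raise ModelSyntaxError(
                "flux needs exactly one k-prefixed parameter "
                f"(found {[str(c) for c in candidates]}); use 'param=NAME' to disambiguate",
                line_no,
            )
        k = candidates[0]
    factor = sp.cancel(flux / k)
    if k in factor.free_symbols:
        raise ModelSyntaxError(
            f"flux {flux} is not of the form {k}*G with {k} absent from G", line_no
        )
    return k, factor


def _classify_rate_law(factor: sp.Expr, states: set[sp.Symbol]) -> RateLawKind:
    """Best-effort kind classification from the structure of G_l."""
    if factor == 1:
        return RateLawKind.PRODUCTION
    num, den = sp.fraction(sp.together(factor))
    if den.free_symbols:
        num_states = num.free_symbols & states
        den_states = den.free_symbols & states
        if den_states & num_states:
            return RateLawKind.MICHAELIS_MENTEN
        if den_states:
            return RateLawKind.INHIBITION
    if den == 1 and num.is_Pow or (num.is_Mul and any(a.is_Pow for a in num.args)):
        exps = [
            a.exp
            for a in (num.args if num.is_Mul else [num])
            if a.is_Pow and a.base in states
        ]
        if any(not (e.is_Integer and e > 0) for e in exps):
            return RateLawKind.POWER_LAW
    if den == 1 and num.as_poly(*states) is not None:
        return RateLawKind.MASS_ACTION
    return RateLawKind.CUSTOM


def parse_network(text: str, name: str = "") -> ReactionNetwork:
    """Parse the line-based model format into a validated ReactionNetwork.

    Grammar (one reaction per line, ``#`` starts a comment)::

        reactants -> products ; flux-expression [; param=NAME]

    where each side is ``0`` (source/sink) or a ``+``-separated sum of
    ``[int] Species``.  State order follows first appearance on a
    reactant/product side; reaction (column) order follows line order.
    """
    raw_reactions: list[tuple[int, list, list, sp.Expr, str | None]] = []
    state_order: list[str] = []
    seen: set[str] = set()

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "->" not in line:
            raise ModelSyntaxError("missing '->'", line_no)
        lhs, rest = line.split("->", 1)
        parts = [p.strip() for p in rest.split(";")]
        if len(parts) < 2 or not parts[1]:
            raise ModelSyntaxError("missing ';' flux expression", line_no)
        products_text = parts[0]
        flux_text = parts[1]
        declared = None
        for extra in parts[2:]:
            if extra.startswith("param="):
                declared = extra[len("param="):].strip()
            elif extra:
                raise ModelSyntaxError(f"unrecognised annotation {extra!r}", line_no)
        reactants = _parse_side(lhs, line_no)
        products = _parse_side(products_text, line_no)
        try:
            flux = parse_expression(flux_text)
        except (sp.SympifyError, SyntaxError) as exc:
            raise ModelSyntaxError(f"cannot parse flux {flux_text!r}: {exc}", line_no) from None
        for species, _ in reactants + products:
            if species not in seen:
                seen.add(species)
                state_order.append(species)
        raw_reactions.append((line_no, reactants, products, flux, declared))

    states = [positive_symbol(s) for s in state_order]
    state_set = set(states)
    reactions: list[Reaction] = []
    n = len(states)
    m = len(raw_reactions)
    S = np.zeros((n, m), dtype=int)
    for col, (line_no, reactants, products, flux, declared) in enumerate(raw_reactions):
        k, factor = _split_flux(flux, declared, line_no)
        extra = tuple(
            sorted((s for s in factor.free_symbols if s not in state_set), key=str)
        )
        involved = {positive_symbol(s) for s, _ in reactants + products}
        modifiers = frozenset(factor.free_symbols & state_set - involved)
        kind = _classify_rate_law(factor, state_set)
        law = RateLaw(kind=kind, flux_parameter=k, factor=factor, extra_parameters=extra)
        reaction = Reaction(
            reactants=tuple((positive_symbol(s), c) for s, c in reactants),
            products=tuple((positive_symbol(s), c) for s, c in products),
            rate_law=law,
            modifiers=modifiers,
        )
        for s, c in reaction.net_stoichiometry().items():
            S[states.index(s), col] = c
        reactions.append(reaction)

    net = ReactionNetwork(states=states, reactions=reactions, stoichiometry=S, name=name)
    problems = validate_network(net)
    fatal = [p for p in problems if p.startswith("flux") or "outflux" in p]
    if fatal:
        raise ModelSyntaxError("; ".join(fatal))
    return net


def rhs(network: ReactionNetwork) -> list[sp.Expr]:
    """The ODE right-hand side S·F as a list of N expressions."""
    fluxes = network.fluxes
    return [
        sp.expand(sum(int(network.stoichiometry[i, l]) * fluxes[l] for l in range(network.n_reactions)))
        for i in range(network.n_states)
    ]


def _vanishes_at_zero(factor: sp.Expr, state: sp.Symbol) -> bool:
    """True iff the flux factor tends to 0 as ``state`` → 0⁺."""
    try:
        value = factor.subs(state, 0)
        if value.is_zero:
            return True
        if value.is_finite and not value.is_zero:
            return False
    except Exception:  # pragma: no cover - pathological substitution
        pass
    limit = sp.limit(factor, state, 0, "+")
    return bool(limit.is_zero)


def validate_network(network: ReactionNetwork) -> list[str]:
    """Check modelling assumptions; returns diagnostics (empty list = valid).

    Checked per reaction: the flux factors as k_l·G_l with k_l absent from
    G_l; every consumed state appears in the factor (outfluxes vanish with
    their state — at least linear dependence); G_l is positive for positive
    arguments (structurally, falling back to numeric sampling for custom
    kinds).
    """
    diagnostics: list[str] = []
    for idx, r in enumerate(network.reactions):
        law = r.rate_law
        tag = f"reaction {idx} ({law.flux})"
        if law.flux_parameter in law.factor.free_symbols:
            diagnostics.append(f"flux not factorable as k*G in {tag}")
            continue
        for s, c in r.net_stoichiometry().items():
            if c < 0 and not _vanishes_at_zero(law.factor, s):
                diagnostics.append(
                    f"outflux of {s} does not depend on {s} in {tag}"
                )
        if not _factor_positive(law.factor):
            diagnostics.append(f"flux factor not provably positive in {tag}")
    return diagnostics


def _factor_positive(factor: sp.Expr, n_samples: int = 16) -> bool:
    if factor.is_positive:  # all symbols carry positive=True
        return True
    rng = np.random.default_rng(0)
    syms = sorted(factor.free_symbols, key=str)
    f = sp.lambdify(syms, factor, "numpy")
    for _ in range(n_samples):
        vals = rng.uniform(0.1, 10.0, size=len(syms))
        try:
            if not np.asarray(f(*vals)).item() > 0:
                return False
        except Exception:
            return False
    return True


# ---------------------------------------------------------------------------
# random fixture generator
# ---------------------------------------------------------------------------

_OUTFLUX_KINDS = (
    RateLawKind.MASS_ACTION,
    RateLawKind.INHIBITION,
    RateLawKind.MICHAELIS_MENTEN,
    RateLawKind.POWER_LAW,
)


def generate_random_network(
    n_states: int,
    n_reactions: int,
    kinds: set[RateLawKind] | None = None,
    seed: int = 0,
) -> ReactionNetwork:
    """Draw a random valid network from the standard rate-law templates.

    The network is built around a flow backbone — a production reaction
    feeding a conversion chain that visits every state and ends in a
    degradation — so that each state has at least one influx and one outflux
    and a strictly positive steady state is plausible; remaining reaction
    slots are filled with random influx/outflux templates.  Requires
    ``n_reactions >= n_states + 1``.  Identical seeds give identical
    networks.
    """
    if n_states < 1 or n_reactions < 1:
        raise ValueError("need at least one state and one reaction")
    if n_reactions < n_states + 1:
        raise ValueError(
            "infeasible configuration: the flow backbone needs "
            f"n_reactions >= n_states + 1 (got {n_reactions} < {n_states + 1})"
        )
    kinds = set(kinds) if kinds else {RateLawKind.MASS_ACTION, RateLawKind.PRODUCTION}
    out_kinds = [k for k in _OUTFLUX_KINDS if k in kinds]
    if not out_kinds:
        raise ValueError("kinds must include at least one outflux-capable kind")

    rng = np.random.default_rng(seed)
    names = [f"X{i}" for i in range(n_states)]
    lines: list[str] = []
    qi = 0

    def other(i: int) -> int:
        if n_states == 1:
            return i
        j = int(rng.integers(0, n_states - 1))
        return j if j < i else j + 1

    def conversion_line(i: int, dst: str, col: int) -> str:
        nonlocal qi
        kind = out_kinds[int(rng.integers(0, len(out_kinds)))]
        src = names[i]
        k = f"k{col}"
        if kind is RateLawKind.MASS_ACTION:
            return f"{src} -> {dst} ; {k}*{src}"
        if kind is RateLawKind.INHIBITION:
            q = f"q{qi}"
            qi += 1
            return f"{src} -> {dst} ; {k}*{src}/({q} + {names[other(i)]})"
        if kind is RateLawKind.MICHAELIS_MENTEN:
            q = f"q{qi}"
            qi += 1
            return f"{src} -> {dst} ; {k}*{src}/({q} + {src})"
        # power law with integer exponent 2 on the consumed state
        return f"{src} -> {dst} ; {k}*{src}^2"

    def outflux_line(i: int, col: int) -> str:
        dst = "0" if rng.random() < 0.5 else names[other(i)]
        if dst == names[i]:
            dst = "0"
        return conversion_line(i, dst, col)

    def influx_line(i: int, col: int) -> str:
        nonlocal qi
        influx_kinds = [
            k
            for k in kinds
            if k
            in (
                RateLawKind.PRODUCTION,
                RateLawKind.MASS_ACTION,
                RateLawKind.HILL,
                RateLawKind.INHIBITION,
            )
        ] or [RateLawKind.PRODUCTION]
        kind = influx_kinds[int(rng.integers(0, len(influx_kinds)))]
        dst = names[i]
        k = f"k{col}"
        if kind is RateLawKind.PRODUCTION:
            return f"0 -> {dst} ; {k}"
        if kind is RateLawKind.MASS_ACTION:
            src = names[other(i)]
            return f"{src} -> {dst} ; {k}*{src}"
        if kind is RateLawKind.HILL:
            q1, q2 = f"q{qi}", f"q{qi + 1}"
            qi += 2
            mod = names[other(i)]
            return f"0 -> {dst} ; {k}*{mod}^2/({q1}^2 + {mod}^2)"
        q = f"q{qi}"
        qi += 1
        return f"0 -> {dst} ; {k}/({q} + {names[other(i)]})"

    def source_line(i: int, col: int) -> str:
        nonlocal qi
        dst = names[i]
        k = f"k{col}"
        source_kinds = [
            kd
            for kd in (RateLawKind.PRODUCTION, RateLawKind.HILL, RateLawKind.INHIBITION)
            if kd in kinds
        ] or [RateLawKind.PRODUCTION]
        kind = source_kinds[int(rng.integers(0, len(source_kinds)))]
        if kind is RateLawKind.HILL:
            q1, q2 = f"q{qi}", f"q{qi + 1}"
            qi += 2
            mod = names[other(i)]
            return f"0 -> {dst} ; {k}*{mod}^2/({q1}^2 + {mod}^2)"
        if kind is RateLawKind.INHIBITION:
            q = f"q{qi}"
            qi += 1
            return f"0 -> {dst} ; {k}/({q} + {names[other(i)]})"
        return f"0 -> {dst} ; {k}"

    # flow backbone: a true source -> conversion chain over all states -> sink
    order = [int(i) for i in rng.permutation(n_states)]
    col = 0
    lines.append(source_line(order[0], col))
    col += 1
    for pos, i in enumerate(order):
        dst = "0" if pos == n_states - 1 else names[order[pos + 1]]
        lines.append(conversion_line(i, dst, col))
        col += 1
    while col < n_reactions:
        i = int(rng.integers(0, n_states))
        if rng.random() < 0.5:
            lines.append(influx_line(i, col))
        else:
            lines.append(outflux_line(i, col))
        col += 1

    net = parse_network("\n".join(lines), name=f"random-{seed}")
    assert net.n_states == n_states
    return net
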