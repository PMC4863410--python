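"""Conserved-quantity detection.

A conserved quantity (CQ) is an expression Σ_j a_j(x, p)·x_j that stays
constant along every trajectory of ẋ = S·F.  Coefficient-constant CQs come
from the left null space of the stoichiometry matrix; their count is
N − rank(S).  Some networks conserve additional combinations whose
coefficients depend on parameters (or states).  Those are found by rewriting
the system as ẋ = C(p, x)·x and hunting for linear dependencies among the
rows of C: dependencies are detected numerically (random substitution + QR)
and then resolved symbolically, and every candidate must pass symbolic
verification before it is reported.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .model import ReactionNetwork, parse_expression, positive_symbol

__all__ = [
    "CQSource",
    "ConservedQuantity",
    "stoichiometric_cqs",
    "state_dependent_cqs",
    "manual_cq",
    "verify_cq",
    "find_conserved_quantities",
]


class CQSource(enum.Enum):
    STOICHIOMETRIC = "stoichiometric"
    STATE_DEPENDENT = "state_dependent"
    MANUAL = "manual"


@dataclass
class ConservedQuantity:
    """Σ_j coefficients[x_j]·x_j = total_symbol along every trajectory."""

    coefficients: dict[sp.Symbol, sp.Expr]
    total_symbol: sp.Symbol
    source: CQSource
    used: bool = False

    @property
    def expression(self) -> sp.Expr:
        return sp.Add(*(a * x for x, a in self.coefficients.items()))

    def involves(self, state: sp.Symbol) -> bool:
        coeff = self.coefficients.get(state)
        return coeff is not None and coeff != 0

    def __str__(self) -> str:
        return f"{self.expression} = {self.total_symbol}"


def _integer_scale(vector: list[sp.Rational]) -> list[sp.Integer]:
    """Scale a rational vector to coprime integers, first nonzero positive."""
    denominators = [sp.Rational(v).q for v in vector]
    scaled = [sp.Integer(v * sp.ilcm(*denominators)) for v in vector]
    g = sp.igcd(*[abs(int(v)) for v in scaled if v != 0])
    scaled = [v // g for v in scaled]
    first = next(v for v in scaled if v != 0)
    if first < 0:
        scaled = [-v for v in scaled]
    return scaled


def _fresh_total(index: int) -> sp.Symbol:
    return positive_symbol(f"total{index}")


def stoichiometric_cqs(network: ReactionNetwork) -> list[ConservedQuantity]:
    """CQs with constant coefficients: an integer basis of the left null
    space of S.  Returns N − rank(S) quantities."""
    S = sp.Matrix(network.stoichiometry)
    basis = S.T.nullspace()
    cqs = []
    for i, vec in enumerate(basis):
        coeffs = _integer_scale(list(vec))
        cqs.append(
            ConservedQuantity(
                coefficients={
                    s: c for s, c in zip(network.states, coeffs) if c != 0
                },
                total_symbol=_fresh_total(i + 1),
                source=CQSource.STOICHIOMETRIC,
            )
        )
    return cqs


def verify_cq(cq: ConservedQuantity, network: ReactionNetwork) -> bool:
    """True iff d/dt Σ a_j(x, p)·x_j vanishes identically along the ODE."""
    f = network.rhs()
    quantity = cq.expression
    derivative = sum(
        sp.diff(quantity, x) * fx for x, fx in zip(network.states, f)
    )
    return sp.simplify(sp.cancel(sp.together(derivative))) == 0


def manual_cq(expression: str | sp.Expr, network: ReactionNetwork,
              total_index: int = 0) -> ConservedQuantity:
    """Build and verify a user-declared CQ such as ``"F + G"``.

    The expression must be linear in the states; coefficients may involve
    parameters.  Raises ``ValueError`` if the quantity is not conserved.
    """
    expr = parse_expression(expression) if isinstance(expression, str) else expression
    coeffs = {}
    for x in network.states:
        a = sp.diff(expr, x)
        if a != 0:
            if x in a.free_symbols:
                raise ValueError(f"manual CQ is not linear in state {x}")
            coeffs[x] = a
    rebuilt = sp.Add(*(a * x for x, a in coeffs.items()))
    if sp.simplify(rebuilt - expr) != 0:
        raise ValueError("manual CQ must be a linear combination of states")
    cq = ConservedQuantity(
        coefficients=coeffs,
        total_symbol=positive_symbol(f"total_manual{total_index}"),
        source=CQSource.MANUAL,
    )
    if not verify_cq(cq, network):
        raise ValueError(f"declared quantity {expr} is not conserved")
    return cq


# ---------------------------------------------------------------------------
# state/parameter-dependent construction
# ---------------------------------------------------------------------------


def _coefficient_matrix(network: ReactionNetwork) -> tuple[sp.Matrix, list[sp.Symbol], bool]:
    """Rewrite ẋ = C(p, x)·x (with a constant pseudo-state when needed).

    Each flux term S_il·F_l is attributed to the column of the first state
    (network order) on which the flux factor at least linearly depends; a
    term involving no state (constant production) goes to the column of an
    appended pseudo-state that is identically one.
    """
    states = network.states
    n = len(states)
    fluxes = network.fluxes
    has_pseudo = False
    C = sp.zeros(n + 1, n + 1)
    for l, flux in enumerate(fluxes):
        column = None
        for j, x in enumerate(states):
            if x in flux.free_symbols:
                ratio = sp.cancel(flux / x)
                num, den = sp.fraction(ratio)
                if x not in den.free_symbols or ratio.subs(x, 0).is_finite:
                    column = j
                    break
        if column is None:
            column = n  # constant production term -> pseudo-state column
            has_pseudo = True
            ratio = flux
        for i in range(n):
            s = int(network.stoichiometry[i, l])
            if s:
                C[i, column] += s * ratio
    if not has_pseudo:
        C = C[:n, :n]
    return C, states, has_pseudo


def state_dependent_cqs(
    network: ReactionNetwork,
    seed: int = 0,
    n_draws: int = 3,
    tol: float = 1e-8,
) -> list[ConservedQuantity]:
    """Find CQs Σ a_j(x, p)·x_j by the numeric-QR / symbolic-solve scheme.

    Random values in [0.5, 2] replace all symbols of Cᵀ; a linear dependence
    is accepted only when every one of ``n_draws`` independent draws shows a
    (near-)zero QR diagonal at the same position, and only when the triangular
    symbolic solve yields a quantity that passes :func:`verify_cq`.  After a
    dependence is processed the dependent row is removed and the search
    restarts.
    """
    C, states, _ = _coefficient_matrix(network)
    rng = np.random.default_rng(seed)
    symbols = sorted(C.free_symbols, key=str)

    active = list(range(len(states)))  # pseudo-state row (all zero) excluded
    found: list[ConservedQuantity] = []
    counter = 0
    while len(active) > 1:
        # columns of C^T corresponding to still-active states
        M_sym = sp.Matrix.hstack(*[C[i, :].T for i in active])
        fn = sp.lambdify(symbols, M_sym, "numpy")
        dependent_at: int | None = None
        for _ in range(max(1, n_draws)):
            values = rng.uniform(0.5, 2.0, size=len(symbols))
            numeric = np.asarray(fn(*values), dtype=float)
            _, R = np.linalg.qr(numeric)
            diag = np.abs(np.diag(R))
            scale = max(diag.max(), 1.0)
            small = np.nonzero(diag < tol * scale)[0]
            pos = int(small[0]) if small.size else None
            if dependent_at is None:
                dependent_at = pos
            elif dependent_at != pos:
                dependent_at = None  # draws disagree: treat as independent
                break
        if dependent_at is None:
            break
        ell = dependent_at
        sub = M_sym[:, : ell + 1]
        null = sub.nullspace()
        candidate = None
        for vec in null:
            if vec[ell] != 0:
                candidate = [sp.cancel(v / vec[ell]) for v in vec]
                break
        if candidate is not None:
            counter += 1
            coeffs = {
                states[active[j]]: sp.cancel(candidate[j])
                for j in range(ell + 1)
                if candidate[j] != 0
            }
            cq = ConservedQuantity(
                coefficients=coeffs,
                total_symbol=positive_symbol(f"ctotal{counter}"),
                source=CQSource.STATE_DEPENDENT,
            )
            if verify_cq(cq, network):
                found.append(cq)
        # drop the dependent row whether or not the candidate verified,
        # otherwise the same dependence is re-detected forever
        del active[ell]
    return found


def _independent_of(cq: ConservedQuantity, others: list[ConservedQuantity],
                    states: list[sp.Symbol]) -> bool:
    if not others:
        return True
    rows = [[o.coefficients.get(x, sp.Integer(0)) for x in states] for o in others]
    with_candidate = rows + [[cq.coefficients.get(x, sp.Integer(0)) for x in states]]
    return sp.Matrix(with_candidate).rank() > sp.Matrix(rows).rank()


def find_conserved_quantities(
    network: ReactionNetwork,
    manual: list[str] | None = None,
    detect_state_dependent: bool = True,
    seed: int = 0,
) -> list[ConservedQuantity]:
    """All CQs: stoichiometric basis, plus independent state-dependent and
    manual ones (each verified)."""
    cqs = stoichiometric_cqs(network)
    if detect_state_dependent:
        for cq in state_dependent_cqs(network, seed=seed):
            if _independent_of(cq, cqs, network.states):
                cqs.append(cq)
    for i, text in enumerate(manual or []):
        cq = manual_cq(text, network, total_index=i + 1)
        if _independent_of(cq, cqs, network.states):
            cqs.append(cq)
    return cqs


def cq_report(cqs: list[ConservedQuantity], network: ReactionNetwork) -> str:
    """JSON report of conserved quantities with verification status."""
    return json.dumps(
        [
            {
                "expression": str(cq.expression),
                "total": str(cq.total_symbol),
                "coefficients": {str(x): str(a) for x, a in cq.coefficients.items()},
                "source": cq.source.value,
                "verified": verify_cq(cq, network),
            }
            for cq in cqs
        ],
        indent=2,
    )
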