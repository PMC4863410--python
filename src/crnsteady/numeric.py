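"""Numeric steady states: damped Newton, implicit-function-theorem
sensitivities, linear stability, and numeric validation of symbolic
solutions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.integrate
import sympy as sp

from .model import ReactionNetwork
from .solver import SteadyStateSolution

__all__ = [
    "CompiledNetwork",
    "NewtonResult",
    "newton_steady_state",
    "steady_state_sensitivities",
    "stability",
    "positive_steady_states",
    "VerificationReport",
    "verify_solution",
]


class CompiledNetwork:
    """Lambdified f(x, p), ∂f/∂x and ∂f/∂p for fast numeric evaluation.

    The parameter vector follows ``network.parameters`` (flux parameters in
    stoichiometry-column order, then extra parameters sorted by name).
    """

    def __init__(self, network: ReactionNetwork):
        self.network = network
        self.states = list(network.states)
        self.parameters = list(network.parameters)
        f = sp.Matrix(network.rhs())
        jx = f.jacobian(self.states)
        jp = f.jacobian(self.parameters)
        args = (self.states, self.parameters)
        self._f = sp.lambdify(args, f, "numpy")
        self._jx = sp.lambdify(args, jx, "numpy")
        self._jp = sp.lambdify(args, jp, "numpy")

    def parameter_vector(self, params: dict | np.ndarray) -> np.ndarray:
        if isinstance(params, dict):
            lookup = {str(k): v for k, v in params.items()}
            return np.array([float(lookup[str(p)]) for p in self.parameters])
        return np.asarray(params, dtype=float)

    def f(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        return np.asarray(self._f(x, p), dtype=float).ravel()

    def jac_x(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        return np.asarray(self._jx(x, p), dtype=float)

    def jac_p(self, x: np.ndarray, p: np.ndarray) -> np.ndarray:
        return np.asarray(self._jp(x, p), dtype=float)


@dataclass
class NewtonResult:
    x0: np.ndarray
    converged: bool
    residual_norm: float
    iterations: int
    sensitivities: np.ndarray | None = None
    message: str = ""


def _as_compiled(network: ReactionNetwork | CompiledNetwork) -> CompiledNetwork:
    if isinstance(network, CompiledNetwork):
        return network
    return CompiledNetwork(network)


def newton_steady_state(
    network: ReactionNetwork | CompiledNetwork,
    params: dict | np.ndarray,
    x_init: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
    compute_sensitivities: bool = False,
) -> NewtonResult:
    """Damped Newton iteration on f(x, p) = 0.

    Steps are halved (up to 20 times) whenever the residual norm fails to
    decrease.  No positivity projection is applied: like any root finder the
    iteration may land on negative or unstable roots.  A singular Jacobian is
    reported, not masked.
    """
    compiled = _as_compiled(network)
    p = compiled.parameter_vector(params)
    x = (
        np.ones(len(compiled.states))
        if x_init is None
        else np.asarray(x_init, dtype=float).copy()
    )
    fx = compiled.f(x, p)
    norm = float(np.linalg.norm(fx, np.inf))
    message = ""
    iterations = 0
    for iterations in range(1, max_iter + 1):
        if norm <= tol:
            iterations -= 1
            break
        jac = compiled.jac_x(x, p)
        try:
            step = np.linalg.solve(jac, -fx)
        except np.linalg.LinAlgError:
            message = "singular Jacobian at iterate"
            break
        lam = 1.0
        for _ in range(21):
            x_new = x + lam * step
            f_new = compiled.f(x_new, p)
            norm_new = float(np.linalg.norm(f_new, np.inf))
            if np.isfinite(norm_new) and norm_new < norm:
                break
            lam *= 0.5
        else:
            message = "damping failed to reduce the residual"
            break
        x, fx, norm = x_new, f_new, norm_new
    converged = bool(norm <= tol and np.all(np.isfinite(x)))
    result = NewtonResult(
        x0=x,
        converged=converged,
        residual_norm=norm,
        iterations=iterations,
        message=message,
    )
    if compute_sensitivities and converged:
        result.sensitivities = steady_state_sensitivities(compiled, p, x)
    return result


def steady_state_sensitivities(
    network: ReactionNetwork | CompiledNetwork,
    params: dict | np.ndarray,
    x0: np.ndarray,
) -> np.ndarray:
    """∂x0/∂p = −(∂f/∂x0)⁻¹·∂f/∂p at a steady state (implicit function
    theorem).  Raises ``numpy.linalg.LinAlgError`` on a singular state
    Jacobian."""
    compiled = _as_compiled(network)
    p = compiled.parameter_vector(params)
    x0 = np.asarray(x0, dtype=float)
    return -np.linalg.solve(compiled.jac_x(x0, p), compiled.jac_p(x0, p))


def stability(
    network: ReactionNetwork | CompiledNetwork,
    params: dict | np.ndarray,
    x0: np.ndarray,
    tol: float = 1e-8,
) -> str:
    """'stable' / 'unstable' / 'marginal' by the maximal real part of the
    state-Jacobian eigenvalues at x0."""
    compiled = _as_compiled(network)
    p = compiled.parameter_vector(params)
    eigenvalues = np.linalg.eigvals(compiled.jac_x(np.asarray(x0, float), p))
    top = float(np.max(eigenvalues.real))
    if abs(top) < tol:
        return "marginal"
    return "stable" if top < 0 else "unstable"


def positive_steady_states(
    network: ReactionNetwork | CompiledNetwork,
    params: dict | np.ndarray,
    n_guesses: int = 50,
    seed: int = 0,
    tol: float = 1e-10,
) -> list[tuple[np.ndarray, str]]:
    """Strictly positive roots of f(x, p) = 0 found by Newton multistart,
    deduplicated, each with its stability label; sorted by first coordinate."""
    compiled = _as_compiled(network)
    p = compiled.parameter_vector(params)
    rng = np.random.default_rng(seed)
    n = len(compiled.states)
    roots: list[np.ndarray] = []
    guesses = [np.ones(n)] + [
        10.0 ** rng.uniform(-1.5, 1.5, size=n) for _ in range(n_guesses - 1)
    ]
    for guess in guesses:
        res = newton_steady_state(compiled, p, x_init=guess, tol=tol)
        if not res.converged or np.any(res.x0 <= 0):
            continue
        if not any(
            np.allclose(res.x0, r, rtol=1e-6, atol=1e-9) for r in roots
        ):
            roots.append(res.x0)
    roots.sort(key=lambda r: r[0])
    return [(r, stability(compiled, p, r)) for r in roots]


def integrate(
    network: ReactionNetwork | CompiledNetwork,
    params: dict | np.ndarray,
    x0: np.ndarray,
    t_eval: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Integrate the ODE with a stiff-capable adaptive method (LSODA)."""
    compiled = _as_compiled(network)
    p = compiled.parameter_vector(params)
    t_eval = np.asarray(t_eval, dtype=float)
    sol = scipy.integrate.solve_ivp(
        lambda t, x: compiled.f(x, p),
        (t_eval[0], t_eval[-1]),
        np.asarray(x0, float),
        t_eval=t_eval,
        method="LSODA",
        jac=lambda t, x: compiled.jac_x(x, p),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol.y.T  # shape (time, state)


@dataclass
class VerificationReport:
    n_samples: int
    max_residual: float
    min_fixed_value: float
    max_flatness_drift: float
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def verify_solution(
    solution: SteadyStateSolution,
    network: ReactionNetwork | None = None,
    n_samples: int = 200,
    seed: int = 1,
    sample_range: tuple[float, float] = (0.1, 10.0),
    residual_tol: float = 1e-9,
    n_integrate: int = 3,
) -> VerificationReport:
    """Numerically validate a steady-state parameterization.

    For ``n_samples`` log-uniform positive draws of the free symbols the
    fixed targets are evaluated; the report records the largest rhs residual
    ‖S·F‖∞ at the implied point, the smallest fixed value (negative means a
    positivity violation), and — for the first ``n_integrate`` draws — the
    relative drift of the trajectory integrated from the implied initial
    state (flatness check).
    """
    network = network or solution.network
    compiled = CompiledNetwork(network)
    if solution.independent_form is None:
        from .solver import back_substitute

        solution = back_substitute(solution)
    form = solution.independent_form
    free = sorted(solution.free_symbols(), key=str)
    targets = [a.target for a in form]
    exprs = [a.expression for a in form]
    evaluate = sp.lambdify([free], sp.Matrix(exprs), "numpy") if form else None

    rng = np.random.default_rng(seed)
    lo, hi = np.log10(sample_range[0]), np.log10(sample_range[1])
    max_residual = 0.0
    min_fixed = np.inf
    max_drift = 0.0
    violations: list[str] = []

    for i in range(n_samples):
        sample = 10.0 ** rng.uniform(lo, hi, size=len(free))
        values = dict(zip(free, sample))
        if evaluate is not None:
            fixed = np.asarray(evaluate(sample), dtype=float).ravel()
            values.update(zip(targets, fixed))
            if fixed.size:
                smallest = float(fixed.min())
                min_fixed = min(min_fixed, smallest)
                if smallest < 0:
                    worst = targets[int(np.argmin(fixed))]
                    violations.append(
                        f"sample {i}: negative value {smallest:.3g} for {worst}"
                    )
        try:
            x = np.array([float(values[s]) for s in compiled.states])
            p = np.array([float(values[s]) for s in compiled.parameters])
        except KeyError as missing:
            violations.append(f"sample {i}: no value for symbol {missing}")
            continue
        residual = float(np.linalg.norm(compiled.f(x, p), np.inf))
        max_residual = max(max_residual, residual)
        if residual > residual_tol:
            violations.append(f"sample {i}: rhs residual {residual:.3g}")
        if i < n_integrate and np.all(x > 0):
            t_eval = np.linspace(0.0, 50.0, 11)
            try:
                traj = integrate(compiled, p, x, t_eval)
            except RuntimeError as exc:
                violations.append(f"sample {i}: {exc}")
                continue
            scale = np.maximum(np.abs(x), 1e-12)
            drift = float(np.max(np.abs(traj - x) / scale))
            max_drift = max(max_drift, drift)
            if drift > 1e-6:
                violations.append(f"sample {i}: trajectory drift {drift:.3g}")

    return VerificationReport(
        n_samples=n_samples,
        max_residual=max_residual,
        min_fixed_value=float(min_fixed) if np.isfinite(min_fixed) else 0.0,
        max_flatness_drift=max_drift,
        violations=violations,
    )
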