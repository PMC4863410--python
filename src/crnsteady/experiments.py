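"""Multi-start parameter-estimation benchmarks for competing steady-state
parameterizations.

The protocol: simulate a network at its stable steady state, displace one
state at a stimulus time, observe noisy time courses under several
displacement conditions, then run many trust-region least-squares fits from
log-uniform random starting parameters.  Each *parameterization* (variant)
maps the fitted parameter vector θ to the full kinetic parameter vector and
a steady-state initial value — analytically solved for states ("standard"
and its reparameterized variants), numerically via Newton ("numeric"), or
with the cycle-splitting solver's non-negative expressions ("proposed").
Fit gradients use forward sensitivity equations, seeded with ∂x0/∂θ of the
variant (implicit-function-theorem gradients for the numeric variant).

Success statistics mirror waterfall-plot practice: a fit is *global* when
its final negative log-likelihood is within a tolerance of the best value
observed on the dataset, *aborted* when the optimizer or the integrator
failed, and *local* otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.integrate
import scipy.optimize
import sympy as sp

from .examples import four_state_chain_network, three_state_feedback_network
from .model import ReactionNetwork, positive_symbol
from .numeric import CompiledNetwork, newton_steady_state, positive_steady_states, \
    steady_state_sensitivities
from .solver import SteadyStateSolution, solve_steady_state

__all__ = [
    "AbortFit",
    "ExperimentDesign",
    "Dataset",
    "FitResult",
    "ExperimentSummary",
    "Parameterization",
    "SymbolicParameterization",
    "ClosedFormStateParameterization",
    "NumericParameterization",
    "parameterization_from_solution",
    "signs_variants",
    "multiplicity_variants",
    "simulate_data",
    "multistart_fit",
    "success_rate",
    "run_case",
    "SIGNS_TRUE_PARAMS",
    "MULTIPLICITY_TRUE_PARAMS",
]


class AbortFit(RuntimeError):
    """Evaluation failed (infeasible steady state, integration failure,
    non-finite objective); the corresponding fit is recorded as aborted."""


class InfeasibleSteadyState(AbortFit):
    """The variant's steady-state parameterization is undefined at the
    requested parameters (negative discriminant, no stable branch, Newton
    failure).  A fit whose path reaches such a point aborts — this is the
    border behaviour sign-indefinite parameterizations exhibit — whereas a
    plain integration failure on a *trial* step is merely rejected."""


# True parameters for data simulation: order-one rate constants.  The
# four-state chain needs k0 > k1 for a positive steady state; the
# three-state feedback loop needs k1²k4k6 > 4k0k2k3k5 (positive
# discriminant) for steady states to exist — here 16 > 4.
SIGNS_TRUE_PARAMS = {"k0": 2.0, "k1": 1.0, "k2": 1.0, "k3": 1.0, "k4": 1.0, "k7": 1.0}
MULTIPLICITY_TRUE_PARAMS = {
    "k0": 1.0, "k1": 2.0, "k2": 1.0, "k3": 1.0, "k4": 2.0, "k5": 1.0, "k6": 2.0,
}


@dataclass(frozen=True)
class ExperimentDesign:
    """Protocol constants of one benchmark case."""

    displacements: tuple[float, ...] = (1.0, 2.0, 4.0)
    stimulus_time: float = 30.0
    t_max: float = 60.0
    n_timepoints: int = 16
    displaced_state: int = 0  # index of the displaced state (state "A")
    noise_sd_fraction: float = 0.05
    noise_floor: float = 0.01
    n_starts: int = 200
    sample_range: tuple[float, float] = (1e-2, 1e2)
    objective_tolerance: float = 0.5
    max_nfev: int = 120
    rtol: float = 1e-6
    atol: float = 1e-8

    @classmethod
    def signs(cls, **overrides) -> "ExperimentDesign":
        return replace(cls(n_timepoints=16), **overrides)

    @classmethod
    def multiplicity(cls, **overrides) -> "ExperimentDesign":
        return replace(cls(n_timepoints=8), **overrides)

    @property
    def times(self) -> np.ndarray:
        """Observation grid: two pre-stimulus baseline points, the rest
        resolving the post-stimulus response."""
        pre = np.array([0.0, 0.5 * self.stimulus_time])
        post = np.linspace(
            self.stimulus_time + 2.0, self.t_max, self.n_timepoints - 2
        )
        return np.concatenate([pre, post])


@dataclass
class Dataset:
    """Simulated observations plus the ground truth behind them."""

    frame: pd.DataFrame  # columns: condition, time, state, value, sd
    network: ReactionNetwork
    true_params: dict[str, float]
    x0: np.ndarray
    design: ExperimentDesign

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(values, sds) shaped (condition, time, state), plus times."""
        states = [str(s) for s in self.network.states]
        conditions = sorted(self.frame["condition"].unique())
        times = np.sort(self.frame["time"].unique())
        values = np.empty((len(conditions), len(times), len(states)))
        sds = np.empty_like(values)
        for ci, cond in enumerate(conditions):
            sub = self.frame[self.frame["condition"] == cond]
            piv = sub.pivot(index="time", columns="state", values="value")
            pivs = sub.pivot(index="time", columns="state", values="sd")
            values[ci] = piv.loc[times, states].to_numpy()
            sds[ci] = pivs.loc[times, states].to_numpy()
        return values, sds, times


@dataclass
class FitResult:
    start_id: int
    initial_parameters: dict[str, float]
    final_parameters: dict[str, float] | None
    objective: float
    status: str  # "global" | "local" | "aborted" (set by success_rate)
    n_steps: int = 0
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# parameterizations
# ---------------------------------------------------------------------------


class Parameterization:
    """Maps fitted parameters θ to (p, x0, ∂p/∂θ, ∂x0/∂θ)."""

    name: str
    theta_names: list[str]

    def fresh(self) -> "Parameterization":
        """Per-fit instance (stateful variants override)."""
        return self

    def evaluate(self, theta: np.ndarray):
        raise NotImplementedError


class SymbolicParameterization(Parameterization):
    """Closed-form variant: kinetic parameters and initial values are
    explicit expressions of the fitted parameters."""

    def __init__(
        self,
        network: ReactionNetwork,
        name: str,
        fitted: list[sp.Symbol],
        parameter_expressions: dict[sp.Symbol, sp.Expr] | None = None,
        state_expressions: dict[sp.Symbol, sp.Expr] | None = None,
    ):
        self.name = name
        self.network = network
        self.fitted = list(fitted)
        self.theta_names = [str(s) for s in self.fitted]
        parameter_expressions = parameter_expressions or {}
        state_expressions = state_expressions or {}
        fitted_set = set(self.fitted)

        def resolve(symbol: sp.Symbol, table: dict) -> sp.Expr:
            if symbol in table:
                return table[symbol]
            if symbol in fitted_set:
                return symbol
            raise ValueError(
                f"{name}: no expression or fitted slot for {symbol}"
            )

        p_exprs = sp.Matrix(
            [resolve(p, parameter_expressions) for p in network.parameters]
        )
        x_exprs = sp.Matrix(
            [resolve(x, state_expressions) for x in network.states]
        )
        self._p = sp.lambdify([self.fitted], p_exprs, "numpy")
        self._x0 = sp.lambdify([self.fitted], x_exprs, "numpy")
        self._dp = sp.lambdify([self.fitted], p_exprs.jacobian(self.fitted), "numpy")
        self._dx0 = sp.lambdify([self.fitted], x_exprs.jacobian(self.fitted), "numpy")

    def evaluate(self, theta: np.ndarray):
        with np.errstate(all="ignore"):
            p = np.asarray(self._p(theta), float).ravel()
            x0 = np.asarray(self._x0(theta), float).ravel()
            dp = np.asarray(self._dp(theta), float)
            dx0 = np.asarray(self._dx0(theta), float)
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(x0))):
            raise InfeasibleSteadyState(
                f"{self.name}: non-finite steady-state expressions"
            )
        return p, x0, dp, dx0


class ClosedFormStateParameterization(Parameterization):
    """Steady state solved analytically for the states ("standard").

    ``sympy.solve`` yields every solution branch; at evaluation time all
    real branches are computed and a stable one (maximal Jacobian eigenvalue
    real part < 0) is selected.  Parameter sets where no real stable branch
    exists (e.g. a negative discriminant) abort.
    """

    def __init__(self, network: ReactionNetwork, name: str = "standard"):
        self.name = name
        self.network = network
        self.compiled = CompiledNetwork(network)
        self.fitted = list(network.parameters)
        self.theta_names = [str(s) for s in self.fitted]
        solutions = sp.solve(network.rhs(), network.states, dict=True)
        if not solutions:
            raise ValueError("no closed-form steady state found")
        self._branches = []
        for branch in solutions:
            x_exprs = sp.Matrix([branch[x] for x in network.states])
            self._branches.append(
                (
                    sp.lambdify([self.fitted], x_exprs, "numpy"),
                    sp.lambdify([self.fitted], x_exprs.jacobian(self.fitted), "numpy"),
                )
            )

    def evaluate(self, theta: np.ndarray):
        p = np.asarray(theta, float)
        dp = np.eye(len(p))
        for x0_fn, dx0_fn in self._branches:
            with np.errstate(all="ignore"):
                x0 = np.asarray(x0_fn(theta), float).ravel()
            if not np.all(np.isfinite(x0)):
                continue
            eig = np.linalg.eigvals(self.compiled.jac_x(x0, p))
            if float(np.max(eig.real)) < 0:
                with np.errstate(all="ignore"):
                    dx0 = np.asarray(dx0_fn(theta), float)
                return p, x0, dp, dx0
        raise InfeasibleSteadyState(f"{self.name}: no real stable steady-state branch")


class NumericParameterization(Parameterization):
    """Steady state computed by Newton's method at every evaluation.

    The previous evaluation's root warm-starts the next one (mirroring
    per-optimization-step recomputation); ∂x0/∂θ comes from the implicit
    function theorem.  Which root Newton lands on depends on the initial
    guess — stability of the returned root is *not* guaranteed, which is
    precisely this baseline's weakness.
    """

    def __init__(self, network: ReactionNetwork, name: str = "numeric"):
        self.name = name
        self.network = network
        self.compiled = CompiledNetwork(network)
        self.fitted = list(network.parameters)
        self.theta_names = [str(s) for s in self.fitted]
        self._warm: np.ndarray | None = None

    def fresh(self) -> "NumericParameterization":
        clone = NumericParameterization.__new__(NumericParameterization)
        clone.__dict__.update(self.__dict__)
        clone._warm = None
        return clone

    def evaluate(self, theta: np.ndarray):
        p = np.asarray(theta, float)
        dp = np.eye(len(p))
        result = newton_steady_state(self.compiled, p, x_init=self._warm)
        if not result.converged:
            raise InfeasibleSteadyState(f"{self.name}: Newton did not converge")
        self._warm = result.x0.copy()
        try:
            dx0 = steady_state_sensitivities(self.compiled, p, result.x0)
        except np.linalg.LinAlgError:
            raise InfeasibleSteadyState(
                f"{self.name}: singular Jacobian at the root"
            ) from None
        return p, result.x0, dp, dx0


def parameterization_from_solution(
    solution: SteadyStateSolution, name: str = "proposed"
) -> SymbolicParameterization:
    """Variant built from a cycle-splitting solver solution: fixed targets
    become expressions, everything else (including ratio parameters and
    released states) is fitted."""
    network = solution.network
    form = solution.independent_form
    assert form is not None
    param_exprs = {}
    state_exprs = {}
    for a in form:
        if a.target in network.states:
            state_exprs[a.target] = a.expression
        else:
            param_exprs[a.target] = a.expression
    fitted = sorted(solution.free_symbols(), key=str)
    return SymbolicParameterization(
        network, name, fitted, param_exprs, state_exprs
    )


def signs_variants(network: ReactionNetwork | None = None) -> dict[str, Parameterization]:
    """The four steady-state representations of the four-state chain.

    All four fit six parameters.  "standard" solves for initial values and
    goes negative for k0 < k1; "solved_for_k7" trades k7 for the initial
    value of B (still sign-indefinite); "solved_for_k0" and
    "standard_with_trafo" are the two non-negative representations.
    """
    net = network or four_state_chain_network()
    k0, k1, k2, k3, k4, k7 = (positive_symbol(s) for s in ["k0", "k1", "k2", "k3", "k4", "k7"])
    A, B, C, D = (positive_symbol(s) for s in ["A", "B", "C", "D"])
    dk0 = positive_symbol("dk0")

    B_std = k1 * k7 / (k2 * (k0 - k1))
    A_of = lambda k0e, k7e, Be: k0e / (k2 * Be + k7e)
    common = {C: k1 / k3, D: k1 / k4}

    standard = SymbolicParameterization(
        net, "standard", [k0, k1, k2, k3, k4, k7],
        state_expressions={A: A_of(k0, k7, B_std), B: B_std, **common},
    )
    k7_expr = B * k2 * (k0 - k1) / k1
    solved_for_k7 = SymbolicParameterization(
        net, "solved_for_k7", [k0, k1, k2, k3, k4, B],
        parameter_expressions={k7: k7_expr},
        state_expressions={A: A_of(k0, k7_expr, B), **common},
    )
    k0_expr = k1 * k7 / (B * k2) + k1
    solved_for_k0 = SymbolicParameterization(
        net, "solved_for_k0", [B, k1, k2, k3, k4, k7],
        parameter_expressions={k0: k0_expr},
        state_expressions={A: A_of(k0_expr, k7, B), **common},
    )
    k0_trafo = k1 + dk0
    standard_with_trafo = SymbolicParameterization(
        net, "standard_with_trafo", [dk0, k1, k2, k3, k4, k7],
        parameter_expressions={k0: k0_trafo},
        state_expressions={
            A: A_of(k0_trafo, k7, B_std.subs(k0, k0_trafo)),
            B: B_std.subs(k0, k0_trafo),
            **common,
        },
    )
    return {
        "standard": standard,
        "solved_for_k7": solved_for_k7,
        "solved_for_k0": solved_for_k0,
        "standard_with_trafo": standard_with_trafo,
    }


def multiplicity_variants(
    network: ReactionNetwork | None = None,
) -> dict[str, Parameterization]:
    """standard / numeric / proposed variants of the three-state feedback
    loop.  All fit seven parameters (the proposed variant trades k1 for the
    initial value of A)."""
    net = network or three_state_feedback_network()
    proposed = parameterization_from_solution(solve_steady_state(net), "proposed")
    return {
        "standard": ClosedFormStateParameterization(net, "standard"),
        "numeric": NumericParameterization(net, "numeric"),
        "proposed": proposed,
    }


# ---------------------------------------------------------------------------
# simulation and fitting
# ---------------------------------------------------------------------------


def _trajectory(
    compiled: CompiledNetwork,
    p: np.ndarray,
    x0: np.ndarray,
    design: ExperimentDesign,
    displacement: float,
    rtol: float | None = None,
    atol: float | None = None,
) -> np.ndarray:
    """Noiseless observation matrix (time × state): steady state before the
    stimulus, displaced trajectory afterwards."""
    times = design.times
    pre = times < design.stimulus_time
    out = np.empty((len(times), len(x0)))
    out[pre] = x0
    post_times = times[~pre]
    if post_times.size:
        y0 = x0.copy()
        y0[design.displaced_state] += displacement
        t_grid = np.concatenate(([design.stimulus_time], post_times))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", scipy.integrate.ODEintWarning)
                traj, info = scipy.integrate.odeint(
                    lambda x, t: compiled.f(x, p),
                    y0,
                    t_grid,
                    Dfun=lambda x, t: compiled.jac_x(x, p),
                    rtol=rtol or design.rtol,
                    atol=atol or design.atol,
                    full_output=True,
                    printmessg=False,
                    mxstep=5000,
                )
        except scipy.integrate.ODEintWarning as exc:
            raise AbortFit(f"integration failed: {exc}") from None
        if "successful" not in info["message"]:
            raise AbortFit(f"integration failed: {info['message']}")
        out[~pre] = traj[1:]
    if not np.all(np.isfinite(out)):
        raise AbortFit("non-finite trajectory")
    return out


def simulate_data(
    network: ReactionNetwork,
    true_params: dict[str, float],
    design: ExperimentDesign,
    seed: int = 0,
) -> Dataset:
    """Simulate the stimulus-displacement protocol from the stable steady
    state, one condition per displacement value, Gaussian noise with
    sd = max(noise_sd_fraction × per-state dynamic range, noise_floor)."""
    compiled = CompiledNetwork(network)
    p = compiled.parameter_vector(true_params)
    stable = [r for r, s in positive_steady_states(compiled, p, seed=seed) if s == "stable"]
    if not stable:
        raise ValueError("no stable positive steady state for the true parameters")
    x0 = stable[0]

    clean = np.stack(
        [
            _trajectory(compiled, p, x0, design, d, rtol=1e-10, atol=1e-12)
            for d in design.displacements
        ]
    )  # (condition, time, state)
    span = clean.max(axis=(0, 1)) - clean.min(axis=(0, 1))
    sd = np.maximum(design.noise_sd_fraction * span, design.noise_floor)

    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, 1.0, size=clean.shape) * sd
    rows = []
    for ci, d in enumerate(design.displacements):
        for ti, t in enumerate(design.times):
            for si, s in enumerate(network.states):
                rows.append(
                    {
                        "condition": ci,
                        "displacement": d,
                        "time": t,
                        "state": str(s),
                        "value": noisy[ci, ti, si],
                        "sd": sd[si],
                    }
                )
    return Dataset(
        frame=pd.DataFrame(rows),
        network=network,
        true_params=dict(true_params),
        x0=x0,
        design=design,
    )


class _Objective:
    """Weighted-residual function with forward-sensitivity gradients, in
    natural-log parameter space."""

    def __init__(
        self,
        parameterization: Parameterization,
        dataset: Dataset,
        design: ExperimentDesign,
    ):
        self.par = parameterization
        self.design = design
        self.compiled = CompiledNetwork(dataset.network)
        self.values, self.sds, _ = dataset.arrays()
        self.displacements = list(design.displacements)
        self._cache: tuple[bytes, np.ndarray] | None = None
        self._jcache: tuple[bytes, np.ndarray] | None = None
        self._n_residuals: int | None = None

    # A trial step whose integration fails is infinitely bad but should not
    # kill the fit: the optimizer rejects it and shrinks the trust region.
    # Only a failure at the *starting* point aborts the fit.
    PENALTY = 1e6

    # -- plain residuals (states only) --------------------------------------

    def residuals(self, log_theta: np.ndarray) -> np.ndarray:
        key = np.asarray(log_theta).tobytes()
        if self._cache and self._cache[0] == key:
            return self._cache[1]
        try:
            theta = np.exp(np.asarray(log_theta, float))
            p, x0, _, _ = self.par.evaluate(theta)
            res = []
            for ci, d in enumerate(self.displacements):
                model = _trajectory(self.compiled, p, x0, self.design, d)
                res.append(((model - self.values[ci]) / self.sds[ci]).ravel())
            out = np.concatenate(res)
            if not np.all(np.isfinite(out)):
                raise AbortFit("non-finite residuals")
        except InfeasibleSteadyState:
            raise  # undefined parameterization: the fit aborts here
        except AbortFit:
            if self._n_residuals is None:
                raise  # infeasible starting point: the fit aborts
            out = np.full(self._n_residuals, self.PENALTY)
            self._cache = (key, out)
            return out
        self._n_residuals = out.size
        self._cache = (key, out)
        return out

    # -- residual Jacobian via forward sensitivities ------------------------

    def jacobian(self, log_theta: np.ndarray) -> np.ndarray:
        key = np.asarray(log_theta).tobytes()
        if self._jcache and self._jcache[0] == key:
            return self._jcache[1]
        theta = np.exp(np.asarray(log_theta, float))
        p, x0, dp, dx0 = self.par.evaluate(theta)
        n = len(x0)
        d_theta = dp.shape[1]
        design = self.design
        times = design.times
        pre = times < design.stimulus_time
        rows = []
        for ci, d in enumerate(self.displacements):
            sens = np.empty((len(times), n, d_theta))
            sens[pre] = dx0
            post_times = times[~pre]
            if post_times.size:
                y0 = np.concatenate([x0, dx0.ravel()])
                y0[design.displaced_state] += d

                def rhs_aug(z, t):
                    x = z[:n]
                    s = z[n:].reshape(n, d_theta)
                    jx = self.compiled.jac_x(x, p)
                    jp = self.compiled.jac_p(x, p)
                    return np.concatenate(
                        [self.compiled.f(x, p), (jx @ s + jp @ dp).ravel()]
                    )

                t_grid = np.concatenate(([design.stimulus_time], post_times))
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("error", scipy.integrate.ODEintWarning)
                        traj, info = scipy.integrate.odeint(
                            rhs_aug, y0, t_grid,
                            rtol=design.rtol, atol=design.atol,
                            full_output=True, printmessg=False, mxstep=5000,
                        )
                except scipy.integrate.ODEintWarning as exc:
                    raise AbortFit(f"sensitivity integration failed: {exc}") from None
                if "successful" not in info["message"]:
                    raise AbortFit(f"sensitivity integration failed: {info['message']}")
                sens[~pre] = traj[1:, n:].reshape(len(post_times), n, d_theta)
            rows.append((sens / self.sds[ci][:, :, None]).reshape(-1, d_theta))
        jac = np.vstack(rows) * theta[None, :]  # chain rule for log-space
        if not np.all(np.isfinite(jac)):
            raise AbortFit("non-finite sensitivities")
        self._jcache = (key, jac)
        return jac


def multistart_fit(
    parameterization: Parameterization,
    dataset: Dataset,
    design: ExperimentDesign | None = None,
    seed: int = 0,
    n_starts: int | None = None,
) -> list[FitResult]:
    """Trust-region least-squares fits from log-uniform random starts.

    Failures (infeasible steady states, exploding integrations, optimizer
    errors) are recorded per start with status "aborted"; statuses
    global/local are assigned later by :func:`success_rate` once a reference
    objective is known.
    """
    design = design or dataset.design
    n_starts = n_starts if n_starts is not None else design.n_starts
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(design.sample_range)
    d = len(parameterization.theta_names)
    starts = 10.0 ** rng.uniform(lo, hi, size=(n_starts, d))

    results: list[FitResult] = []
    for sid in range(n_starts):
        theta0 = starts[sid]
        par = parameterization.fresh()
        objective = _Objective(par, dataset, design)
        initial = dict(zip(parameterization.theta_names, theta0))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = scipy.optimize.least_squares(
                    objective.residuals,
                    np.log(theta0),
                    jac=objective.jacobian,
                    method="trf",
                    bounds=(np.log(1e-12), np.log(1e12)),
                    max_nfev=design.max_nfev,
                )
            theta_hat = np.exp(fit.x)
            result = FitResult(
                start_id=sid,
                initial_parameters=initial,
                final_parameters=dict(zip(parameterization.theta_names, theta_hat)),
                objective=float(fit.cost),
                status="converged",
                n_steps=int(fit.nfev),
            )
            _attach_details(result, par, theta_hat, dataset)
        except (AbortFit, np.linalg.LinAlgError, ValueError, OverflowError) as exc:
            result = FitResult(
                start_id=sid,
                initial_parameters=initial,
                final_parameters=None,
                objective=float("inf"),
                status="aborted",
                details={"error": str(exc)},
            )
        results.append(result)
    return results


def _attach_details(
    result: FitResult,
    parameterization: Parameterization,
    theta_hat: np.ndarray,
    dataset: Dataset,
) -> None:
    """For the numeric variant, compare the Newton root with the stable
    analytic branch at the final parameters (root-identity diagnostic)."""
    if not isinstance(parameterization, NumericParameterization):
        return
    try:
        p, x0, _, _ = parameterization.evaluate(theta_hat)
        compiled = parameterization.compiled
        stable = [
            r
            for r, s in positive_steady_states(compiled, p, n_guesses=20, seed=0)
            if s == "stable"
        ]
        if stable:
            idx = dataset.design.displaced_state
            result.details["root_ratio"] = float(x0[idx] / stable[0][idx])
            result.details["on_stable_root"] = bool(
                np.allclose(x0, stable[0], rtol=1e-6, atol=1e-9)
            )
    except AbortFit:
        pass


@dataclass
class ExperimentSummary:
    n_fits: int
    fraction_global: float
    fraction_local: float
    fraction_aborted: float
    best_objective: float
    plateaus: list[tuple[float, int]]  # (objective level, multiplicity)


def success_rate(
    fits: list[FitResult],
    tolerance: float = 0.5,
    best_objective: float | None = None,
) -> ExperimentSummary:
    """Classify fits and summarize the waterfall.

    ``best_objective`` is the reference for "global" (pass the best across
    all variants fitted to the same dataset to compare variants fairly);
    plateaus are clusters of sorted converged objectives separated by more
    than ``tolerance``.
    """
    if not fits:
        raise ValueError("empty fit list")
    converged = [f for f in fits if f.status != "aborted" and np.isfinite(f.objective)]
    if best_objective is None:
        best_objective = min((f.objective for f in converged), default=float("inf"))
    n_global = n_local = 0
    for f in fits:
        if f.status == "aborted" or not np.isfinite(f.objective):
            f.status = "aborted"
        elif f.objective <= best_objective + tolerance:
            f.status = "global"
            n_global += 1
        else:
            f.status = "local"
            n_local += 1
    plateaus: list[tuple[float, int]] = []
    for obj in sorted(f.objective for f in converged):
        if plateaus and obj - plateaus[-1][0] <= tolerance:
            plateaus[-1] = (plateaus[-1][0], plateaus[-1][1] + 1)
        else:
            plateaus.append((obj, 1))
    n = len(fits)
    return ExperimentSummary(
        n_fits=n,
        fraction_global=n_global / n,
        fraction_local=n_local / n,
        fraction_aborted=(n - n_global - n_local) / n,
        best_objective=best_objective,
        plateaus=plateaus,
    )


def run_case(
    case: str,
    seed: int = 1,
    n_starts: int | None = None,
    variants: list[str] | None = None,
    design: ExperimentDesign | None = None,
):
    """Run one full benchmark case.

    Returns (dataset, fits_by_variant, summaries_by_variant).  The "global"
    reference objective is the best converged objective across all variants
    on the shared dataset.
    """
    if case == "signs":
        network = four_state_chain_network()
        true_params = SIGNS_TRUE_PARAMS
        design = design or ExperimentDesign.signs()
        table = signs_variants(network)
    elif case == "multiplicity":
        network = three_state_feedback_network()
        true_params = MULTIPLICITY_TRUE_PARAMS
        design = design or ExperimentDesign.multiplicity()
        table = multiplicity_variants(network)
    else:
        raise ValueError("case must be 'signs' or 'multiplicity'")
    if variants:
        table = {k: v for k, v in table.items() if k in variants}

    root = np.random.SeedSequence(seed)
    data_seed, *variant_seeds = root.spawn(1 + len(table))
    dataset = simulate_data(
        network, true_params, design, seed=int(data_seed.generate_state(1)[0] % 2**31)
    )
    fits = {}
    for (name, par), vseed in zip(table.items(), variant_seeds):
        fits[name] = multistart_fit(
            par,
            dataset,
            design,
            seed=int(vseed.generate_state(1)[0] % 2**31),
            n_starts=n_starts,
        )
    best = min(
        (
            f.objective
            for results in fits.values()
            for f in results
            if f.status != "aborted" and np.isfinite(f.objective)
        ),
        default=float("inf"),
    )
    summaries = {
        name: success_rate(results, design.objective_tolerance, best)
        for name, results in fits.items()
    }
    return dataset, fits, summaries


def fits_to_frame(fits_by_variant: dict[str, list[FitResult]]) -> pd.DataFrame:
    """Flatten fit results for CSV export."""
    rows = []
    for variant, fits in fits_by_variant.items():
        for f in fits:
            row = {
                "variant": variant,
                "start_id": f.start_id,
                "objective": f.objective,
                "status": f.status,
                "n_steps": f.n_steps,
            }
            for k, v in f.initial_parameters.items():
                row[f"init_{k}"] = v
            for k, v in (f.final_parameters or {}).items():
                row[f"final_{k}"] = v
            if "root_ratio" in f.details:
                row["root_ratio"] = f.details["root_ratio"]
            rows.append(row)
    return pd.DataFrame(rows)


def waterfall_plot(fits_by_variant: dict[str, list[FitResult]], ax=None):
    """Sorted converged objectives per variant (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for variant, fits in fits_by_variant.items():
        objs = sorted(
            f.objective for f in fits if f.status != "aborted" and np.isfinite(f.objective)
        )
        ax.plot(range(1, len(objs) + 1), objs, marker=".", label=variant)
    ax.set_xlabel("fit index (sorted)")
    ax.set_ylabel("negative log-likelihood")
    ax.legend()
    return ax
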