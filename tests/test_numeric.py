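"""Newton steady states, IFT sensitivities, stability, numeric validation."""

import numpy as np
import pytest
import sympy as sp

from crnsteady.model import parse_network
from crnsteady.numeric import (
    CompiledNetwork,
    newton_steady_state,
    positive_steady_states,
    stability,
    steady_state_sensitivities,
    verify_solution,
)
from crnsteady.solver import (
    Assignment,
    Provenance,
    SteadyStateSolution,
    back_substitute,
    solve_steady_state,
)
from conftest import sym

FEEDBACK_TRUE = {"k0": 1.0, "k1": 2.0, "k2": 1.0, "k3": 1.0, "k4": 2.0, "k5": 1.0, "k6": 2.0}


def quadratic_roots(params):
    """Independent oracle for the feedback model: positive roots of
    (k2k3k5/(k4k6))·A² − k1·A + k0 = 0, with B and C back-computed."""
    k = params
    c = k["k2"] * k["k3"] * k["k5"] / (k["k4"] * k["k6"])
    roots = np.roots([c, -k["k1"], k["k0"]])
    out = []
    for A in sorted(r.real for r in roots if abs(r.imag) < 1e-12 and r.real > 0):
        B = k["k2"] * A / k["k4"]
        C = k["k5"] * A * B / k["k6"]
        out.append(np.array([A, B, C]))
    return out


class TestNewton:
    def test_linear_chain_converges_immediately(self):
        net = parse_network("0 -> X ; k0\nX -> 0 ; k1*X")
        res = newton_steady_state(net, {"k0": 3.0, "k1": 1.5})
        assert res.converged and res.iterations <= 2
        assert res.x0[0] == pytest.approx(2.0)

    def test_feedback_model_matches_closed_form_branch(self, three_state):
        roots = quadratic_roots(FEEDBACK_TRUE)
        assert len(roots) == 2
        res = newton_steady_state(
            three_state, FEEDBACK_TRUE, x_init=roots[1] * 1.05
        )
        assert res.converged
        np.testing.assert_allclose(res.x0, roots[1], rtol=1e-8)

    def test_negative_discriminant_flagged(self, three_state):
        params = dict(FEEDBACK_TRUE, k0=10.0)  # k1²k4k6=16 < 4·k0·…=40
        assert 16 < 4 * 10.0  # brute-check: discriminant negative
        res = newton_steady_state(three_state, params)
        assert not res.converged

    def test_basin_sanity_around_stable_root(self, three_state):
        stable = quadratic_roots(FEEDBACK_TRUE)[0]
        rng = np.random.default_rng(0)
        for _ in range(50):
            start = stable * (1 + rng.uniform(-0.2, 0.2, size=3))
            res = newton_steady_state(three_state, FEEDBACK_TRUE, x_init=start)
            assert res.converged
            np.testing.assert_allclose(res.x0, stable, rtol=1e-6)


class TestSensitivities:
    def test_one_state_closed_form(self):
        net = parse_network("0 -> X ; k0\nX -> 0 ; k1*X")
        k0, k1 = 3.0, 1.5
        S = steady_state_sensitivities(net, {"k0": k0, "k1": k1}, np.array([k0 / k1]))
        np.testing.assert_allclose(S, [[1 / k1, -k0 / k1**2]], rtol=1e-12)

    @pytest.mark.parametrize("model", ["three_state", "four_state"])
    def test_matches_finite_differences(self, model, request):
        net = request.getfixturevalue(model)
        compiled = CompiledNetwork(net)
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 3:
            p = 10.0 ** rng.uniform(-0.3, 0.3, size=len(compiled.parameters))
            res = newton_steady_state(compiled, p)
            if not res.converged or np.any(res.x0 <= 0):
                continue
            S = steady_state_sensitivities(compiled, p, res.x0)
            fd = np.empty_like(S)
            for j in range(len(p)):
                h = 1e-6 * p[j]
                up, dn = p.copy(), p.copy()
                up[j] += h
                dn[j] -= h
                fd[:, j] = (
                    newton_steady_state(compiled, up, x_init=res.x0).x0
                    - newton_steady_state(compiled, dn, x_init=res.x0).x0
                ) / (2 * h)
            np.testing.assert_allclose(S, fd, rtol=1e-5, atol=1e-8)
            checked += 1


class TestStability:
    def test_pure_decay_is_stable(self):
        net = parse_network("X -> 0 ; k*X ; param=k")
        assert stability(net, {"k": 2.0}, np.array([0.0])) == "stable"

    def test_feedback_branches(self, three_state):
        lo, hi = quadratic_roots(FEEDBACK_TRUE)
        assert stability(three_state, FEEDBACK_TRUE, lo) == "stable"
        assert stability(three_state, FEEDBACK_TRUE, hi) == "unstable"

    def test_exactly_one_stable_branch_for_random_draws(self, three_state):
        rng = np.random.default_rng(11)
        compiled = CompiledNetwork(three_state)
        found = 0
        while found < 50:
            vals = 10.0 ** rng.uniform(-1, 1, size=7)
            params = dict(zip([str(p) for p in compiled.parameters], vals))
            roots = quadratic_roots(params)
            if len(roots) != 2:  # discriminant not positive
                continue
            labels = [stability(compiled, params, r) for r in roots]
            assert sorted(labels) == ["stable", "unstable"]
            found += 1

    def test_multistart_enumeration_finds_both_roots(self, three_state):
        roots = positive_steady_states(three_state, FEEDBACK_TRUE, seed=3)
        assert len(roots) == 2
        assert [s for _, s in roots] == ["stable", "unstable"]


class TestVerifySolution:
    def test_six_state_solution_is_clean(self, six_state_solution):
        report = verify_solution(six_state_solution, n_samples=60, seed=2)
        assert report.ok
        assert report.max_residual < 1e-9
        assert report.min_fixed_value > 0
        assert report.max_flatness_drift < 1e-6

    def test_chain_solution_has_zero_violations(self):
        net = parse_network("0 -> A ; k0\nA -> B ; k1*A\nB -> 0 ; k2*B")
        report = verify_solution(solve_steady_state(net), n_samples=40, seed=1)
        assert report.ok

    def test_state_solved_chain_reports_negativity(self, four_state):
        """The initial-value-solved representation of the open chain has
        B = k1k7/(k2(k0−k1)), negative whenever k0 < k1."""
        A, B, C, D = (sym(s) for s in "ABCD")
        k0, k1, k2, k3, k4, k7 = (sym(f"k{i}") for i in (0, 1, 2, 3, 4, 7))
        B_expr = k1 * k7 / (k2 * (k0 - k1))
        assignments = [
            Assignment(B, B_expr, Provenance.TREE_SOLVE),
            Assignment(A, k0 / (k2 * B_expr + k7), Provenance.TREE_SOLVE),
            Assignment(C, k1 / k3, Provenance.TREE_SOLVE),
            Assignment(D, k1 / k4, Provenance.TREE_SOLVE),
        ]
        solution = back_substitute(
            SteadyStateSolution(
                network=four_state,
                assignments=assignments,
                ratio_parameters=[],
                free_states=[],
                conserved=[],
                trace=[],
            )
        )
        report = verify_solution(solution, n_samples=100, seed=4, n_integrate=0)
        assert report.min_fixed_value < 0
        assert any("negative" in v for v in report.violations)
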