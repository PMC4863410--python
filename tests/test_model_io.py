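"""Parsing, validation, serialization and random generation of networks."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from crnsteady.model import (
    ModelSyntaxError,
    RateLawKind,
    generate_random_network,
    parse_network,
    validate_network,
)
from conftest import sym


class TestParse:
    def test_single_mass_action_conversion(self):
        net = parse_network("A -> B ; k1*A")
        assert [str(s) for s in net.states] == ["A", "B"]
        assert net.stoichiometry.tolist() == [[-1], [1]]
        assert net.fluxes[0] == sym("k1") * sym("A")

    def test_six_state_model_shape_and_mediated_degradation(self, six_state):
        assert six_state.n_states == 6
        assert six_state.n_reactions == 9
        # degradation of B is mediated by F: flux k7*B*F, F only a modifier
        reaction = six_state.reactions[7]
        assert reaction.rate_law.flux == sym("k7") * sym("B") * sym("F")
        assert sym("F") in reaction.modifiers
        col = six_state.stoichiometry[:, 7]
        assert col[six_state.state_index(sym("B"))] == -1
        assert col[six_state.state_index(sym("F"))] == 0

    def test_mediated_production_has_single_stoichiometry_entry(self, three_state):
        # production of C is mediated by A and B: only C gains molecules
        reaction = three_state.reactions[5]
        assert reaction.rate_law.flux == sym("k5") * sym("A") * sym("B")
        col = three_state.stoichiometry[:, 5]
        nonzero = {str(three_state.states[i]): int(v) for i, v in enumerate(col) if v}
        assert nonzero == {"C": 1}

    def test_param_annotation_overrides_prefix_rule(self):
        net = parse_network("A -> 0 ; gamma*A ; param=gamma")
        assert str(net.flux_parameters[0]) == "gamma"
        assert net.reactions[0].rate_law.factor == sym("A")

    def test_explicit_coefficients_and_source_sink(self):
        net = parse_network("0 -> A ; k0\n2 A -> C ; k3*A^2")
        assert net.stoichiometry[net.state_index(sym("A")), 1] == -2
        net2 = parse_network("A + A -> C ; k3*A^2")
        assert net2.stoichiometry[0, 0] == -2

    @pytest.mark.parametrize(
        "text,match",
        [
            ("A -> B", "flux"),
            ("A -> B ; k1*A + k2*B", "exactly one"),
            ("A -> B ; k1", "outflux"),
            ("A ->> B ; k1*A", "species"),
        ],
    )
    def test_syntax_and_assumption_errors(self, text, match):
        with pytest.raises(ModelSyntaxError, match=match):
            parse_network(text)


class TestRhs:
    def test_four_state_printed_odes(self, four_state):
        f = four_state.rhs()
        A, B, C, D = (sym(s) for s in "ABCD")
        k0, k1, k2, k3, k4, k7 = (sym(f"k{i}") for i in (0, 1, 2, 3, 4, 7))
        assert sp.expand(f[four_state.state_index(B)] - (k1 - k2 * A * B)) == 0
        assert sp.expand(f[four_state.state_index(A)] - (k0 - k7 * A - k2 * A * B)) == 0

    def test_three_state_printed_odes(self, three_state):
        f = three_state.rhs()
        A, C = sym("A"), sym("C")
        expected = sym("k0") + sym("k3") * C - sym("k1") * A
        assert sp.expand(f[three_state.state_index(A)] - expected) == 0

    def test_empty_network(self):
        assert parse_network("").rhs() == []

    def test_rhs_matches_per_reaction_assembly(self, six_state):
        """Independent assembly oracle: sum (products − reactants)·flux over
        reactions, plus modifier-free bookkeeping, reproduces S·F."""
        per_state = {s: sp.Integer(0) for s in six_state.states}
        for reaction in six_state.reactions:
            for s, c in reaction.net_stoichiometry().items():
                per_state[s] += c * reaction.rate_law.flux
        for s, expr in zip(six_state.states, six_state.rhs()):
            assert sp.expand(expr - per_state[s]) == 0


class TestValidate:
    def test_worked_models_pass(self, six_state, four_state, three_state):
        for net in (six_state, four_state, three_state):
            assert validate_network(net) == []

    def test_round_trip_text(self, six_state, four_state, three_state):
        for net in (six_state, four_state, three_state):
            again = parse_network(net.to_text())
            assert again.states == net.states
            assert (again.stoichiometry == net.stoichiometry).all()
            assert again.fluxes == net.fluxes

    def test_round_trip_json(self, six_state):
        from crnsteady.model import ReactionNetwork

        again = ReactionNetwork.from_json(six_state.to_json())
        assert again.states == six_state.states
        assert (again.stoichiometry == six_state.stoichiometry).all()


_side = st.lists(
    st.tuples(st.sampled_from("ABCD"), st.integers(1, 3)),
    min_size=0,
    max_size=3,
    unique_by=lambda pair: pair[0],
)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(reactants=_side.filter(bool), products=_side)
def test_parsed_stoichiometry_matches_mass_balance(reactants, products):
    """Property: for any mass-action reaction line, the parsed stoichiometry
    column equals products − reactants, species by species."""
    lhs = " + ".join(f"{c} {s}" for s, c in reactants)
    rhs_side = " + ".join(f"{c} {s}" for s, c in products) or "0"
    flux = "k1*" + "*".join(f"{s}^{c}" for s, c in reactants)
    net = parse_network(f"{lhs} -> {rhs_side} ; {flux}")
    expected = {}
    for s, c in reactants:
        expected[s] = expected.get(s, 0) - c
    for s, c in products:
        expected[s] = expected.get(s, 0) + c
    for i, state in enumerate(net.states):
        assert net.stoichiometry[i, 0] == expected.get(str(state), 0)


class TestGenerator:
    def test_seed_determinism(self):
        a = generate_random_network(4, 7, seed=1)
        b = generate_random_network(4, 7, seed=1)
        assert a.to_text() == b.to_text()
        c = generate_random_network(4, 7, seed=2)
        assert c.to_text() != a.to_text()

    def test_monomial_kinds(self):
        net = generate_random_network(
            3, 6, kinds={RateLawKind.MASS_ACTION, RateLawKind.PRODUCTION}, seed=3
        )
        for r in net.reactions:
            num, den = sp.fraction(sp.together(r.rate_law.factor))
            assert den == 1  # monomial flux factors only

    @pytest.mark.parametrize("seed", range(5))
    def test_generated_networks_validate(self, seed):
        net = generate_random_network(5, 8, seed=seed)
        assert net.stoichiometry.shape == (5, 8)
        assert validate_network(net) == []
        # every state has at least one outflux
        assert (net.stoichiometry.min(axis=1) < 0).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_fluxes_positive_at_positive_points(self, seed):
        net = generate_random_network(
            4,
            7,
            kinds=set(RateLawKind) - {RateLawKind.CUSTOM},
            seed=seed,
        )
        rng = np.random.default_rng(seed)
        symbols = sorted(
            {s for f in net.fluxes for s in f.free_symbols}, key=str
        )
        fn = sp.lambdify([symbols], sp.Matrix(net.fluxes), "numpy")
        for _ in range(20):
            vals = 10.0 ** rng.uniform(-1, 1, size=len(symbols))
            assert (np.asarray(fn(vals), dtype=float) > 0).all()

    def test_infeasible_configurations(self):
        with pytest.raises(ValueError):
            generate_random_network(0, 3)
        with pytest.raises(ValueError):
            generate_random_network(2, 4, kinds={RateLawKind.PRODUCTION})
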