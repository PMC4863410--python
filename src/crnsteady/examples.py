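"""Built-in example networks used throughout the documentation and tests.

Three small mass-action networks that exercise the solver in qualitatively
different ways:

* ``six_state_network`` — six states, nine reactions, one conservation
  relation (F + G); solving its steady state for the state variables leads to
  a sixth-order polynomial, while the cycle-splitting solver fixes six
  quantities with a single free flux ratio.
* ``four_state_chain_network`` — an open four-state chain whose steady state,
  solved for initial values, turns negative whenever k0 < k1.
* ``three_state_feedback_network`` — a three-state positive-feedback loop
  with two coexisting steady states (one stable, one unstable) controlled by
  the sign of the discriminant k1²k4k6·(k1²k4k6 − 4k0k2k3k5).
"""

from __future__ import annotations

from .model import ReactionNetwork, parse_network

__all__ = [
    "SIX_STATE_TEXT",
    "FOUR_STATE_CHAIN_TEXT",
    "THREE_STATE_FEEDBACK_TEXT",
    "six_state_network",
    "four_state_chain_network",
    "three_state_feedback_network",
]

# Dimerization of A feeds C; degradation of B is mediated by F; D and G bind
# to form F which recycles to G, making F + G a conserved total.
SIX_STATE_TEXT = """\
0 -> A ; k0
A -> B ; k1*A
B -> A ; k2*B
A -> C ; k3*A^2        # dimerization, written with unit net stoichiometry
C -> 0 ; k4*C
B + C -> D ; k5*B*C
D + G -> F ; k6*D*G
B -> 0 ; k7*B*F        # degradation of B mediated by F
F -> G ; k8*F
"""

# Open production/degradation chain: A and B bind to C which converts to D.
FOUR_STATE_CHAIN_TEXT = """\
0 -> A ; k0
A -> 0 ; k7*A
A + B -> C ; k2*A*B
0 -> B ; k1
C -> D ; k3*C
D -> 0 ; k4*D
"""

# Positive feedback: A drives B, A and B drive C, C drives A.
THREE_STATE_FEEDBACK_TEXT = """\
0 -> A ; k0
A -> 0 ; k1*A
0 -> B ; k2*A          # production of B mediated by A
0 -> A ; k3*C          # production of A mediated by C
B -> 0 ; k4*B
0 -> C ; k5*A*B        # production of C mediated by A and B
C -> 0 ; k6*C
"""


def six_state_network() -> ReactionNetwork:
    return parse_network(SIX_STATE_TEXT, name="six-state")


def four_state_chain_network() -> ReactionNetwork:
    return parse_network(FOUR_STATE_CHAIN_TEXT, name="four-state-chain")


def three_state_feedback_network() -> ReactionNetwork:
    return parse_network(THREE_STATE_FEEDBACK_TEXT, name="three-state-feedback")
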