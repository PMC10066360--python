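"""Simulate a giving-at-random game and summarise where tokens come from.

Under the null every player picks a receiver uniformly over all 14 players
each round, so in expectation a player receives 6/14 of tokens from the six
other members of their own group, 7/14 from the outgroup, and 1/14 from
themself.
"""

from tokengame import (STUDY_CONFIG, RngSpec, received_proportions,
                       reciprocity_correlation, simulate_null_game)

game = simulate_null_game(STUDY_CONFIG, RngSpec(seed=1))

p = received_proportions(game, t=40)
print(f"received from ingroup : {p.ingroup:.3f}   (uniform expectation 6/14 = {6/14:.3f})")
print(f"received from outgroup: {p.outgroup:.3f}   (uniform expectation 7/14 = {7/14:.3f})")
print(f"received from self    : {p.self_:.3f}   (uniform expectation 1/14 = {1/14:.3f})")

for scope in ("ingroup", "outgroup"):
    r = reciprocity_correlation(game, scope, t=40)
    print(f"{scope} give/receive correlation: {r:+.3f}  (random giving -> near 0)")
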