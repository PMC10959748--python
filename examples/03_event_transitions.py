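"""Markov transition structure of social-event sequences.

Draws per-trial sequences over the four social events from a known
transition matrix and recovers it with the bigram maximum-likelihood
estimator, honouring the all-four-states trial-inclusion rule.
"""

import numpy as np

from socoop.markov import STATES, estimate_transitions
from socoop.synth import simulate_event_sequence

rng = np.random.default_rng(3)
true = np.array([[0.10, 0.40, 0.30, 0.20],
                 [0.30, 0.10, 0.40, 0.20],
                 [0.45, 0.30, 0.10, 0.15],
                 [0.25, 0.40, 0.25, 0.10]])

seq = simulate_event_sequence(true, 5000, rng)
tm = estimate_transitions(seq)

print("estimated transition probabilities (rows = from, cols = to):")
print("            " + "  ".join(f"{s[:9]:>9}" for s in STATES))
for i, s in enumerate(STATES):
    row = "  ".join(f"{tm.probs[i, j]:9.3f}" for j in range(4))
    print(f"{s[:11]:>11} {row}")
print(f"\nmax |estimate - truth| = {np.abs(tm.probs - true).max():.3f} "
      f"over {tm.n_transitions} transitions")
print("\nHigh view->push entries against low push->push entries capture the")
print("finding that fixations on social cues, not repeated pushing, lead")
print("into cooperative actions.")
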