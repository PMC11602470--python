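"""Quantify state-sequence dynamics and test transition randomness.

Builds a consolidated state sequence, prints frequency / mean duration /
coverage per state, and runs the chi-square permutation test that asks
whether the observed transition probabilities carry structure beyond what
the state frequencies alone would produce.
"""

import numpy as np

import mwnetdyn as mw

# a maximally structured sequence: the deterministic A->B->C->D cycle
# (the permutation test is deliberately conservative; see docs/methods.md)
labels = ["ABCD"[i % 4] for i in range(300)]

seq = mw.build_state_sequence(
    [(i, i + 1.0, s) for i, s in enumerate(labels)],
    participant_id="P01", trial_label="FL-1", band="gamma",
)

print("per-state dynamics metrics:")
for state, m in mw.sequence_metrics(seq).items():
    print(f"  {state}: frequency {m['frequency']:.3f}/s, "
          f"mean duration {m['mean_duration']:.2f} s, coverage {m['coverage']:.2f}")

observed = mw.observed_transitions(seq)
expected = mw.expected_transitions(seq)
result = mw.transition_randomness_test(observed, expected, n_perm=999, seed=1)
print(f"chi-square distance between observed and frequency-only expectation: "
      f"{result.chi_square_d:.4f}")
print(f"permutation p-value: {result.p_value:.4f} "
      "(small p = transitions are structured, not frequency-driven)")
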