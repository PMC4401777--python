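"""Score one triplet against all 16 gates.

Builds a 20-sample binary triplet in which the target is on almost exactly
when both regulators are on, tabulates the per-input-combination counts,
and prints every gate's consistency score.  The best gate is AND with score
900/2401 ~ 0.37; a score near 1 would mean the truth table is reproduced in
every sample, and 1/16 = 0.0625 is the no-information baseline.
"""

import numpy as np

from loregic import enumerate_gates, match_gate, tabulate_counts

# 5 samples per input combination (RF1, RF2); T follows AND with one
# discordant sample at (0,1) and one at (1,1)
x = np.array([0] * 10 + [1] * 10)
y = np.array([0] * 5 + [1] * 5 + [0] * 5 + [1] * 5)
z = np.array([0] * 5 + [0, 0, 0, 0, 1] + [0] * 5 + [1, 1, 1, 1, 0])

counts = tabulate_counts(x, y, z)
print(f"samples per input combination (0,0),(0,1),(1,0),(1,1): {counts.m_i}")
print(f"target=1 counts per combination:                       {counts.n1_i}")

match = match_gate(x, y, z)
print("\nper-gate consistency scores:")
for gate, score in zip(enumerate_gates(), match.per_gate_scores):
    marker = "  <- best" if gate is match.best_gate else ""
    print(f"  {gate.expr:<24} {float(score):.4f}{marker}")

print(f"\nmatched gate: {match.gate_label}  (score {float(match.score):.2f})")
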