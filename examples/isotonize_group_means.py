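"""Correct order reversals in noisy group mean exposures by weighted PAVA.

Five ordered exposure groups were sampled with (4, 3, 5, 3, 4) measurements;
the observed means reverse the hypothesized order in two places.  The weighted
isotonic regression pools the offending adjacent groups into blocks carrying
their weighted average, restoring monotonicity while conserving the weighted
total.
"""

from semieco import pava

means = [0.7755, 0.6229, 1.8207, 2.2878, 1.7054]
counts = [4, 3, 5, 3, 4]

fit = pava(means, counts)

print("observed group means :", means)
print("observed sample sizes:", counts)
print("isotonized scores    :", [round(float(v), 4) for v in fit.fitted])
print("pooled blocks (0-based index ranges):", fit.blocks)
print()
print("Groups 1-2 and 4-5 violated the increasing order and were pooled;")
print("each pooled value is the sample-size-weighted mean of its block.")
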