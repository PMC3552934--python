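"""Replicated bias comparison of the estimators under classical error.

Reruns a slice of the bias experiment: linear outcome, 5 ordered groups of
30, slope 0.3, between-subject variance 0.6, error variance 0.5, with either
all or 10-of-30 exposures measured; 200 replications per cell.  Reported per
cell and method: percent relative bias of the slope (signed), its Monte-Carlo
standard error, and the empirical MSE.
"""

from semieco import CemOptions, Scenario, run_experiment

cells = [
    Scenario(seed=7),                 # all exposures observed
    Scenario(seed=7, n_x=10),         # 10 of 30 observed per group
]

table = run_experiment(cells, methods=["naive", "gbs", "cgbs", "cem"],
                       cem_options=CemOptions(compute_se=False))

cols = ["n_x", "method", "bias_pct", "mc_se_bias_pct", "mse", "n_failed"]
print(table[cols].round(3).to_string(index=False))
print()
print("With full data the naive slope is attenuated ~40% while CEM removes")
print("most of the bias; with 10/30 measured the group-score estimators are")
print("competitive. Group-score biases are noisy across seeds: when PAVA")
print("pools the means into nearly flat scores the fitted slope is unstable,")
print("so judge them by the MC standard error alongside the bias.")
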