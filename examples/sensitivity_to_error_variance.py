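"""Sensitivity of the EM slope to the assumed measurement-error variance.

The error variance is not identifiable from single measurements per subject,
so it enters as a known input; in practice one fits over a plausible grid.
This example simulates a cohort shaped like an 8-job-category occupational
study (synthetic; published group sizes and variance components) and refits
the constrained EM across a grid of assumed error variances.
"""

import numpy as np

from semieco import CemOptions, fit_cem, generate_carbonblack_like

rng = np.random.default_rng(3)
data = generate_carbonblack_like(rng, beta0=0.0, beta1=-0.16, n_x=50)
true_eta2 = 0.92

print(f"synthetic cohort: G={data.G}, n={data.n}, 50 exposures measured per group")
print(f"data generated with beta1 = -0.16 and error variance {true_eta2}")
print(f"{'assumed eta2':>12s} {'beta1_hat':>10s} {'se':>8s}")
for eta2 in (0.5, 0.7, 0.92, 1.1):
    res = fit_cem(data, "linear", sigma_eta2=eta2, options=CemOptions(seed=11))
    se = f"{res.se_beta1:8.4f}" if res.se_beta1 is not None else "      --"
    print(f"{eta2:12.2f} {res.beta1_hat:10.4f} {se}")
print()
print("Understating the error variance leaves residual attenuation: the")
print("fitted slope strengthens monotonically as the assumed variance grows.")
print("Reporting the fit over a plausible grid is the standard sensitivity")
print("analysis when no replicate measurements pin the variance down.")
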