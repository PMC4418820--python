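"""Parameter recovery: generate noisy blood measurements, refit, re-derive rates.

Emulates a 14-subject cohort sampled at 12 time points with 10% lognormal
assay noise, pools the samples, fits the biexponential model by log-residual
least squares (curve-peeling initialization) and compares the recovered
elimination constant k_10 with the truth.
"""

import numpy as np

from eprkit import DOXIL_PK, derive_rate_constants, fit_biexponential, generate_synthetic_pk

times = np.geomspace(0.1, 240, 12)
truth = derive_rate_constants(DOXIL_PK)

cohort = generate_synthetic_pk(DOXIL_PK, times, noise_cv=0.1, n_subjects=14, seed=20150504)
pooled = [s for subject in cohort for s in subject]
result = fit_biexponential(pooled)
fitted = derive_rate_constants(result.params)

print(f"true   k_10 = {truth.k_10:.5f} /h")
print(f"fitted k_10 = {fitted.k_10:.5f} /h "
      f"({100 * abs(fitted.k_10 - truth.k_10) / truth.k_10:.1f}% error)")
print(f"fitted (A, B, alpha, beta) = ({result.params.A:.2f} mg, {result.params.B:.2f} mg, "
      f"{result.params.alpha:.4f}/h, {result.params.beta:.5f}/h)")
print()
print("The recovered elimination constant is what the tumor-uptake simulations")
print("take as k_el, so fit error propagates directly into predicted %ID.")
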