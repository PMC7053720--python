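"""Simulate levodopa plasma kinetics and refit the rate parameters.

Builds a 100 mg oral-dose plasma curve from known transfer/elimination
clearances, then recovers them from the simulated samples with the
single-guess Nelder-Mead fit.
"""

import numpy as np

import levotap as lt

truth = lt.PKParameters(k12=0.6, k21=0.5, ketot=0.45)
dose = lt.DoseEvent(amount=100.0)
times = np.array([0.0, 15, 30, 45, 60, 75, 90, 120, 150, 180.0])

plasma = lt.simulate_plasma(truth, dose, times)
print("plasma (mg/l) at", times.astype(int).tolist())
print("         ", np.round(plasma.values, 3).tolist())

fit = lt.fit_pk(plasma)
est = fit.parameters
print(f"\nrecovered  k12={est.k12:.3f}  k21={est.k21:.3f}  "
      f"ketot={est.ketot:.3f}  (truth 0.6 / 0.5 / 0.45 l/min)")
print(f"SSE={fit.cost:.2e}  R^2={fit.r2:.5f}")
print("\nThe concentrations rise to a peak near 45 min and decay over the "
      "test; the fit recovers the three clearances from the ten samples.")
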