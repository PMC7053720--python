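"""Group comparison on a small synthetic cohort.

Fits every patient of a 7 + 7 stable/fluctuating cohort and runs the
exact Wilcoxon rank-sum test with Bonferroni correction on the nine
estimated parameters.  (A full 13 + 13 cohort works the same way and is
what the clinical protocol uses; 7 + 7 keeps this example quick.)
"""

import numpy as np
import pandas as pd

import levotap as lt
from levotap.cohort_analysis import compare_groups

curve = lt.default_frequency_curve()
cohort = lt.generate_cohort(7, 7, master_seed=1, curve=curve)
seeds = np.random.SeedSequence(1).generate_state(len(cohort))

rows = []
for record, s in zip(cohort, seeds):
    pk = lt.fit_pk(record.plasma).parameters
    fit = lt.fit_pd(record.tapping, pk, curve, n_restarts=10,
                    seed=int(s % (1 << 31)), n_hops=2, axis_rounds=0,
                    maxiter=400)
    e = fit.parameters
    rows.append({"group": record.group, "k12": pk.k12, "k21": pk.k21,
                 "ketot": pk.ketot, "ke3": e.ke3, "D0": e.D0, "T": e.T,
                 "Dmax": e.Dmax, "Dc50": e.Dc50, "ND": e.ND})
df = pd.DataFrame(rows)

stats = compare_groups(df[df.group == "stable"],
                       df[df.group == "fluctuating"])
print(stats.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print("\nke3 (effect-site removal) and ND (Hill steepness) separate the "
      "groups even after the x9 Bonferroni correction; the plasma-kinetics "
      "parameters do not - wearing-off lives in the brain, not the blood.")
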