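"""Two-stage fit of one synthetic fluctuating patient.

Generates a patient with known ground truth (plasma + tapping on the
clinical schedule), fits the three kinetic parameters to the plasma
samples, then the six dynamic parameters to the tapping samples, and
prints estimates against truth.
"""

import levotap as lt

curve = lt.default_frequency_curve()
record = lt.generate_patient(lt.FLUCTUATING_ARCHETYPE, seed=2, curve=curve)
pk_truth, pd_truth = record.ground_truth

pk_fit = lt.fit_pk(record.plasma)
pd_fit = lt.fit_pd(record.tapping, pk_fit.parameters, curve,
                   n_restarts=10, seed=0)

print(f"patient {record.id} ({record.group});  "
      f"R^2 plasma {pk_fit.r2:.3f}, tapping {pd_fit.r2:.3f}")
print(f"{'param':>6} {'truth':>8} {'estimate':>9}")
for name in ("k12", "k21", "ketot"):
    print(f"{name:>6} {getattr(pk_truth, name):8.3f} "
          f"{getattr(pk_fit.parameters, name):9.3f}")
for name in ("ke3", "T", "D0", "Dmax", "Dc50", "ND"):
    print(f"{name:>6} {getattr(pd_truth, name):8.3f} "
          f"{getattr(pd_fit.parameters, name):9.3f}")

from levotap.cohort_analysis import response_metrics

m = response_metrics(record.tapping, float(record.tapping.values[0]))
print(f"\nonset {m.latency_min} min, duration {m.duration_min} min "
      f"-> classified {m.classification}")
print("\nThe kinetic parameters, the effect-site removal rate and the "
      "basal tone come back close to truth.  The Hill coefficient is only "
      "identified one-sidedly here: once the concentration-effect relation "
      "is effectively all-or-nothing, every very steep ND fits the noisy "
      "samples equally well - what matters (and survives the group "
      "comparison) is that it is large.")
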