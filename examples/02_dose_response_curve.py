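"""The basal-ganglia dose-response curve: dopaminergic input -> tapping rate.

Evaluates the calibrated network's steady-state curve and compares the
default timing (10 ms neurons, 90 ms inter-movement lag) with the legacy
timing (15 ms / 115 ms).
"""

import numpy as np

import levotap as lt

config = lt.default_network_config()
synapses = lt.default_synapses(config)

curve = lt.steady_state_frequency_curve(config, synapses)
print("D grid:     ", np.round(curve.D[::5], 1).tolist())
print("taps/min:   ", np.round(curve.frequency[::5], 1).tolist())
print(f"floor {curve.frequency[0]:.0f}, plateau {curve.frequency.max():.0f}"
      " taps/min")

legacy = lt.steady_state_frequency_curve(
    lt.legacy_network_config(config), synapses)
print(f"legacy plateau (15 ms / 115 ms): {legacy.frequency.max():.0f}"
      " taps/min")

print("\nThe default network saturates above 220 taps/min while the legacy "
      "timing tops out near 180 - the two anchors of the calibration. "
      "Low dopaminergic input leaves the pallidal gate nearly closed, so "
      "selection is slow: the bradykinetic floor.")
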