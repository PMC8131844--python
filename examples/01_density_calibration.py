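"""Fit a refractive-index -> buoyant-density standard curve and apply it.

Builds a small dilution-series standards table, fits the linear calibration
by ordinary least squares, and converts a refractometer reading into a
buoyant density for assigning gradient fractions.
"""

import numpy as np

import sipdetect as sd

# serial dilutions of a CsCl stock: (refractive index, measured density g/ml)
rng = np.random.default_rng(0)
ri = np.linspace(1.385, 1.425, 8)
density = 10.302 * ri - 12.747 + rng.normal(0, 1e-4, size=ri.size)
standards = [sd.CalibrationStandard(r, d) for r, d in zip(ri, density)]

model = sd.fit_density_calibration(standards)
print(f"fitted curve: BD = {model.slope:.3f}*RI + {model.intercept:.3f}  "
      f"(r = {model.r:.4f}, n = {model.n_points})")

reading = 1.4040
print(f"RI {reading} -> {sd.ri_to_bd(reading, model):.6f} g/ml")
print("A fraction reading RI 1.4040 sits just above the 1.70 g/ml heavy-window "
      "threshold, so it would be analyzed as a heavy fraction.")
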