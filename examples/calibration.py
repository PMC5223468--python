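"""Calibration statistics: OD-volume regression and measurement agreement.

A dye-extraction optical density (OD) reading is proportional to, but not
1:1 with, imaged lipid volume, so absolute volumes from OD need a fitted
calibration line. The ICC quantifies whether two measurement procedures of
the same muscles are interchangeable.
"""

import numpy as np

from lipidstack import (
    CalibrationPair,
    RaterPair,
    icc_absolute_agreement,
    od_volume_regression,
)

rng = np.random.default_rng(0)

# --- OD vs volume: synthetic panel of 15 muscles around a true line --------
volumes = rng.uniform(5e4, 2e6, size=15)  # um^3
ods = 4e-7 * volumes + 0.05 + rng.normal(0.0, 0.04, size=15)
pairs = [CalibrationPair(f"m{i}", float(max(o, 0)), float(v))
         for i, (o, v) in enumerate(zip(ods, volumes))]
fit = od_volume_regression(pairs)
print(f"OD = {fit.slope:.3e} * volume + {fit.intercept:.3f}   (r^2 = {fit.r_squared:.3f})")
print(f"an OD of 0.40 implies ~{fit.predict_volume(0.40):,.0f} um^3 of lipid")

# --- agreement between two measurement procedures ---------------------------
truth = rng.uniform(1e5, 2e6, size=12)
semi_auto = truth * 0.97 + rng.normal(0, 2e4, size=12)
manual = truth + rng.normal(0, 2e4, size=12)
raters = [RaterPair(f"m{i}", float(a), float(b))
          for i, (a, b) in enumerate(zip(semi_auto, manual))]
print(f"ICC(2,1) semi-automated vs manual: {icc_absolute_agreement(raters):.3f}")
# values above 0.95 indicate the procedures are effectively interchangeable.
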