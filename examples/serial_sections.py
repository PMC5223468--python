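"""Adipocyte volume from serial histological sections.

An adipocyte tracked through consecutive sections contributes one slab per
section: volume = sum(area_i) x thickness. A sphere of radius 30 um sampled
every 10 um illustrates the discretization error of the estimate.
"""

import math

import numpy as np

from lipidstack import SectionTrack, serial_section_volume

r, thickness = 30.0, 10.0
offsets = np.arange(-25.0, 26.0, thickness)  # section midplanes through the cell
areas = tuple(math.pi * (r**2 - z**2) for z in offsets)

track = SectionTrack(track_id=1, areas=areas, section_thickness=thickness)
slab = serial_section_volume(track)
analytic = 4.0 / 3.0 * math.pi * r**3

print(f"section areas (um^2): {[f'{a:.0f}' for a in areas]}")
print(f"slab-summed volume:   {slab:,.0f} um^3")
print(f"analytic sphere:      {analytic:,.0f} um^3  "
      f"(slab error {slab / analytic - 1:+.1%})")
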