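"""Quantitative T1 mapping on the digital phantom.

Builds the lookup table from the forward Bloch model, simulates the
noise-free phantom signals, inverts the TI1/TI2 ratio voxelwise with
B1-binned tables, and compares recovered T1 to the ground truth.
"""

import numpy as np

from t1234.phantom import ideal_signal_volume, make_phantom
from t1234.protocol import packaged_protocol
from t1234.t1map import build_lut, map_t1

p = packaged_protocol("retrospective")
ph = make_phantom((64, 64, 64), seed=0)

lut = build_lut(p)
print(f"lookup table: {len(lut.t1_axis)} T1 nodes, ratio "
      f"{lut.ratio_axis[0]:+.3f} -> {lut.ratio_axis[-1]:+.3f} over "
      f"{lut.monotonic_domain[0]:.0f}-{lut.monotonic_domain[1]:.0f} ms (monotonic)")

s1 = ideal_signal_volume(ph, p, 1)
s2 = ideal_signal_volume(ph, p, 2)
t1_map = map_t1(s1, s2, p, b1_map=ph.b1_map)

for name, label, truth in (("CSF", 1, 2800.0), ("GM", 2, 1900.0), ("WM", 3, 1200.0)):
    vals = t1_map.values[ph.labels == label]
    print(f"{name}: true {truth:.0f} ms, recovered median {np.nanmedian(vals):.1f} ms, "
          f"median |error| {np.nanmedian(np.abs(vals - truth)):.1f} ms")
# Residual errors come from the finite B1 binning (50 bins over the
# phantom's 0.7-1.3 transmit range); the 10 ms lookup grid itself
# contributes < 0.1 ms after piecewise-linear inversion.
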