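"""Cortical-depth T1 profile and mid-depth landmark detection.

Injects a 100 ms T1 dip at mid-depth into the phantom's gray-matter
ribbon (emulating the heavily myelinated inner band), runs the full T1
pipeline, and recovers the landmark from the depth profile.
"""

import numpy as np

from t1234.phantom import LABEL_GM, ideal_signal_volume, make_phantom
from t1234.profiles import detect_dip, extract_profile
from t1234.protocol import packaged_protocol
from t1234.t1map import map_t1

p = packaged_protocol("retrospective")
ph = make_phantom((64, 64, 64), seed=0)
gm = ph.labels == LABEL_GM

t1_override = np.full(ph.labels.shape, np.nan)
t1_override[gm] = 1900.0 - 100.0 * np.exp(-((ph.depth_map[gm] - 0.5) ** 2) / (2 * 0.1**2))

s1 = ideal_signal_volume(ph, p, 1, t1_override=t1_override)
s2 = ideal_signal_volume(ph, p, 2, t1_override=t1_override)
t1_map = map_t1(s1, s2, p, b1_map=ph.b1_map)

profile = extract_profile(t1_map.values, ph.depth_map, gm, n_bins=21)
dip = detect_dip(profile, min_prominence=50.0)
print("depth   mean T1 [ms]   n")
for d, m, n in zip(profile.depth_bins, profile.mean, profile.n):
    marker = "  <-- dip" if dip is not None and abs(d - dip) < 1e-9 else ""
    print(f"{d:5.3f}   {m:12.1f}   {n:5d}{marker}")
print(f"\ndetected landmark dip at depth {dip:.3f} (injected at 0.500)")
# Depth 0 is the white-matter surface, 1 the pial surface; the dip marks
# the myeloarchitectonic band used to calibrate depth bins to layers.
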